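"""CSV/YAML/JSON interchange and the end-to-end analysis pipeline.

Formats (all UTF-8, header required):

curves CSV    subject, time_min, source, value[, sd]
MID CSV       subject, time_min, metabolite, n_carbons, iso_index, value, is_excess
dose YAML     A0/P0/B0 (mmol), delivery_time_min
subject YAML  subject, body_weight_kg[, v_plasma_L]
results       JSON (fit), CSV (attribution, collinearity, fractions)

The pipeline runs the analysis in the study's order: natural-abundance
correction → source attribution → kinetic fit → identifiability scan →
fractional dose contributions, writing one artifact per stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import attribute_sources, citrate_design, glucose_design, screen_enrichment
from .estimate import STUDY_FIXED, FitResult, fit, grid_fix
from .fractions import estimate_fractions
from .identifiability import identifiable_subsets, sensitivity_matrix
from .mid import MassIsotopologueDistribution, NaturalAbundanceModel, correct_natural_abundance
from .model import SOURCES, EnrichmentCurve, RateConstants, SubjectProfile, TracerDose
from .synthetic import GeneratorConfig, generate_enrichment_curves, generate_raw_mids

logger = logging.getLogger("gutflux")

__all__ = [
    "read_curves",
    "write_curves",
    "read_mids",
    "write_mids",
    "load_dose",
    "load_subject",
    "PipelineConfig",
    "run_pipeline",
]

_CURVE_COLS = ["subject", "time_min", "source", "value"]
_MID_COLS = ["subject", "time_min", "metabolite", "n_carbons", "iso_index", "value", "is_excess"]


class SchemaError(ValueError):
    """CSV failed schema validation; message carries the offending rows."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def write_curves(curves: Iterable[EnrichmentCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for i in range(len(c)):
            row = {
                "subject": c.subject,
                "time_min": c.times_min[i],
                "source": c.source,
                "value": c.values[i],
            }
            if c.sd is not None:
                row["sd"] = c.sd[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves(path: str | Path) -> dict[str, dict[str, EnrichmentCurve]]:
    """Read a curves CSV into {subject: {source: EnrichmentCurve}}.

    The sd column is optional; downstream weighting then falls back to a
    pooled per-curve scale.  Duplicated (subject, time, source) rows,
    non-monotone times and non-positive sd are fatal, with row numbers
    (1-based, counting the header as row 1) in the message.
    """
    path = str(path)
    df = pd.read_csv(path)
    _require_columns(df, _CURVE_COLS, path)
    dup = df.duplicated(subset=["subject", "time_min", "source"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise SchemaError(f"{path}: duplicated (subject, time_min, source) rows at lines {rows}")
    if "sd" in df.columns:
        bad = df["sd"].notna() & (df["sd"] <= 0)
        if bad.any():
            rows = (df.index[bad] + 2).tolist()
            raise SchemaError(f"{path}: non-positive sd at lines {rows}")
    out: dict[str, dict[str, EnrichmentCurve]] = {}
    for (subj, source), g in df.groupby(["subject", "source"], sort=True):
        t = g["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            rows = (g.index[1:][np.diff(t) <= 0] + 2).tolist()
            raise SchemaError(f"{path}: non-increasing time_min for {subj}/{source} at lines {rows}")
        sd = None
        if "sd" in g.columns and g["sd"].notna().all():
            sd = g["sd"].to_numpy(dtype=float)
        out.setdefault(str(subj), {})[str(source)] = EnrichmentCurve(
            times_min=t,
            values=g["value"].to_numpy(dtype=float),
            source=str(source),
            sd=sd,
            subject=str(subj),
        )
    return out


def write_mids(mids: Iterable[MassIsotopologueDistribution], path: str | Path) -> None:
    rows = []
    for m in mids:
        for i, v in enumerate(m.values):
            rows.append(
                {
                    "subject": m.subject,
                    "time_min": m.time_min,
                    "metabolite": m.metabolite,
                    "n_carbons": m.n_carbons,
                    "iso_index": i,
                    "value": v,
                    "is_excess": int(m.is_excess),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mids(path: str | Path) -> list[MassIsotopologueDistribution]:
    path = str(path)
    df = pd.read_csv(path)
    _require_columns(df, _MID_COLS, path)
    dup = df.duplicated(subset=["subject", "time_min", "metabolite", "iso_index"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise SchemaError(f"{path}: duplicated MID rows at lines {rows}")
    out = []
    for (subj, t, metab, n_c, is_exc), g in df.groupby(
        ["subject", "time_min", "metabolite", "n_carbons", "is_excess"], sort=True
    ):
        g = g.sort_values("iso_index")
        idx = g["iso_index"].to_numpy(dtype=int)
        if not np.array_equal(idx, np.arange(int(n_c) + 1)):
            raise SchemaError(
                f"{path}: {subj}/{metab}@{t} min must have iso_index 0..{int(n_c)}, got {idx.tolist()}"
            )
        out.append(
            MassIsotopologueDistribution(
                metabolite=str(metab),
                n_carbons=int(n_c),
                values=g["value"].to_numpy(dtype=float),
                time_min=float(t),
                subject=str(subj),
                is_excess=bool(is_exc),
            )
        )
    return out


def load_dose(path: str | Path) -> TracerDose:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return TracerDose(**raw)


def load_subject(path: str | Path) -> SubjectProfile:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return SubjectProfile(**raw)


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end run.

    When ``curves_csv``/``mids_csv`` are None the synthetic generator supplies
    the corresponding inputs (seeded by ``seed``), so a default config runs
    the whole pipeline self-contained.
    """

    out_dir: str | Path = "gutflux_out"
    curves_csv: str | Path | None = None
    mids_csv: str | Path | None = None
    dose: TracerDose = field(default_factory=TracerDose)
    subject: SubjectProfile | None = None  # None -> average over input subjects
    fixed: Mapping[str, float] | None = None  # None -> STUDY_FIXED
    run_grid_search: bool = False
    grid: Sequence[float] | None = None
    collinearity_threshold: float = 20.0
    attribution_metabolites: tuple[str, ...] = ("glucose", "citrate")
    screen_threshold: float = 0.005
    p13C: float = 0.0107
    luminal_uncorrected: bool = True  # luminal spectra are never NA-corrected
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "dose" in raw:
            raw["dose"] = TracerDose(**raw["dose"])
        if raw.get("subject"):
            raw["subject"] = SubjectProfile(**raw["subject"])
        return cls(**raw)


def _average_curves(
    curves: Mapping[str, Mapping[str, EnrichmentCurve]]
) -> dict[str, EnrichmentCurve]:
    subj_ids = sorted(curves)
    out = {}
    for source in SOURCES:
        stack = np.array([curves[s][source].values for s in subj_ids])
        times = curves[subj_ids[0]][source].times_min
        sd = None
        if stack.shape[0] > 1:
            sd = stack.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                sd = None
        out[source] = EnrichmentCurve(
            times_min=times, values=stack.mean(axis=0), source=source, sd=sd, subject="average"
        )
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run correct → attribute → fit → identify → fractions; write artifacts.

    Returns a summary dict; artifacts land in cfg.out_dir.  Any stage failure
    aborts with the stage name in the exception message.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": cfg.seed}
    logger.info("gutflux %s pipeline, seed=%d, out=%s", __version__, cfg.seed, out)

    stage = "load-inputs"
    try:
        if cfg.curves_csv is not None:
            curves = read_curves(cfg.curves_csv)
        else:
            ds = generate_enrichment_curves(GeneratorConfig(seed=cfg.seed, dose=cfg.dose))
            curves = ds.curves
            with open(out / "truth_curves.json", "w", encoding="utf-8") as fh:
                json.dump(ds.truth, fh, indent=2)
        if not curves:
            logger.warning("no subjects in input; nothing to do")
            summary["status"] = "empty"
            return summary
        if cfg.mids_csv is not None:
            mids = read_mids(cfg.mids_csv)
        else:
            gen = generate_raw_mids(GeneratorConfig(seed=cfg.seed, dose=cfg.dose))
            mids = gen.mids
            with open(out / "truth_mids.json", "w", encoding="utf-8") as fh:
                json.dump(gen.truth, fh, indent=2)

        stage = "correct-na"
        na = NaturalAbundanceModel(p13C=cfg.p13C)
        corrected = [
            m if m.is_excess else correct_natural_abundance(m, na) for m in mids
        ]
        write_mids(corrected, out / "corrected_mids.csv")

        stage = "attribute"
        designs = {"glucose": glucose_design(), "citrate": citrate_design()}
        rows = []
        for m in corrected:
            if m.metabolite in designs and m.metabolite in cfg.attribution_metabolites:
                r = attribute_sources(m, designs[m.metabolite], dose=cfg.dose)
                for scfa in r.coefficients:
                    rows.append(
                        {
                            "subject": m.subject,
                            "time_min": m.time_min,
                            "metabolite": m.metabolite,
                            "scfa": scfa,
                            "coefficient": r.coefficients[scfa],
                            "normalized_contribution": r.normalized_contribution[scfa],
                            "condition_number": r.condition_number,
                        }
                    )
            else:
                for iso, v in screen_enrichment(m, cfg.screen_threshold):
                    rows.append(
                        {
                            "subject": m.subject,
                            "time_min": m.time_min,
                            "metabolite": m.metabolite,
                            "scfa": f"screen:M+{iso}",
                            "coefficient": v,
                            "normalized_contribution": np.nan,
                            "condition_number": np.nan,
                        }
                    )
        pd.DataFrame(rows).to_csv(out / "attribution.csv", index=False)

        stage = "fit"
        avg = _average_curves(curves)
        subject = cfg.subject or SubjectProfile(subject="average", body_weight_kg=75.0)
        fixed = dict(cfg.fixed) if cfg.fixed is not None else dict(STUDY_FIXED)
        if cfg.run_grid_search:
            grid = cfg.grid if cfg.grid is not None else None
            fixed, _ = grid_fix(avg, cfg.dose, subject, tuple(fixed), grid=grid)
        result = fit(avg, cfg.dose, subject, fixed=fixed)
        with open(out / "fit.json", "w", encoding="utf-8") as fh:
            json.dump(result.to_dict(), fh, indent=2)

        stage = "identify"
        times = avg["acetate"].times_min
        post = times[times >= 0]
        w = None
        if all(avg[s].sd is not None for s in SOURCES):
            w = {s: avg[s].sd[times >= 0] for s in SOURCES}
        S, zero_cols = sensitivity_matrix(result.estimated, cfg.dose, subject, post, weights=w)
        report = identifiable_subsets(S, threshold=cfg.collinearity_threshold)
        report.to_frame().to_csv(out / "collinearity.csv", index=False)

        stage = "fractions"
        fracs = estimate_fractions(result.estimated, cfg.dose, subject)
        pd.DataFrame(
            [
                {
                    "source": f.source,
                    "auc_mM_min": f.auc,
                    "clearance_L_per_min": f.clearance_L_per_min,
                    "fraction_auc": f.fraction_auc,
                    "fraction_ratio": f.fraction_ratio,
                    "agreement_gap": f.agreement_gap,
                }
                for f in fracs.values()
            ]
        ).to_csv(out / "fractions.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    summary.update(
        {
            "status": "ok",
            "n_subjects": len(curves),
            "fixed": result.fixed,
            "estimated": result.estimated.to_dict(),
            "fractional_incorporation": result.fractions,
            "max_identifiable_size": report.max_identifiable_size,
            "zero_sensitivity_columns": zero_cols,
        }
    )
    with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("pipeline complete: %s", summary["fractional_incorporation"])
    return summary
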