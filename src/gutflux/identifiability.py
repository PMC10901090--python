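"""Practical identifiability via scaled sensitivity functions and collinearity indices.

For a candidate parameter set θ evaluated on a measurement layout, the scaled
sensitivity of observation i to parameter j is

    S[i, j] = (∂Ŷ_i/∂θ_j) · θ_j / w_i

with θ_j providing relative (per-parameter) scaling and w_i an observation
scale (the per-point standard deviation when available, otherwise the maximum
of the corresponding curve).  The collinearity index of a parameter subset is

    γ = 1 / sqrt(λ_min(ŜᵀŜ))

where Ŝ holds the subset's columns normalized to unit Euclidean norm.  γ = 1
for orthogonal effects and diverges as the subset's effects on the observable
outputs become linearly dependent; subsets with γ below a threshold
(conventionally 20) are considered jointly identifiable in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .model import PARAM_NAMES, SOURCES, RateConstants, SubjectProfile, TracerDose, simulate

__all__ = [
    "CollinearityReport",
    "sensitivity_matrix",
    "collinearity_index",
    "identifiable_subsets",
    "choose_fixed_pair",
]

_SOURCE_COL = {"acetate": 2, "propionate": 4, "butyrate": 6}


def sensitivity_matrix(
    k: RateConstants,
    dose: TracerDose,
    subject: SubjectProfile,
    times: Sequence[float],
    weights: dict[str, np.ndarray] | None = None,
    rel_step: float = 1e-6,
) -> tuple[np.ndarray, list[str]]:
    """Parameter- and observation-scaled sensitivity matrix.

    Observations are the three plasma glucose curves stacked in source order
    (acetate, propionate, butyrate) over `times`.  Central finite differences
    with relative step `rel_step` are used; a parameter that is exactly zero
    yields an identically zero column (structurally uninformative at that
    point) which downstream code reports as unidentifiable.

    Returns (S, zero_columns) where S has shape (3·len(times), 8) with columns
    ordered per PARAM_NAMES, and zero_columns lists parameters flagged as
    structurally unidentifiable at the evaluation point.
    """
    times = np.asarray(times, dtype=float)
    theta = k.as_array()

    def observed(kv: RateConstants) -> np.ndarray:
        res = simulate(kv, dose, subject, times)
        return np.concatenate([res.states[:, _SOURCE_COL[s]] for s in SOURCES])

    base = observed(k)
    n_t = times.size

    if weights is None:
        w = np.empty_like(base)
        for i, s in enumerate(SOURCES):
            seg = base[i * n_t : (i + 1) * n_t]
            scale = np.max(np.abs(seg))
            w[i * n_t : (i + 1) * n_t] = scale if scale > 0 else 1.0
    else:
        w = np.concatenate([np.asarray(weights[s], dtype=float) for s in SOURCES])
        if np.any(w <= 0):
            raise ValueError("weights must be > 0")

    S = np.zeros((base.size, len(PARAM_NAMES)))
    zero_columns: list[str] = []
    for j, name in enumerate(PARAM_NAMES):
        if theta[j] == 0.0:
            zero_columns.append(name)
            continue
        h = rel_step * theta[j]
        up = theta.copy()
        dn = theta.copy()
        up[j] += h
        dn[j] -= h
        y_up = observed(RateConstants.from_array(up))
        y_dn = observed(RateConstants.from_array(dn))
        # (dY/dθ)·θ / w  ==  (Y+ − Y−) / (2·rel_step) / w
        S[:, j] = (y_up - y_dn) / (2.0 * rel_step) / w
        if not np.any(S[:, j]):
            zero_columns.append(name)
    return S, zero_columns


def collinearity_index(S: np.ndarray, subset: Sequence[int | str]) -> float:
    """Collinearity index of a parameter subset (>= 1; inf if rank-deficient)."""
    idx = [PARAM_NAMES.index(p) if isinstance(p, str) else int(p) for p in subset]
    if len(idx) < 2:
        raise ValueError("subset must contain at least 2 parameters")
    cols = S[:, idx]
    norms = np.linalg.norm(cols, axis=0)
    if np.any(norms == 0):
        return np.inf
    normed = cols / norms
    lam_min = float(np.linalg.eigvalsh(normed.T @ normed)[0])
    if lam_min <= 0:
        return np.inf
    return 1.0 / np.sqrt(lam_min)


@dataclass
class CollinearityReport:
    """Exhaustive collinearity scan over parameter subsets."""

    records: list[dict] = field(default_factory=list)  # subset, size, index, identifiable
    threshold: float = 20.0
    max_identifiable_size: int = 0

    def identifiable(self, size: int | None = None) -> list[dict]:
        out = [r for r in self.records if r["identifiable"]]
        if size is not None:
            out = [r for r in out if r["size"] == size]
        return out

    def best_subset(self, size: int) -> dict | None:
        cands = [r for r in self.records if r["size"] == size]
        if not cands:
            return None
        return min(cands, key=lambda r: r["index"])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "subset": "+".join(r["subset"]),
                    "size": r["size"],
                    "index": r["index"],
                    "identifiable": int(r["identifiable"]),
                }
                for r in self.records
            ]
        )


def identifiable_subsets(
    S: np.ndarray,
    threshold: float = 20.0,
    parameters: Sequence[str] = PARAM_NAMES,
    min_size: int = 2,
) -> CollinearityReport:
    """Enumerate all parameter subsets of sizes min_size..n and score each.

    With eight parameters this is at most 247 subsets, so enumeration is
    exhaustive rather than heuristic.
    """
    n = len(parameters)
    records: list[dict] = []
    max_size = 0
    for size in range(min_size, n + 1):
        for combo in combinations(range(n), size):
            gamma = collinearity_index(S, combo)
            ok = bool(gamma < threshold)
            records.append(
                {
                    "subset": tuple(parameters[i] for i in combo),
                    "size": size,
                    "index": gamma,
                    "identifiable": ok,
                }
            )
            if ok and size > max_size:
                max_size = size
    return CollinearityReport(records=records, threshold=threshold, max_identifiable_size=max_size)


def choose_fixed_pair(
    S: np.ndarray,
    first: str = "kLa",
    parameters: Sequence[str] = PARAM_NAMES,
) -> tuple[str, float]:
    """Pick the second parameter to fix alongside `first`.

    The chosen partner is the one whose removal (together with `first`)
    minimizes the collinearity index of the six remaining free parameters.
    Returns (partner_name, index_of_remaining_six).
    """
    best: tuple[str, float] | None = None
    for cand in parameters:
        if cand == first:
            continue
        free = [p for p in parameters if p not in (first, cand)]
        gamma = collinearity_index(S, free)
        if best is None or gamma < best[1]:
            best = (cand, gamma)
    assert best is not None
    return best
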