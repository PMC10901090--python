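"""Objectives, grid search and weighted least-squares parameter recovery."""

import numpy as np
import pytest

import gutflux as gf
from gutflux.estimate import STUDY_FIXED, default_grid


def perturbed_start(truth: gf.RateConstants, factor: float = 2.0) -> dict[str, float]:
    return {
        n: factor * getattr(truth, n) for n in gf.PARAM_NAMES if n not in STUDY_FIXED
    }


class TestObjectives:
    def test_perfect_fit_has_zero_objective(self, regime_k, noiseless_dataset):
        cfg, ds = noiseless_dataset
        curves, subj = ds.curves["S01"], ds.subjects["S01"]
        assert gf.weighted_sse(curves, regime_k, cfg.dose, subj) == pytest.approx(0.0, abs=1e-10)
        assert gf.rmse(curves, regime_k, cfg.dose, subj) == pytest.approx(0.0, abs=1e-14)

    def test_single_point_weighted_residual(self, regime_k, subject, dose):
        # one observation, residual 0.2, sd 0.1 -> ((0.2)/0.1)^2 = 4
        sim = gf.simulate(regime_k, dose, subject, [60.0])
        curves = {}
        for s in gf.SOURCES:
            c = sim.curve(s)
            offset = 0.2 if s == "acetate" else 0.0
            curves[s] = gf.EnrichmentCurve(
                c.times_min, c.values + offset, s, sd=np.array([0.1])
            )
        assert gf.weighted_sse(curves, regime_k, dose, subject) == pytest.approx(4.0, rel=1e-6)

    def test_doubling_sd_quarters_sse(self, regime_k, average_dataset):
        cfg, ds, avg = average_dataset
        subj = gf.SubjectProfile(subject="average")
        base = gf.weighted_sse(avg, regime_k, cfg.dose, subj)
        wide = {
            s: gf.EnrichmentCurve(c.times_min, c.values, s, sd=2 * c.sd, subject=c.subject)
            for s, c in avg.items()
        }
        assert gf.weighted_sse(wide, regime_k, cfg.dose, subj) == pytest.approx(base / 4, rel=1e-9)

    def test_rmse_forms_rank_identically(self, average_dataset):
        cfg, ds, avg = average_dataset
        subj = gf.SubjectProfile(subject="average")
        candidates = [
            gf.PAPER_REGIME_K,
            gf.PAPER_REGIME_K.replace(k2=0.05),
            gf.PAPER_REGIME_K.replace(k1b=0.01),
        ]
        literal = [gf.rmse(avg, k, cfg.dose, subj, form="literal") for k in candidates]
        conventional = [gf.rmse(avg, k, cfg.dose, subj, form="conventional") for k in candidates]
        assert np.argsort(literal).tolist() == np.argsort(conventional).tolist()
        # residuals (1, 2): literal 5, conventional sqrt(2.5)
        assert np.sqrt(np.array([5.0]) / 2)[0] == pytest.approx(np.sqrt(2.5))


class TestFractionalIncorporation:
    @pytest.mark.parametrize(
        "k1p,k0p,expected", [(0.01, 0.03, 0.25), (0.01, 0.0, 1.0), (0.0, 0.03, 0.0)]
    )
    def test_ratio_arithmetic(self, k1p, k0p, expected):
        k = gf.RateConstants(k1a=0, k1p=k1p, k1b=k1p, kLa=0, k2=0, k0a=k0p, k0p=k0p, k0b=k0p)
        assert gf.fractional_incorporation(k)["propionate"] == pytest.approx(expected)

    def test_undefined_branch_reported_missing(self):
        k = gf.RateConstants(0, 0.01, 0.01, 0, 0, 0, 0.01, 0.01)
        assert gf.fractional_incorporation(k)["acetate"] is None


class TestFit:
    def test_noiseless_recovery_from_doubled_start(self, regime_k, noiseless_dataset):
        cfg, ds = noiseless_dataset
        curves, subj = ds.curves["S01"], ds.subjects["S01"]
        res = gf.fit(curves, cfg.dose, subj, start=perturbed_start(regime_k))
        assert res.converged
        for n in res.free_names:
            assert getattr(res.estimated, n) == pytest.approx(getattr(regime_k, n), rel=1e-3)
        for s, target in res.fractions.items():
            assert target == pytest.approx(gf.fractional_incorporation(regime_k)[s], rel=1e-3)
        assert all(res.pvalues[n] < 0.05 for n in res.free_names)

    def test_zero_information_data_hits_lower_bound(self, dose, subject, times):
        flat = {
            s: gf.EnrichmentCurve(times, np.zeros_like(times), s, subject="flat")
            for s in gf.SOURCES
        }
        # kLa kept positive so k1a still influences G_a; all uptake constants
        # must then fall to the lower bound on identically zero observations
        res = gf.fit(flat, dose, subject, fixed={"kLa": 0.0071, "k0p": 0.0109})
        # uptake constants collapse toward the lower bound (flat directions in
        # the loss constants keep them from landing on it exactly)
        assert res.estimated.k1a == pytest.approx(0.0, abs=1e-3)
        assert res.estimated.k1p == pytest.approx(0.0, abs=1e-3)
        assert res.estimated.k1b == pytest.approx(0.0, abs=1e-3)
        assert res.sse == pytest.approx(0.0, abs=1e-4)

    def test_fit_invariant_to_curve_ordering(self, noiseless_dataset):
        cfg, ds = noiseless_dataset
        curves, subj = ds.curves["S01"], ds.subjects["S01"]
        reordered = {s: curves[s] for s in reversed(gf.SOURCES)}
        r1 = gf.fit(curves, cfg.dose, subj)
        r2 = gf.fit(reordered, cfg.dose, subj)
        np.testing.assert_allclose(r1.estimated.as_array(), r2.estimated.as_array(), rtol=1e-10)

    def test_partition_validation(self, noiseless_dataset):
        cfg, ds = noiseless_dataset
        with pytest.raises(ValueError):
            gf.fit(ds.curves["S01"], cfg.dose, ds.subjects["S01"], fixed={"bogus": 0.1})


class TestGridFix:
    def test_single_point_grid_returns_that_point(self, noiseless_dataset):
        cfg, ds = noiseless_dataset
        fixed, _ = gf.grid_fix(
            ds.curves["S01"], cfg.dose, ds.subjects["S01"], grid=[0.0071]
        )
        assert fixed == {"kLa": 0.0071, "k0p": 0.0071}

    def test_noiseless_grid_selects_generating_node(self, regime_k, noiseless_dataset):
        cfg, ds = noiseless_dataset
        grid = {"kLa": [0.002, 0.0071, 0.02], "k0p": [0.004, 0.0109, 0.03]}
        fixed, objective = gf.grid_fix(
            ds.curves["S01"], cfg.dose, ds.subjects["S01"], grid=grid,
            start=perturbed_start(regime_k, 1.5),
        )
        assert fixed == {"kLa": 0.0071, "k0p": 0.0109}
        assert objective == pytest.approx(0.0, abs=1e-12)

    def test_study_defaults_when_skipping_search(self):
        assert STUDY_FIXED == {"kLa": 0.0071, "k0p": 0.0109}

    def test_default_grid_shape(self):
        g = default_grid(10)
        assert g[0] == 0.0 and g.size == 11
        assert np.all((g >= 0) & (g <= 1))
        with pytest.raises(ValueError):
            gf.grid_fix({}, gf.TracerDose(), gf.SubjectProfile(), grid=[])
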