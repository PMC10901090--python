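"""Scaled sensitivities and collinearity-index identifiability analysis."""

import numpy as np
import pytest
import sympy as sp

import gutflux as gf
from gutflux.identifiability import (
    choose_fixed_pair,
    collinearity_index,
    identifiable_subsets,
    sensitivity_matrix,
)
from gutflux.model import PARAM_NAMES


class TestCollinearityIndex:
    def test_orthogonal_columns_give_one(self):
        S = np.eye(4)[:, :2]
        assert collinearity_index(S, [0, 1]) == pytest.approx(1.0)

    def test_identical_columns_unidentifiable(self):
        S = np.column_stack([np.ones(5), np.ones(5)])
        assert collinearity_index(S, [0, 1]) == np.inf

    def test_sixty_degree_columns(self):
        # two unit columns at 60 degrees: Gram [[1, .5], [.5, 1]], eigmin 1/2
        a = np.array([1.0, 0.0])
        b = np.array([0.5, np.sqrt(3) / 2])
        S = np.column_stack([a, b])
        assert collinearity_index(S, [0, 1]) == pytest.approx(np.sqrt(2.0))

    def test_invariant_to_positive_column_rescaling(self):
        rng = np.random.default_rng(0)
        S = rng.normal(size=(20, 4))
        g1 = collinearity_index(S, [0, 1, 2])
        S2 = S * np.array([3.0, 0.1, 7.0, 1.0])
        assert collinearity_index(S2, [0, 1, 2]) == pytest.approx(g1)

    def test_matches_condition_oracle_on_random_matrices(self):
        # for unit-normalized columns, gamma = 1/smallest singular value
        rng = np.random.default_rng(1)
        for _ in range(20):
            S = rng.normal(size=(12, 5))
            idx = [0, 2, 4]
            normed = S[:, idx] / np.linalg.norm(S[:, idx], axis=0)
            expected = 1.0 / np.linalg.svd(normed, compute_uv=False)[-1]
            assert collinearity_index(S, idx) == pytest.approx(expected, rel=1e-9)

    def test_subset_size_validation(self):
        with pytest.raises(ValueError):
            collinearity_index(np.eye(3), [0])


class TestSubsetEnumeration:
    def test_orthogonal_design_fully_identifiable(self):
        S = np.eye(10)[:, :8]
        rep = identifiable_subsets(S)
        assert rep.max_identifiable_size == 8
        assert len(rep.records) == 2 ** 8 - 8 - 1  # all subsets of sizes 2..8

    def test_duplicated_column_never_identifiable_together(self):
        rng = np.random.default_rng(2)
        S = rng.normal(size=(30, 8))
        S[:, 3] = S[:, 5]
        rep = identifiable_subsets(S)
        for r in rep.records:
            if {"kLa", "k0a"} <= set(r["subset"]):  # indices 3 and 5 in PARAM_NAMES
                assert not r["identifiable"]

    def test_superset_index_monotone(self):
        rng = np.random.default_rng(3)
        S = rng.normal(size=(25, 6))
        sub = collinearity_index(S, [0, 1, 2])
        sup = collinearity_index(S, [0, 1, 2, 3])
        assert sup >= sub - 1e-12


class TestSensitivityMatrix:
    def test_absent_tracer_zeroes_branch_parameters(self, regime_k, subject, times):
        dose = gf.TracerDose(A0=0.0, P0=4.0, B0=0.9)
        S, zero_cols = sensitivity_matrix(regime_k, dose, subject, times[1:])
        for name in ("k1a", "kLa", "k0a"):
            assert name in zero_cols
            assert not np.any(S[:, PARAM_NAMES.index(name)])

    def test_zero_parameter_flagged_structurally_unidentifiable(self, dose, subject, times):
        k = gf.PAPER_REGIME_K.replace(k1a=0.0)
        S, zero_cols = sensitivity_matrix(k, dose, subject, times[1:])
        assert "k1a" in zero_cols
        rep = identifiable_subsets(S)
        for r in rep.records:
            if "k1a" in r["subset"]:
                assert r["index"] == np.inf and not r["identifiable"]

    def test_k2_column_matches_symbolic_derivative(self, regime_k, dose, subject):
        """Finite-difference sensitivity vs symbolic d(G_p)/d(k2) of the
        closed-form two-exponential solution."""
        t_sym, k1p, k0p, k2s, P0, V = sp.symbols("t k1p k0p k2 P0 V", positive=True)
        alpha = k1p + k0p
        gp = k1p * P0 / (V * (k2s - alpha)) * (sp.exp(-alpha * t_sym) - sp.exp(-k2s * t_sym))
        dgp_dk2 = sp.lambdify((t_sym, k1p, k0p, k2s, P0, V), sp.diff(gp, k2s), "numpy")

        times = np.linspace(15.0, 210.0, 14)
        S, _ = sensitivity_matrix(regime_k, dose, subject, times)
        # propionate block is the middle third; unscale by theta/w
        n = times.size
        col = S[n : 2 * n, PARAM_NAMES.index("k2")]
        res = gf.simulate(regime_k, dose, subject, times)
        w = res.curve("propionate").values.max()
        raw = col * w / regime_k.k2
        expected = dgp_dk2(
            times, regime_k.k1p, regime_k.k0p, regime_k.k2, dose.P0, subject.v_plasma_L
        )
        np.testing.assert_allclose(raw, expected, rtol=1e-5)


class TestStudyLayout:
    def test_eight_set_collinear_but_large_subsets_exist(self, regime_k, average_dataset):
        """At the paper-regime constants on default synthetic average curves the
        full eight-parameter set is collinear (index > 20) while six-parameter
        subsets are comfortably identifiable."""
        cfg, ds, avg = average_dataset
        times = avg["acetate"].times_min
        post = times >= 0
        weights = {s: avg[s].sd[post] for s in gf.SOURCES}
        subj = gf.SubjectProfile(subject="average")
        S, zero_cols = sensitivity_matrix(regime_k, cfg.dose, subj, times[post], weights=weights)
        assert not zero_cols
        rep = identifiable_subsets(S)
        assert rep.best_subset(8)["index"] > 20
        assert rep.best_subset(6)["index"] < 20
        assert rep.max_identifiable_size >= 6
        partner, gamma = choose_fixed_pair(S)
        assert gamma < 20
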