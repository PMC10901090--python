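"""Mass-isotopologue distributions and natural ¹³C-abundance correction.

A mass-isotopologue distribution (MID) is the vector of fractional abundances
m0..m+n of a metabolite fragment with n carbons.  Raw GC-MS distributions mix
tracer-derived label with naturally occurring ¹³C (≈1.07% of carbon); the
correction removes the natural component by inverting a convolution matrix,
yielding the excess fractional distribution M⁰..M⁺ⁿ that reflects tracer
label only.  The correction considers ¹³C on carbon atoms only; the abundance
model is pluggable so richer corrections (derivatization heteroatoms) can be
added without touching the inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import lsq_linear
from scipy.stats import binom

__all__ = [
    "MassIsotopologueDistribution",
    "NaturalAbundanceModel",
    "build_correction_matrix",
    "correct_natural_abundance",
    "total_enrichment",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class NaturalAbundanceModel:
    """Natural ¹³C abundance used to build the correction matrix.

    p13C defaults to 0.0107, the terrestrial fractional abundance of ¹³C.
    """

    p13C: float = 0.0107

    def __post_init__(self) -> None:
        if not 0.0 <= self.p13C < 1.0:
            raise ValueError(f"p13C must be in [0, 1), got {self.p13C}")


@dataclass
class MassIsotopologueDistribution:
    """Fractional abundances m0..m+n of one metabolite fragment at one time.

    In raw form all entries are non-negative and sum to one.  In excess
    (natural-abundance-corrected) form the labeled entries M⁺¹..M⁺ⁿ are
    non-negative while M⁰ may be slightly negative from noise propagation.
    """

    metabolite: str
    n_carbons: int
    values: np.ndarray
    time_min: float = 0.0
    subject: str = "average"
    is_excess: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_carbons < 1:
            raise ValueError("n_carbons must be >= 1")
        if self.values.shape != (self.n_carbons + 1,):
            raise ValueError(
                f"expected {self.n_carbons + 1} isotopologue values, got {self.values.shape}"
            )
        if not self.is_excess:
            if np.any(self.values < -_SUM_TOL):
                raise ValueError("raw MID values must be >= 0")
            total = self.values.sum()
            if total <= 0:
                raise ValueError("raw MID must have positive total abundance")
            if abs(total - 1.0) > _SUM_TOL:
                self.values = self.values / total
        else:
            if np.any(self.values[1:] < -1e-6):
                raise ValueError("excess MID labeled entries must be >= 0 (within tolerance)")

    def normalized(self) -> "MassIsotopologueDistribution":
        out = replace(self)
        out.values = self.values / self.values.sum()
        return out

    def __len__(self) -> int:
        return self.values.size


def build_correction_matrix(
    n_carbons: int, model: NaturalAbundanceModel | None = None
) -> np.ndarray:
    """Convolution matrix mapping excess MIDs to observed raw MIDs.

    Entry (i, j) is the probability that a molecule carrying j tracer-labeled
    carbons is observed at nominal mass shift i, i.e. the binomial probability
    of i − j natural ¹³C among the remaining n − j carbons.  Columns sum to 1
    exactly (no mass shift beyond n is possible for a fragment of n carbons);
    entries with i < j are zero because label cannot reduce the mass shift.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    model = model or NaturalAbundanceModel()
    n = n_carbons
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        shifts = np.arange(0, n - j + 1)
        M[j : n + 1, j] = binom.pmf(shifts, n - j, model.p13C)
    return M


def correct_natural_abundance(
    raw: MassIsotopologueDistribution, model: NaturalAbundanceModel | None = None
) -> MassIsotopologueDistribution:
    """Remove natural ¹³C abundance from a raw MID by regression.

    Solves (correction matrix)·x ≈ raw values by bounded least squares with
    non-negativity enforced on the labeled entries M⁺¹..M⁺ⁿ (M⁰ is left
    unconstrained so noise cannot bias the labeled fractions upward), then
    renormalizes to sum 1 and marks the result as excess form.
    """
    model = model or NaturalAbundanceModel()
    if raw.is_excess:
        raise ValueError("input is already in excess form")
    M = build_correction_matrix(raw.n_carbons, model)
    cond = np.linalg.cond(M)
    assert np.isfinite(cond), "correction matrix must be invertible for p13C < 1"
    n = raw.n_carbons
    # the matrix is square and invertible, so solve exactly first; fall back
    # to the bounded solver only when noise drives labeled entries negative
    x = np.linalg.solve(M, raw.values)
    if np.any(x[1:] < -1e-12):
        lb = np.full(n + 1, 0.0)
        lb[0] = -np.inf
        res = lsq_linear(
            M, raw.values, bounds=(lb, np.full(n + 1, np.inf)), tol=1e-14, lsmr_tol=1e-14
        )
        x = res.x
    x[1:] = np.clip(x[1:], 0.0, None)
    total = x.sum()
    if total > 0:
        x = x / total
    out = replace(raw)
    out.values = x
    out.is_excess = True
    return out


def total_enrichment(dist: MassIsotopologueDistribution) -> float:
    """Atom-fraction ¹³C (excess) of the fragment: Σ m·values[m] / n_carbons."""
    m = np.arange(dist.n_carbons + 1)
    return float(np.dot(dist.values, m) / dist.n_carbons)
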