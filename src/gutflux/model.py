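"""Three-compartment model of intraintestinal ¹³C-SCFA incorporation into plasma glucose.

The model tracks three independent label chains, one per delivered short-chain
fatty acid (SCFA), from the gut lumen into plasma glucose:

* acetate:    A_gut → A_liver → G_a   (uptake k1a, hepatic conversion kLa)
* propionate: P_gut → G_p             (lumped uptake+conversion k1p)
* butyrate:   B_gut → G_b             (lumped uptake+conversion k1b)

Each gut pool additionally loses tracer at a first-order rate (k0a, k0p, k0b:
oxidation, excretion, incorporation into other metabolites), and all three
plasma ¹³C-glucose pools are cleared with a single constant k2.  Gut and liver
pools are expressed in mmol; plasma pools in mM ¹³C-glucose equivalents, the
two linked by the plasma volume V_plasma = 0.15 L per kg body weight.

All transfer constants are *apparent* first-order rate constants in min⁻¹:
lumped descriptions of transport plus metabolism, not single enzymatic steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PARAM_NAMES",
    "SOURCES",
    "STATE_NAMES",
    "RateConstants",
    "TracerDose",
    "SubjectProfile",
    "EnrichmentCurve",
    "SimulationResult",
    "system_matrix",
    "ode_rhs",
    "simulate",
]

#: canonical parameter ordering used by fitting and identifiability code
PARAM_NAMES: tuple[str, ...] = ("k1a", "k1p", "k1b", "kLa", "k2", "k0a", "k0p", "k0b")

#: the three tracer sources, in delivery order
SOURCES: tuple[str, ...] = ("acetate", "propionate", "butyrate")

#: state vector layout: gut/liver pools in mmol, plasma glucose pools in mM
STATE_NAMES: tuple[str, ...] = ("A_gut", "A_liver", "G_a", "P_gut", "G_p", "B_gut", "G_b")

_PLASMA_L_PER_KG = 0.15


@dataclass(frozen=True)
class RateConstants:
    """The eight apparent first-order rate constants of the model (min⁻¹)."""

    k1a: float
    k1p: float
    k1b: float
    kLa: float
    k2: float
    k0a: float
    k0p: float
    k0b: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "RateConstants":
        values = np.asarray(values, dtype=float)
        if values.shape != (8,):
            raise ValueError(f"expected 8 rate constants, got shape {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    def replace(self, **updates: float) -> "RateConstants":
        return replace(self, **updates)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


@dataclass(frozen=True)
class TracerDose:
    """Delivered ¹³C-SCFA amounts (mmol) defining the gut initial conditions."""

    A0: float = 9.6
    P0: float = 4.0
    B0: float = 0.9
    delivery_time_min: float = 0.0

    def __post_init__(self) -> None:
        for name in ("A0", "P0", "B0"):
            if getattr(self, name) < 0:
                raise ValueError(f"dose {name} must be >= 0")

    @classmethod
    def from_infusion(
        cls,
        concentrations_M: Sequence[float] = (0.96, 0.40, 0.09),
        volume_mL: float = 10.0,
        delivery_time_min: float = 0.0,
    ) -> "TracerDose":
        """Dose from the infusate composition: mmol = molarity (M) × volume (mL)."""
        a, p, b = (float(c) * float(volume_mL) for c in concentrations_M)
        return cls(A0=a, P0=p, B0=b, delivery_time_min=delivery_time_min)

    def amount(self, source: str) -> float:
        return {"acetate": self.A0, "propionate": self.P0, "butyrate": self.B0}[source]

    def to_dict(self) -> dict[str, float]:
        return {
            "A0": self.A0,
            "P0": self.P0,
            "B0": self.B0,
            "delivery_time_min": self.delivery_time_min,
        }


@dataclass(frozen=True)
class SubjectProfile:
    """Subject metadata fixing the plasma compartment volume.

    V_plasma defaults to 0.15 L per kg body weight and can be overridden.
    """

    subject: str = "average"
    body_weight_kg: float = 75.0
    v_plasma_L: float | None = None

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be > 0")
        if self.v_plasma_L is None:
            object.__setattr__(self, "v_plasma_L", _PLASMA_L_PER_KG * self.body_weight_kg)
        if self.v_plasma_L <= 0:
            raise ValueError("v_plasma_L must be > 0")


@dataclass
class EnrichmentCurve:
    """Time course of one plasma ¹³C-glucose pool (mM labeled-glucose
    equivalents attributed to one source SCFA)."""

    times_min: np.ndarray
    values: np.ndarray
    source: str
    sd: np.ndarray | None = None
    subject: str = "average"

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.times_min.ndim != 1 or self.times_min.shape != self.values.shape:
            raise ValueError("times_min and values must be 1-D and of equal length")
        if self.times_min.size and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.values.shape:
                raise ValueError("sd must match values in length")
            if np.any(self.sd <= 0):
                raise ValueError("sd must be > 0 where present")

    def __len__(self) -> int:
        return self.times_min.size


def system_matrix(k: RateConstants, v_plasma_L: float) -> np.ndarray:
    """Constant coefficient matrix A of the linear system dx/dt = A·x.

    State order follows :data:`STATE_NAMES`; the 1/V factor converts hepatic
    mmol/min fluxes to plasma mM/min.
    """
    if v_plasma_L <= 0:
        raise ValueError("v_plasma_L must be > 0")
    V = v_plasma_L
    A = np.zeros((7, 7))
    # acetate chain: gut -> liver -> plasma glucose
    A[0, 0] = -(k.k1a + k.k0a)
    A[1, 0] = k.k1a
    A[1, 1] = -k.kLa
    A[2, 1] = k.kLa / V
    A[2, 2] = -k.k2
    # propionate: gut -> plasma glucose
    A[3, 3] = -(k.k1p + k.k0p)
    A[4, 3] = k.k1p / V
    A[4, 4] = -k.k2
    # butyrate: gut -> plasma glucose
    A[5, 5] = -(k.k1b + k.k0b)
    A[6, 5] = k.k1b / V
    A[6, 6] = -k.k2
    return A


def ode_rhs(state: Sequence[float], k: RateConstants, subject: SubjectProfile) -> np.ndarray:
    """Right-hand side of the model ODEs for one state vector."""
    x = np.asarray(state, dtype=float)
    if x.shape != (7,):
        raise ValueError(f"state must have 7 entries ({STATE_NAMES}), got shape {x.shape}")
    return system_matrix(k, subject.v_plasma_L) @ x


def initial_state(dose: TracerDose) -> np.ndarray:
    """Initial condition: all tracer in the gut, liver and plasma empty."""
    return np.array([dose.A0, 0.0, 0.0, dose.P0, 0.0, dose.B0, 0.0])


@dataclass
class SimulationResult:
    """Full model trajectory plus per-source plasma glucose curves."""

    times_min: np.ndarray
    states: np.ndarray  # (n_times, 7), columns per STATE_NAMES
    subject: SubjectProfile
    k: RateConstants
    dose: TracerDose

    def curve(self, source: str) -> EnrichmentCurve:
        col = {"acetate": 2, "propionate": 4, "butyrate": 6}[source]
        return EnrichmentCurve(
            times_min=self.times_min,
            values=self.states[:, col],
            source=source,
            subject=self.subject.subject,
        )

    def curves(self) -> dict[str, EnrichmentCurve]:
        return {s: self.curve(s) for s in SOURCES}

    def state_at_end(self) -> dict[str, float]:
        return dict(zip(STATE_NAMES, self.states[-1]))


def simulate(
    k: RateConstants,
    dose: TracerDose,
    subject: SubjectProfile,
    times: Iterable[float],
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SimulationResult:
    """Integrate the model and return the trajectory at the requested times.

    Times are minutes since tracer delivery, must be >= 0 and increasing.
    Uses a stiff-capable integrator (LSODA) with the exact constant Jacobian;
    defaults rtol=1e-8 / atol=1e-12 because the rate constants span more than
    two orders of magnitude.
    """
    t = np.asarray(list(times) if not isinstance(times, np.ndarray) else times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(t < 0):
        raise ValueError("times must be >= 0 (minutes since tracer delivery)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    A = system_matrix(k, subject.v_plasma_L)
    y0 = initial_state(dose)
    t0 = 0.0
    sol = solve_ivp(
        lambda _t, y: A @ y,
        (t0, float(t[-1]) if t[-1] > t0 else t0 + 1e-9),
        y0,
        t_eval=t,
        method="LSODA",
        jac=lambda _t, _y: A,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    states = sol.y.T
    # clip integrator-level negative round-off; the exact solution is >= 0
    states[(states < 0) & (states > -10 * atol)] = 0.0
    return SimulationResult(times_min=t, states=states, subject=subject, k=k, dose=dose)
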