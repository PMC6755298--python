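"""Right-hand side of the six-compartment chemoradiotherapy model.

State ordering is ``(T, TR, N, I, M, R)``: tumor-sensitive cells,
tumor-resistant cells, normal cells, immune cells, chemotherapy concentration
(mg) and radiotherapy concentration (mg).  Cell compartments grow
logistically; drug action follows exponential-saturation (fractional-cell-
kill) kinetics, ``a * (1 - exp(-delta * C))``, so the per-capita kill rate
saturates at the kill coefficient as concentration grows.  Drug
concentrations obey a single well-mixed compartment with constant or
piecewise-constant infusion and first-order decay.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .params import ModelParams

__all__ = [
    "IDX",
    "COMPARTMENTS",
    "DoseSchedule",
    "kill_fraction",
    "rhs",
    "rhs_terms",
    "drug_concentration_closed_form",
]

COMPARTMENTS: tuple[str, ...] = ("T", "TR", "N", "I", "M", "R")
IDX: dict[str, int] = {name: i for i, name in enumerate(COMPARTMENTS)}


def kill_fraction(c: float | np.ndarray, delta: float) -> float | np.ndarray:
    """Saturating fraction ``1 - exp(-delta*c)`` of the maximal drug kill rate.

    Strictly increasing in the concentration ``c``, zero at ``c = 0`` and
    approaching one as ``c`` grows — the exponential-saturation kinetics of
    fractional cell kill.
    """
    c = np.asarray(c, dtype=float)
    if delta <= 0:
        raise ValueError(f"saturation exponent delta must be > 0, got {delta}")
    if np.any(c < 0):
        raise ValueError("drug concentration must be nonnegative")
    out = -np.expm1(-delta * c)
    return float(out) if out.ndim == 0 else out


class _PiecewiseConstant:
    """Right-continuous piecewise-constant function of time."""

    def __init__(self, breakpoints: Sequence[float], values: Sequence[float]):
        self.breakpoints = np.asarray(breakpoints, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.breakpoints.ndim != 1 or self.values.ndim != 1:
            raise ValueError("breakpoints and values must be 1-d")
        if len(self.values) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one more value than breakpoints")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("infusion rates must be nonnegative")

    def __call__(self, t: float) -> float:
        # side="right" makes the function right-continuous at breakpoints
        return float(self.values[np.searchsorted(self.breakpoints, t, side="right")])


@dataclasses.dataclass(frozen=True)
class DoseSchedule:
    """Piecewise-constant infusion rates (mg/day) for both therapies."""

    VM_of_t: _PiecewiseConstant
    VR_of_t: _PiecewiseConstant

    @classmethod
    def constant(cls, VM: float, VR: float) -> "DoseSchedule":
        return cls(_PiecewiseConstant([], [VM]), _PiecewiseConstant([], [VR]))

    @classmethod
    def piecewise(
        cls,
        breakpoints: Sequence[float],
        VM_values: Sequence[float],
        VR_values: Sequence[float],
    ) -> "DoseSchedule":
        return cls(
            _PiecewiseConstant(breakpoints, VM_values),
            _PiecewiseConstant(breakpoints, VR_values),
        )

    @classmethod
    def from_params(cls, p: ModelParams) -> "DoseSchedule":
        return cls.constant(p.VM, p.VR)

    @property
    def breakpoints(self) -> np.ndarray:
        return np.union1d(self.VM_of_t.breakpoints, self.VR_of_t.breakpoints)


def rhs_terms(
    t: float, x: np.ndarray, p: ModelParams, sched: DoseSchedule | None = None
) -> dict[str, dict[str, float]]:
    """Every named term of the model equations, evaluated separately.

    The state is clipped at zero component-wise before evaluation (adaptive
    steppers may overshoot into slightly negative values; the vector field
    itself never drives a compartment below zero).  Returns a nested dict
    ``{compartment: {term name: rate}}`` whose per-compartment sums are the
    model derivatives.
    """
    if sched is None:
        sched = DoseSchedule.from_params(p)
    T, TR, N, I, M, R = np.clip(np.asarray(x, dtype=float), 0.0, None)
    sM = kill_fraction(M, p.delta1)
    sR = kill_fraction(R, p.delta2)
    return {
        "T": {
            "logistic_growth": p.r1 * T * (1.0 - T / p.Tmax),
            "immune_kill": -p.alpha1 * I * T,
            "mutation_loss": -p.mu * T,
            "chemo_kill": -p.aT * sM * T,
            "radio_kill": -p.bT * sR * T,
        },
        "TR": {
            "logistic_growth": p.r2 * TR * (1.0 - TR / p.Tmax),
            "mutation_gain": p.mu * T,
            "chemo_kill": -p.aTR * sM * TR,
            "radio_kill": -p.bTR * sR * TR,
        },
        "N": {
            "logistic_growth": p.r3 * N * (1.0 - N / p.Nmax),
            "tumor_activation": p.k * T * (1.0 - T / p.Tstar),
            "chemo_toxicity": -p.aN * sM * N,
            "radio_toxicity": -p.bN * sR * N,
        },
        "I": {
            "source": p.s,
            "tumor_stimulation": p.eps1 * I * T / (p.eps2 + T),
            "natural_death": -p.d * I,
            "exhaustion": -p.alpha2 * I * T,
            "chemo_toxicity": -p.aI * sM * I,
            "radio_toxicity": -p.bI * sR * I,
        },
        "M": {"infusion": sched.VM_of_t(t), "decay": -p.d1 * M},
        "R": {"infusion": sched.VR_of_t(t), "decay": -p.d2 * R},
    }


def rhs(
    t: float, x: np.ndarray, p: ModelParams, sched: DoseSchedule | None = None
) -> np.ndarray:
    """Time derivative of the six-compartment state at time ``t`` (days)."""
    if sched is None:
        sched = DoseSchedule.from_params(p)
    T, TR, N, I, M, R = np.clip(np.asarray(x, dtype=float), 0.0, None)
    sM = kill_fraction(M, p.delta1)
    sR = kill_fraction(R, p.delta2)
    dT = T * (p.r1 * (1.0 - T / p.Tmax) - p.alpha1 * I - p.mu - p.aT * sM - p.bT * sR)
    dTR = TR * (p.r2 * (1.0 - TR / p.Tmax) - p.aTR * sM - p.bTR * sR) + p.mu * T
    dN = N * (p.r3 * (1.0 - N / p.Nmax) - p.aN * sM - p.bN * sR) + p.k * T * (
        1.0 - T / p.Tstar
    )
    dI = p.s + I * (
        p.eps1 * T / (p.eps2 + T) - p.d - p.alpha2 * T - p.aI * sM - p.bI * sR
    )
    dM = sched.VM_of_t(t) - p.d1 * M
    dR = sched.VR_of_t(t) - p.d2 * R
    return np.array([dT, dTR, dN, dI, dM, dR])


def drug_concentration_closed_form(
    t: float | np.ndarray, V: float, dk: float, c0: float = 0.0
) -> float | np.ndarray:
    """Concentration under constant infusion ``V`` and first-order decay ``dk``.

    ``c(t) = V/dk + (c0 - V/dk) * exp(-dk*t)``, approaching the steady state
    ``V/dk`` as t grows.
    """
    if dk <= 0:
        raise ValueError(f"decay rate must be > 0, got {dk}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    css = V / dk
    out = css + (c0 - css) * np.exp(-dk * t)
    return float(out) if out.ndim == 0 else out
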