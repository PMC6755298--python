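"""Steady states and local stability of the chemoradiotherapy model.

Two biologically meaningful equilibria are analyzed under constant infusion:

* the *tumor-free* state, ``T = TR = 0`` with normal and immune cells at
  closed-form positive levels and drugs at their steady concentrations
  ``V/d``; and
* the *coexistence* (endemic) state, where both tumor compartments persist
  at positive levels, found by root finding on the ``(T, TR, I)`` subsystem
  (which decouples from N) followed by the scalar quadratic for N.

Stability is classified numerically from the eigenvalues of the full 6x6
analytic Jacobian; the simplified immune-threshold inequality used in the
original analysis is evaluated alongside for comparison.

A note on boundary states: cell counts are constrained to be nonnegative, so
an equilibrium may sit on the boundary of the positive orthant (a compartment
at exactly zero whose raw inflow is negative).  Residuals are therefore
measured on the *projected* vector field — a component pinned at zero with
negative raw derivative contributes no residual, because the constrained
dynamics cannot leave the boundary there.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import scipy.optimize

from .dynamics import COMPARTMENTS, DoseSchedule, kill_fraction, rhs
from .params import ModelParams

__all__ = [
    "Equilibrium",
    "NoEquilibriumError",
    "tumor_free_equilibrium",
    "coexistence_equilibrium",
    "find_coexistence_equilibria",
    "jacobian",
    "threshold_condition",
    "classify_stability",
]

#: A tumor compartment below this absolute level (cells) counts as extinct
#: when classifying the kind of an equilibrium.
_EXTINCT_TOL = 1.0

_STABILITY_TOL = 1e-9


class NoEquilibriumError(RuntimeError):
    """No steady state of the requested kind exists for these parameters."""


@dataclasses.dataclass
class Equilibrium:
    """A steady state with its stability diagnosis.

    ``residual`` is the max-norm of the projected vector field at ``state``
    (see module docstring); ``raw_residual`` ignores the nonnegativity
    projection.  ``boundary_defect`` names compartments pinned at zero whose
    raw derivative is negative — for those the unconstrained equations have
    no nonnegative root and the constrained dynamics rest on the boundary.
    """

    state: np.ndarray
    kind: str  # "tumor-free" | "coexistence" | "other"
    residual: float
    raw_residual: float
    eigenvalues: np.ndarray
    stable: bool
    verdict: str  # "stable" | "unstable" | "marginal"
    threshold: dict
    boundary_defect: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "state": {c: float(v) for c, v in zip(COMPARTMENTS, self.state)},
            "residual": float(self.residual),
            "raw_residual": float(self.raw_residual),
            "eigenvalues": [
                {"re": float(ev.real), "im": float(ev.imag)}
                for ev in self.eigenvalues
            ],
            "stable": bool(self.stable),
            "verdict": self.verdict,
            "threshold_condition": self.threshold,
            "boundary_defect": list(self.boundary_defect),
            "notes": list(self.notes),
        }


def _projected_rhs(x: np.ndarray, p: ModelParams, sched: DoseSchedule) -> np.ndarray:
    """Vector field with outflow suppressed on boundary components at zero."""
    f = rhs(0.0, x, p, sched)
    pinned = (np.asarray(x) <= 0.0) & (f < 0.0)
    return np.where(pinned, 0.0, f)


def jacobian(x: np.ndarray, p: ModelParams) -> np.ndarray:
    """Analytic 6x6 Jacobian of the model vector field at state ``x``."""
    T, TR, N, I, M, R = np.clip(np.asarray(x, dtype=float), 0.0, None)
    sM = kill_fraction(M, p.delta1)
    sR = kill_fraction(R, p.delta2)
    dsM = p.delta1 * np.exp(-p.delta1 * M)  # d(sM)/dM
    dsR = p.delta2 * np.exp(-p.delta2 * R)
    J = np.zeros((6, 6))
    # dT/dt row
    J[0, 0] = p.r1 * (1 - 2 * T / p.Tmax) - p.alpha1 * I - p.mu - p.aT * sM - p.bT * sR
    J[0, 3] = -p.alpha1 * T
    J[0, 4] = -p.aT * dsM * T
    J[0, 5] = -p.bT * dsR * T
    # dTR/dt row
    J[1, 0] = p.mu
    J[1, 1] = p.r2 * (1 - 2 * TR / p.Tmax) - p.aTR * sM - p.bTR * sR
    J[1, 4] = -p.aTR * dsM * TR
    J[1, 5] = -p.bTR * dsR * TR
    # dN/dt row
    J[2, 0] = p.k * (1 - 2 * T / p.Tstar)
    J[2, 2] = p.r3 * (1 - 2 * N / p.Nmax) - p.aN * sM - p.bN * sR
    J[2, 4] = -p.aN * dsM * N
    J[2, 5] = -p.bN * dsR * N
    # dI/dt row
    J[3, 0] = p.eps1 * I * p.eps2 / (p.eps2 + T) ** 2 - p.alpha2 * I
    J[3, 3] = p.eps1 * T / (p.eps2 + T) - p.d - p.alpha2 * T - p.aI * sM - p.bI * sR
    J[3, 4] = -p.aI * dsM * I
    J[3, 5] = -p.bI * dsR * I
    # drug rows are linear
    J[4, 4] = -p.d1
    J[5, 5] = -p.d2
    return J


def classify_stability(eigenvalues: np.ndarray) -> str:
    """Local verdict from Jacobian eigenvalues: stable/unstable/marginal."""
    max_re = float(np.max(np.real(eigenvalues)))
    if max_re < -_STABILITY_TOL:
        return "stable"
    if max_re > _STABILITY_TOL:
        return "unstable"
    return "marginal"


def threshold_condition(kind: str, I_eq: float, p: ModelParams, M: float, R: float) -> dict:
    """The simplified immune-threshold inequality of the original analysis.

    Tumor-free state: stable when the equilibrium immune level exceeds
    ``r1/alpha1``.  Coexistence: the tumor-free state loses stability when
    the immune level falls below ``(r1 - aT(1-e^-M) - bT(1-e^-R))/alpha1``.
    The inequality omits the mutation loss term, so the eigenvalue
    classification is authoritative; this report is for comparison.
    """
    if p.alpha1 == 0:
        return {"kind": kind, "lhs": I_eq, "rhs": np.inf, "satisfied": False}
    if kind == "tumor-free":
        rhs_value = p.r1 / p.alpha1
        satisfied = I_eq > rhs_value
    else:
        rhs_value = (
            p.r1
            - p.aT * kill_fraction(M, p.delta1)
            - p.bT * kill_fraction(R, p.delta2)
        ) / p.alpha1
        satisfied = I_eq < rhs_value
    return {
        "kind": kind,
        "lhs": float(I_eq),
        "rhs": float(rhs_value),
        "satisfied": bool(satisfied),
    }


def _finalize(
    state: np.ndarray, kind: str, p: ModelParams, notes: tuple[str, ...] = ()
) -> Equilibrium:
    sched = DoseSchedule.from_params(p)
    f_raw = rhs(0.0, state, p, sched)
    f_proj = _projected_rhs(state, p, sched)
    pinned = tuple(
        c
        for c, xv, fv in zip(COMPARTMENTS, state, f_raw)
        if xv <= 0.0 and fv < 0.0
    )
    eig = np.linalg.eigvals(jacobian(state, p))
    verdict = classify_stability(eig)
    thr = threshold_condition(
        "tumor-free" if kind == "tumor-free" else "coexistence",
        float(state[3]),
        p,
        float(state[4]),
        float(state[5]),
    )
    return Equilibrium(
        state=state,
        kind=kind,
        residual=float(np.max(np.abs(f_proj))),
        raw_residual=float(np.max(np.abs(f_raw))),
        eigenvalues=eig,
        stable=verdict == "stable",
        verdict=verdict,
        threshold=thr,
        boundary_defect=pinned,
        notes=notes,
    )


def tumor_free_equilibrium(p: ModelParams) -> Equilibrium:
    """Closed-form steady state with both tumor compartments extinct.

    Drugs equilibrate at ``V/d``; with the resulting saturated kill fractions
    ``sM, sR`` the positive normal-cell branch is
    ``N = Nmax (1 - (aN sM + bN sR)/r3)`` and the immune level is
    ``I = s / (d + aI sM + bI sR)``.  If the toxicity load exceeds the
    normal-cell growth rate there is no positive normal branch and the
    ``N = 0`` boundary state is returned, flagged "other".
    """
    M = p.VM / p.d1
    R = p.VR / p.d2
    sM = kill_fraction(M, p.delta1)
    sR = kill_fraction(R, p.delta2)
    I_eq = p.s / (p.d + p.aI * sM + p.bI * sR)
    toxicity = p.aN * sM + p.bN * sR
    notes: tuple[str, ...] = ()
    if p.r3 > toxicity:
        N_eq = p.Nmax * (1.0 - toxicity / p.r3)
        kind = "tumor-free"
    else:
        N_eq = 0.0
        kind = "other"
        notes = (
            "drug toxicity exceeds normal-cell growth rate; no positive "
            "normal-cell branch, N pinned at 0",
        )
    state = np.array([0.0, 0.0, N_eq, I_eq, M, R])
    return _finalize(state, kind, p, notes)


def _reduced_residuals(u: np.ndarray, p: ModelParams, sM: float, sR: float) -> np.ndarray:
    """Scaled steady-state equations of the (T, TR, I) subsystem.

    Variables are scaled by (Tmax, Tmax, s/d); residuals by the natural rate
    scale of each equation so the root finder sees O(1) quantities.
    """
    T = u[0] * p.Tmax
    TR = u[1] * p.Tmax
    I = u[2] * p.s / p.d
    fT = T * (p.r1 * (1 - T / p.Tmax) - p.alpha1 * I - p.mu - p.aT * sM - p.bT * sR)
    fTR = TR * (p.r2 * (1 - TR / p.Tmax) - p.aTR * sM - p.bTR * sR) + p.mu * T
    fI = p.s + I * (
        p.eps1 * T / (p.eps2 + T) - p.d - p.alpha2 * T - p.aI * sM - p.bI * sR
    )
    return np.array([fT / (p.r1 * p.Tmax), fTR / (p.r2 * p.Tmax), fI / p.s])


def _solve_N(p: ModelParams, T: float, sM: float, sR: float) -> tuple[float | None, list[float]]:
    """Positive roots of the scalar steady-state equation for N given T.

    ``-(r3/Nmax) N^2 + (r3 - aN sM - bN sR) N + k T (1 - T/Tstar) = 0``.
    Returns (largest positive root or None, all nonnegative roots).
    """
    a = -p.r3 / p.Nmax
    b = p.r3 - p.aN * sM - p.bN * sR
    c = p.k * T * (1.0 - T / p.Tstar)
    roots = np.roots([a, b, c])
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-9 * max(1.0, abs(r))]
    nonneg = sorted(r for r in real if r >= 0.0)
    if c == 0.0 and b > 0:
        # N=0 is always a root when the tumor-activation term vanishes;
        # prefer the positive branch Nmax*(1 - toxicity/r3)
        nonneg = [r for r in nonneg if r > 0.0] or [0.0]
    positive = [r for r in nonneg if r > 0.0]
    return (max(positive) if positive else None), nonneg


def find_coexistence_equilibria(p: ModelParams) -> list[Equilibrium]:
    """All steady states with a positive tumor burden, sorted by T descending.

    The drug equations are autonomous, so ``M = VM/d1`` and ``R = VR/d2``
    analytically.  The ``(T, TR, I)`` subsystem — independent of N — is
    solved by a damped Newton/hybrid root finder multi-started from a 3x3x3
    grid over ``(0, Tmax] x (0, Tmax] x (0, s/d]``; the scalar quadratic for
    N is then solved analytically, keeping only nonnegative roots.  When the
    N equation has no nonnegative root (strong tumor inhibition of normal
    cells), the state is returned with N pinned at 0 and flagged.
    """
    if p.d1 <= 0 or p.d2 <= 0:
        raise ValueError("drug decay rates must be positive to equilibrate drugs")
    M = p.VM / p.d1
    R = p.VR / p.d2
    sM = kill_fraction(M, p.delta1)
    sR = kill_fraction(R, p.delta2)

    found: list[np.ndarray] = []
    fractions = (0.05, 0.4, 0.9)
    for u0 in itertools.product(fractions, fractions, fractions):
        sol = scipy.optimize.root(
            _reduced_residuals, np.array(u0), args=(p, sM, sR), method="hybr",
            options={"xtol": 1e-12},
        )
        if not sol.success:
            continue
        T, TR, I = sol.x[0] * p.Tmax, sol.x[1] * p.Tmax, sol.x[2] * p.s / p.d
        if T < _EXTINCT_TOL or TR < 0 or I <= 0:
            continue
        if np.max(np.abs(_reduced_residuals(sol.x, p, sM, sR))) > 1e-9:
            continue
        cand = np.array([T, TR, I])
        if any(np.allclose(cand, prev, rtol=1e-6) for prev in found):
            continue
        found.append(cand)

    out: list[Equilibrium] = []
    for T, TR, I in sorted(found, key=lambda v: -v[0]):
        N_eq, _ = _solve_N(p, T, sM, sR)
        notes: tuple[str, ...] = ()
        if N_eq is None:
            N_eq = 0.0
            notes = (
                "N equation has no nonnegative root at this tumor burden "
                "(tumor-activation term strongly negative for T >> Tstar); "
                "N pinned at the 0 boundary of the constrained dynamics",
            )
        kind = "coexistence" if TR >= _EXTINCT_TOL else "other"
        state = np.array([T, TR, N_eq, I, M, R])
        out.append(_finalize(state, kind, p, notes))
    return out


def coexistence_equilibrium(
    p: ModelParams, guess: np.ndarray | None = None
) -> Equilibrium:
    """The coexistence steady state with the largest tumor burden.

    ``guess`` (a six-component state) adds one extra start to the multi-start
    grid.  Raises :class:`NoEquilibriumError` when no positive-tumor root is
    found.
    """
    eqs = find_coexistence_equilibria(p)
    if guess is not None:
        M = p.VM / p.d1
        R = p.VR / p.d2
        sM = kill_fraction(M, p.delta1)
        sR = kill_fraction(R, p.delta2)
        u0 = np.array(
            [guess[0] / p.Tmax, guess[1] / p.Tmax, guess[3] * p.d / p.s]
        )
        sol = scipy.optimize.root(
            _reduced_residuals, u0, args=(p, sM, sR), method="hybr"
        )
        if sol.success:
            T, TR, I = sol.x[0] * p.Tmax, sol.x[1] * p.Tmax, sol.x[2] * p.s / p.d
            if T >= _EXTINCT_TOL and TR >= 0 and I > 0:
                N_eq, _ = _solve_N(p, T, sM, sR)
                state = np.array([T, TR, N_eq if N_eq is not None else 0.0, I, M, R])
                if not any(
                    np.allclose(state[:2], e.state[:2], rtol=1e-6) for e in eqs
                ):
                    eqs.append(_finalize(state, "coexistence", p))
                    eqs.sort(key=lambda e: -e.state[0])
    if not eqs:
        raise NoEquilibriumError(
            "no positive-tumor steady state found within the state bounds"
        )
    return eqs[0]
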