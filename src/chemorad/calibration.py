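"""Least-squares calibration of the model to tumor-size observations.

Observations are (time in days, tumor diameter in cm) pairs.  Diameters are
converted to total cell counts under a spherical-tumor convention with a
fixed packing density; the loss is the sum of squared differences between
the model's total tumor burden T + TR and the observed counts at the
observation times, minimized over a chosen free-parameter subset within the
published ranges by bounded nonlinear least squares with Latin-hypercube
multi-start.

The default packing density is pinned by the study's own initial condition
(4.9e6 total tumor cells at 2.147 cm diameter, giving ~9.455e5 cells/cm^3)
rather than the ~1e9 cells/cm^3 of the histology literature: only the former
is consistent with the printed initial conditions and diameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .params import RANGES, ModelParams, make_params
from .treatment import simulate

__all__ = [
    "DEFAULT_CELLS_PER_CM3",
    "DEFAULT_FREE",
    "Observation",
    "SizeCalibration",
    "FitResult",
    "cells_to_diameter",
    "diameter_to_cells",
    "fit",
    "predict",
    "read_observations",
    "write_observations",
]

#: Packing density consistent with 4.9e6 cells <-> 2.147 cm diameter.
DEFAULT_CELLS_PER_CM3: float = 4.9e6 / (np.pi / 6.0 * 2.147**3)

#: Default free parameters: the four treatment-efficacy (kill-rate)
#: coefficients of the tumor compartments, the constants the study itself
#: marks as estimated/assumed; everything else stays at its point value.
DEFAULT_FREE: tuple[str, ...] = ("aT", "bT", "aTR", "bTR")


@dataclasses.dataclass(frozen=True)
class Observation:
    """One tumor-size measurement."""

    time: float  # days since first measurement
    diameter: float  # cm

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("observation time must be >= 0")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")


@dataclasses.dataclass(frozen=True)
class SizeCalibration:
    """Spherical cells <-> diameter conversion at fixed packing density."""

    cells_per_cm3: float = DEFAULT_CELLS_PER_CM3
    geometry: str = "sphere"

    def __post_init__(self):
        if self.cells_per_cm3 <= 0:
            raise ValueError("cells_per_cm3 must be positive")
        if self.geometry != "sphere":
            raise ValueError("only spherical geometry is supported")


def cells_to_diameter(count: float | np.ndarray, cal: SizeCalibration | None = None):
    """Diameter (cm) of a sphere holding ``count`` cells."""
    if cal is None:
        cal = SizeCalibration()
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("cell count must be nonnegative")
    out = np.cbrt(6.0 * count / (np.pi * cal.cells_per_cm3))
    return float(out) if out.ndim == 0 else out


def diameter_to_cells(diameter: float | np.ndarray, cal: SizeCalibration | None = None):
    """Cell count of a sphere of the given diameter (cm); exact inverse."""
    if cal is None:
        cal = SizeCalibration()
    diameter = np.asarray(diameter, dtype=float)
    if np.any(diameter < 0):
        raise ValueError("diameter must be nonnegative")
    out = np.pi / 6.0 * diameter**3 * cal.cells_per_cm3
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class FitResult:
    """Outcome of a bounded least-squares calibration."""

    free: tuple[str, ...]
    fitted: dict[str, float]
    params: ModelParams  # full parameter set with fitted values applied
    x0: np.ndarray
    cal: SizeCalibration
    bounds: dict[str, tuple[float, float]]
    residuals: np.ndarray  # predicted - observed, cells (or cm)
    sse: float
    loss_units: str
    converged: bool
    n_model_evaluations: int
    n_starts: int
    seed: int
    bound_active: dict[str, bool]
    observations: tuple[Observation, ...]

    def as_dict(self) -> dict:
        return {
            "free": list(self.free),
            "fitted": self.fitted,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "sse": float(self.sse),
            "loss_units": self.loss_units,
            "residuals": [float(r) for r in self.residuals],
            "converged": bool(self.converged),
            "n_model_evaluations": int(self.n_model_evaluations),
            "n_starts": int(self.n_starts),
            "seed": int(self.seed),
            "bound_active": self.bound_active,
        }


def _predict_cells(
    p: ModelParams, x0: np.ndarray, times: np.ndarray, rtol: float
) -> np.ndarray:
    """Total tumor burden at the requested times (includes t=0 handling)."""
    horizon = float(times.max()) if times.max() > 0 else 1.0
    traj = simulate(p, x0=x0, horizon=horizon, rtol=rtol)
    return np.interp(times, traj.times, traj.total_tumor)


def fit(
    obs: Sequence[Observation],
    free: Sequence[str] = DEFAULT_FREE,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    p0: ModelParams | None = None,
    x0: np.ndarray | None = None,
    cal: SizeCalibration | None = None,
    seed: int = 0,
    n_starts: int = 8,
    loss_units: str = "cells",
    rtol: float = 1e-8,
) -> FitResult:
    """Bounded least-squares fit of ``free`` parameters to observations.

    Observations are converted to cell counts via ``cal`` (or compared in
    diameter units when ``loss_units="cm"``).  ``n_starts`` Latin-hypercube
    starting points are drawn over the bounds (plus the point-value start),
    each refined by a trust-region-reflective least-squares solve; the best
    run is returned.  Bit-reproducible for a fixed seed.
    """
    obs = tuple(obs)
    if len(obs) == 0:
        raise ValueError("need at least one observation")
    free = tuple(free)
    unknown = sorted(set(free) - set(RANGES))
    if unknown:
        raise KeyError(f"unknown free parameter(s): {', '.join(unknown)}")
    if p0 is None:
        p0 = make_params()
    if x0 is None:
        from .synthetic import tanzania_fixture

        x0 = tanzania_fixture().initial_state
    x0 = np.asarray(x0, dtype=float)
    if cal is None:
        cal = SizeCalibration()
    if loss_units not in ("cells", "cm"):
        raise ValueError("loss_units must be 'cells' or 'cm'")

    bounds = dict(bounds or {})
    resolved_bounds = {}
    for name in free:
        lo, hi = bounds.get(name, RANGES[name])
        if not lo < hi:
            raise ValueError(f"degenerate bounds for {name}: ({lo}, {hi})")
        resolved_bounds[name] = (float(lo), float(hi))

    times = np.array([o.time for o in obs], dtype=float)
    obs_cells = np.array([diameter_to_cells(o.diameter, cal) for o in obs])
    obs_diam = np.array([o.diameter for o in obs])

    evals = [0]

    def residual_fn(theta: np.ndarray) -> np.ndarray:
        evals[0] += 1
        p = p0.replace(**dict(zip(free, theta)))
        pred_cells = _predict_cells(p, x0, times, rtol)
        if loss_units == "cells":
            return pred_cells - obs_cells
        return cells_to_diameter(pred_cells, cal) - obs_diam

    if not free:
        res = residual_fn(np.array([]))
        return FitResult(
            free=free,
            fitted={},
            params=p0,
            x0=x0,
            cal=cal,
            bounds=resolved_bounds,
            residuals=res,
            sse=float(res @ res),
            loss_units=loss_units,
            converged=True,
            n_model_evaluations=evals[0],
            n_starts=0,
            seed=seed,
            bound_active={},
            observations=obs,
        )

    lo = np.array([resolved_bounds[n][0] for n in free])
    hi = np.array([resolved_bounds[n][1] for n in free])
    # starts: the point-value start (clipped into bounds) + LHS over bounds
    from .sensitivity import lhs_sample

    theta0 = np.clip([getattr(p0, n) for n in free], lo, hi)
    starts = [theta0]
    if n_starts > 2:
        lhs = lhs_sample({n: resolved_bounds[n] for n in free}, n_starts - 1, seed)
        starts.extend(lhs.values)
    elif n_starts == 2:
        starts.append(lo + np.random.default_rng(seed).uniform(size=len(free)) * (hi - lo))

    best = None
    for theta_start in starts:
        try:
            sol = scipy.optimize.least_squares(
                residual_fn,
                theta_start,
                bounds=(lo, hi),
                method="trf",
                x_scale=np.maximum(hi - lo, 1e-12),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        sse = float(sol.fun @ sol.fun)
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise RuntimeError("all optimization starts failed")
    sse, sol = best

    fitted = dict(zip(free, (float(v) for v in sol.x)))
    width = hi - lo
    bound_active = {
        n: bool(
            min(fitted[n] - resolved_bounds[n][0], resolved_bounds[n][1] - fitted[n])
            <= 1e-6 * width[i]
        )
        for i, n in enumerate(free)
    }
    return FitResult(
        free=free,
        fitted=fitted,
        params=p0.replace(**fitted),
        x0=x0,
        cal=cal,
        bounds=resolved_bounds,
        residuals=sol.fun,
        sse=sse,
        loss_units=loss_units,
        converged=bool(sol.success),
        n_model_evaluations=evals[0],
        n_starts=len(starts),
        seed=seed,
        bound_active=bound_active,
        observations=obs,
    )


def predict(fitres: FitResult, times: Sequence[float], rtol: float = 1e-8) -> pd.DataFrame:
    """Forward-simulate the fitted model and report both unit systems."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("prediction times must be nonnegative")
    cells = _predict_cells(fitres.params, fitres.x0, times, rtol)
    return pd.DataFrame(
        {
            "time_days": times,
            "total_tumor_cells": cells,
            "diameter_cm": cells_to_diameter(cells, fitres.cal),
        }
    )


def read_observations(path: str | Path) -> list[Observation]:
    """Read observations from CSV (time_days, diameter_cm) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return [Observation(float(o["time_days"]), float(o["diameter_cm"])) for o in data]
    df = pd.read_csv(path)
    missing = {"time_days", "diameter_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"observation file missing column(s): {sorted(missing)}")
    return [
        Observation(float(t), float(d))
        for t, d in zip(df["time_days"], df["diameter_cm"])
    ]


def write_observations(obs: Sequence[Observation], path: str | Path) -> None:
    pd.DataFrame(
        {"time_days": [o.time for o in obs], "diameter_cm": [o.diameter for o in obs]}
    ).to_csv(path, index=False)
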