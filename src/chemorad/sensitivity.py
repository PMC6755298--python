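"""Global sensitivity analysis: Latin hypercube sampling + PRCC.

Parameters are sampled uniformly and independently over their published
ranges by stratified Latin hypercube sampling; each sample row is run
through the model and a scalar output — by default the total tumor burden
T + TR at day 150, inside the eradication window the combination-therapy
runs exhibit — is recorded.  Partial rank correlation coefficients (PRCC)
then measure the monotone association between each parameter and the output
after removing the (rank-linear) influence of all other sampled parameters.

The default varied set is the seven most sensitive constants identified by
the study: the resistant-cell growth rate r2, the resistant-cell kill
coefficients aTR and bTR, the drug decay rates d1 and d2, and the infusion
rates VM and VR.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .dynamics import DoseSchedule
from .params import RANGES, ModelParams, make_params
from .treatment import DEFAULT_X0, IntegrationFailure, simulate

__all__ = [
    "FIG_PARAMS",
    "LHSSample",
    "SensitivityConfig",
    "PRCCResult",
    "lhs_sample",
    "evaluate_samples",
    "prcc",
    "run_sensitivity",
]

#: The seven parameters screened in the study's tornado analysis.
FIG_PARAMS: tuple[str, ...] = ("r2", "aTR", "bTR", "d1", "d2", "VM", "VR")

#: Extended set: every rate with a published range that the model is
#: plausibly monotone in (capacities and steepness constants excluded).
EXTENDED_PARAMS: tuple[str, ...] = FIG_PARAMS + (
    "r1", "mu", "aT", "bT", "r3", "aN", "bN", "s", "d", "aI", "bI",
)


@dataclasses.dataclass(frozen=True)
class LHSSample:
    """A Latin hypercube sample: parameter names and an (n, k) value matrix."""

    names: tuple[str, ...]
    values: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))


def lhs_sample(
    ranges: Mapping[str, tuple[float, float]], n: int, seed: int
) -> LHSSample:
    """Stratified uniform Latin hypercube over the given ranges.

    For each parameter the interval is cut into ``n`` equal-probability
    strata; exactly one point is drawn uniformly inside each stratum, and
    the strata are permuted independently per parameter.
    """
    if n < 2:
        raise ValueError("need n >= 2 LHS samples")
    names = tuple(ranges)
    k = len(names)
    if k == 0:
        raise ValueError("no parameters to sample")
    rng = np.random.default_rng(seed)
    values = np.empty((n, k))
    for j, name in enumerate(names):
        lo, hi = ranges[name]
        if not lo < hi:
            raise ValueError(f"degenerate range for {name!r}: ({lo}, {hi})")
        strata = (rng.permutation(n) + rng.uniform(size=n)) / n
        values[:, j] = lo + strata * (hi - lo)
    return LHSSample(names=names, values=values, seed=seed)


@dataclasses.dataclass(frozen=True)
class SensitivityConfig:
    """Configuration of one LHS/PRCC run."""

    ranges: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {name: RANGES[name] for name in FIG_PARAMS}
    )
    n: int = 100
    seed: int = 0
    output: str = "total_tumor"  # total_tumor | T | TR
    eval_day: float = 150.0
    x0: np.ndarray = dataclasses.field(default_factory=lambda: DEFAULT_X0.copy())
    base_params: ModelParams = dataclasses.field(default_factory=make_params)
    rtol: float = 1e-6

    def __post_init__(self):
        k = len(self.ranges)
        if self.n < k + 2:
            raise ValueError(f"n={self.n} too small for k={k} parameters (need n >= k+2)")
        if self.output not in ("total_tumor", "T", "TR"):
            raise ValueError(f"unknown output functional {self.output!r}")
        if self.eval_day <= 0:
            raise ValueError("eval_day must be positive")


@dataclasses.dataclass
class PRCCResult:
    """Per-parameter partial rank correlations with significance."""

    names: tuple[str, ...]
    prcc: np.ndarray
    pvalue: np.ndarray
    n: int
    n_missing: int
    seed: int | None
    output: str
    sample: LHSSample | None = None
    outputs: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-np.abs(self.prcc))
        df = pd.DataFrame(
            {
                "parameter": list(self.names),
                "prcc": self.prcc,
                "pvalue": self.pvalue,
            }
        )
        df["rank"] = np.empty(len(df), dtype=int)
        df.loc[order, "rank"] = np.arange(1, len(df) + 1)
        return df

    def as_dict(self) -> dict:
        return {
            "n": int(self.n),
            "n_missing": int(self.n_missing),
            "seed": self.seed,
            "output": self.output,
            "prcc": {
                name: {"prcc": float(r), "pvalue": float(pv)}
                for name, r, pv in zip(self.names, self.prcc, self.pvalue)
            },
        }


def evaluate_samples(sample: LHSSample, cfg: SensitivityConfig) -> np.ndarray:
    """Model output for every sample row; failed integrations become NaN.

    Unvaried parameters stay at their point values.  More than 10% failed
    rows aborts with diagnostics.
    """
    n = sample.values.shape[0]
    out = np.full(n, np.nan)
    failures: list[tuple[int, str]] = []
    base = cfg.base_params.to_dict()
    for i in range(n):
        overrides = dict(zip(sample.names, sample.values[i]))
        try:
            p = make_params({**base, **overrides})
            sched = DoseSchedule.constant(p.VM, p.VR)
            traj = simulate(
                p,
                x0=cfg.x0,
                horizon=cfg.eval_day,
                sched=sched,
                samples_per_day=2.0,
                rtol=cfg.rtol,
            )
            out[i] = float(traj.series(cfg.output)[-1])
        except (IntegrationFailure, ValueError) as exc:
            failures.append((i, str(exc)))
    if failures:
        warnings.warn(f"{len(failures)} of {n} model runs failed and are excluded")
    if len(failures) > 0.1 * n:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in failures[:5])
        raise RuntimeError(
            f"{len(failures)}/{n} sensitivity runs failed (> 10%): {detail}"
        )
    return out


def _rank(v: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(v, method="average")


def prcc(
    samples: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    seed: int | None = None,
    output: str = "",
) -> PRCCResult:
    """Partial rank correlation of each column of ``samples`` with ``y``.

    Every column and the output are rank-transformed (average ranks on
    ties).  For parameter j, the rank vectors of x_j and y are each
    regressed (with intercept) on all other rank-transformed parameters;
    the PRCC is the Pearson correlation of the two residual vectors.  The
    p-value comes from the t statistic ``r * sqrt(df / (1 - r^2))`` with
    ``df = n - 2 - (k - 1)`` degrees of freedom.  Rows with missing output
    (NaN) are excluded, with their count reported.
    """
    samples = np.asarray(samples, dtype=float)
    y = np.asarray(y, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be an (n, k) matrix")
    n_total, k = samples.shape
    if names is None:
        names = tuple(f"x{j+1}" for j in range(k))
    names = tuple(names)
    keep = np.isfinite(y) & np.all(np.isfinite(samples), axis=1)
    n_missing = int(n_total - keep.sum())
    samples, y = samples[keep], y[keep]
    n = len(y)
    if n <= k + 1:
        raise ValueError(f"n={n} usable rows too small for k={k} parameters")
    for j in range(k):
        if np.ptp(samples[:, j]) == 0:
            raise ValueError(f"constant parameter column {names[j]!r}")

    rx = np.column_stack([_rank(samples[:, j]) for j in range(k)])
    ry = _rank(y)
    df = n - 2 - (k - 1)
    values = np.empty(k)
    pvals = np.empty(k)
    for j in range(k):
        others = np.delete(rx, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        # residuals after projecting onto the other rank columns
        res_x = rx[:, j] - design @ np.linalg.lstsq(design, rx[:, j], rcond=None)[0]
        res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
        denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
        r = float(res_x @ res_y / denom) if denom > 0 else 0.0
        r = float(np.clip(r, -1.0, 1.0))
        values[j] = r
        if abs(r) >= 1.0:
            pvals[j] = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r**2))
            pvals[j] = 2.0 * scipy.stats.t.sf(abs(t), df)
    return PRCCResult(
        names=names,
        prcc=values,
        pvalue=pvals,
        n=n,
        n_missing=n_missing,
        seed=seed,
        output=output,
    )


def run_sensitivity(cfg: SensitivityConfig) -> PRCCResult:
    """Full pipeline: LHS sampling, model evaluation, PRCC."""
    sample = lhs_sample(cfg.ranges, cfg.n, cfg.seed)
    y = evaluate_samples(sample, cfg)
    result = prcc(sample.values, y, names=sample.names, seed=cfg.seed, output=cfg.output)
    result.sample = sample
    result.outputs = y
    return result
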