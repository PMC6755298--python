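"""Model parameterization for the tumor-immune chemoradiotherapy system.

The model tracks six compartments — tumor-sensitive cells (T), tumor-resistant
cells (TR), normal cells (N), immune/natural-killer cells (I), and the
concentrations of the chemotherapeutic (M) and radiotherapeutic (R) agents —
driven by 28 rate, capacity and dose constants.  :class:`ModelParams` carries
the published point values as defaults together with the published plausible
range of each constant, which downstream modules use as fitting bounds and
sensitivity-sampling ranges.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ModelParams",
    "PARAM_NAMES",
    "POINT_VALUES",
    "RANGES",
    "SCENARIOS",
    "make_params",
    "load_config",
    "save_config",
]

#: Published point values used for numerical simulation (units: day^-1 for
#: rates, cells for capacities, mg/day for infusion rates, mg^-1 for the
#: kill-saturation exponents delta1/delta2).
POINT_VALUES: dict[str, float] = {
    "r1": 0.431,        # growth rate, tumor-sensitive cells
    "Tmax": 5.5e7,      # tumor carrying capacity
    "alpha1": 1e-8,     # immune-induced tumor kill coefficient
    "mu": 0.001,        # mutation rate (sensitive -> resistant)
    "aT": 0.08,         # chemo kill coefficient, sensitive tumor
    "bT": 0.03,         # radio kill coefficient, sensitive tumor
    "r2": 0.25,         # growth rate, tumor-resistant cells
    "aTR": 0.08,        # chemo kill coefficient, resistant tumor
    "bTR": 0.03,        # radio kill coefficient, resistant tumor
    "r3": 0.65,         # growth rate, normal cells
    "Nmax": 3e7,        # normal-cell carrying capacity
    "k": 1.1e-6,        # normal-cell activation by tumor presence
    "Tstar": 5e5,       # critical tumor size
    "aN": 0.03,         # chemo kill coefficient, normal cells
    "bN": 0.03,         # radio kill coefficient, normal cells
    "s": 1e5,           # constant immune source (cells/day)
    "d": 0.0125,        # immune natural death rate
    "eps1": 0.0206,     # maximum immune recruitment rate
    "eps2": 3e4,        # immune recruitment steepness (cells)
    "alpha2": 1e-8,     # immune exhaustion coefficient
    "aI": 0.03,         # chemo kill coefficient, immune cells
    "bI": 0.03,         # radio kill coefficient, immune cells
    "VM": 0.5,          # chemotherapy infusion rate (mg/day)
    "d1": 0.011,        # chemotherapy decay rate
    "VR": 0.5,          # radiotherapy infusion rate (mg/day)
    "d2": 0.011,        # radiotherapy decay rate
    "delta1": 1.0,      # chemo kill-saturation exponent (per mg)
    "delta2": 1.0,      # radio kill-saturation exponent (per mg)
}

#: Published value ranges, used as default fitting bounds and sensitivity
#: sampling intervals.  delta1/delta2 carry no published range; (0.1, 10)
#: around the unit default is this package's convention.
RANGES: dict[str, tuple[float, float]] = {
    "r1": (0.02, 0.95),
    "Tmax": (1e7, 6e7),
    "alpha1": (0.0, 1.0),
    "mu": (0.0, 0.1),
    "aT": (0.001, 1.0),
    "bT": (0.001, 1.0),
    "r2": (0.02, 0.95),
    "aTR": (0.001, 1.0),
    "bTR": (0.001, 1.0),
    "r3": (0.02, 0.90),
    "Nmax": (1e7, 5e7),
    "k": (0.0, 1.0),
    "Tstar": (1e5, 9e5),
    "aN": (0.001, 1.0),
    "bN": (0.001, 1.0),
    "s": (1e4, 1.5e5),
    "d": (0.001, 1.0),
    "eps1": (0.0, 1.0),
    "eps2": (50.0, 5e4),
    "alpha2": (0.0, 1.0),
    "aI": (0.001, 1.0),
    "bI": (0.001, 1.0),
    "VM": (0.0, 1.0),
    "d1": (0.0, 0.1),
    "VR": (0.0, 1.0),
    "d2": (0.0, 0.1),
    "delta1": (0.1, 10.0),
    "delta2": (0.1, 10.0),
}

PARAM_NAMES: tuple[str, ...] = tuple(POINT_VALUES)

#: Fields that may legitimately be zero (no mutation, no infusion, no
#: normal-cell activation); every other field must be strictly positive.
_MAY_BE_ZERO = frozenset({"mu", "VM", "VR", "k"})

#: Named parameter scenarios from the equilibrium analysis: slow tumor growth
#: yields a stable tumor-free state; slow normal-cell growth yields a stable
#: coexistence (endemic) state.
SCENARIOS: dict[str, dict[str, float]] = {
    "tumor-free": {"r1": 0.00431, "r2": 0.0025},
    "endemic": {"r3": 0.007},
}


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the six-compartment model.

    Defaults are the published simulation point values.  ``overridden``
    records which fields were changed from those defaults.
    """

    r1: float = POINT_VALUES["r1"]
    Tmax: float = POINT_VALUES["Tmax"]
    alpha1: float = POINT_VALUES["alpha1"]
    mu: float = POINT_VALUES["mu"]
    aT: float = POINT_VALUES["aT"]
    bT: float = POINT_VALUES["bT"]
    r2: float = POINT_VALUES["r2"]
    aTR: float = POINT_VALUES["aTR"]
    bTR: float = POINT_VALUES["bTR"]
    r3: float = POINT_VALUES["r3"]
    Nmax: float = POINT_VALUES["Nmax"]
    k: float = POINT_VALUES["k"]
    Tstar: float = POINT_VALUES["Tstar"]
    aN: float = POINT_VALUES["aN"]
    bN: float = POINT_VALUES["bN"]
    s: float = POINT_VALUES["s"]
    d: float = POINT_VALUES["d"]
    eps1: float = POINT_VALUES["eps1"]
    eps2: float = POINT_VALUES["eps2"]
    alpha2: float = POINT_VALUES["alpha2"]
    aI: float = POINT_VALUES["aI"]
    bI: float = POINT_VALUES["bI"]
    VM: float = POINT_VALUES["VM"]
    d1: float = POINT_VALUES["d1"]
    VR: float = POINT_VALUES["VR"]
    d2: float = POINT_VALUES["d2"]
    delta1: float = POINT_VALUES["delta1"]
    delta2: float = POINT_VALUES["delta2"]
    overridden: tuple[str, ...] = dataclasses.field(
        default=(), compare=False, repr=False
    )

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not (value >= 0.0):  # also rejects NaN
                raise ValueError(f"parameter {name!r} must be nonnegative, got {value}")
            if value == 0.0 and name not in _MAY_BE_ZERO:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if self.Tmax < self.Tstar:
            raise ValueError("Tmax must be >= Tstar")

    def replace(self, **overrides: float) -> "ModelParams":
        """Return a copy with ``overrides`` applied (validated like make_params)."""
        return make_params({**self.to_dict(), **overrides})

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def range_of(self, name: str) -> tuple[float, float]:
        if name not in RANGES:
            raise KeyError(f"unknown parameter {name!r}")
        return RANGES[name]


def make_params(
    overrides: Mapping[str, float] | None = None,
    *,
    allow_out_of_range: bool = True,
) -> ModelParams:
    """Build a :class:`ModelParams` from the published point values.

    Parameters
    ----------
    overrides
        Mapping of parameter name to value; every name must be one of the 28
        model constants.  Positivity constraints are always enforced.
    allow_out_of_range
        When False, an override falling outside the published value range
        raises instead of being accepted.
    """
    overrides = dict(overrides or {})
    unknown = sorted(set(overrides) - set(PARAM_NAMES))
    if unknown:
        raise KeyError(f"unknown parameter name(s): {', '.join(unknown)}")
    for name, value in overrides.items():
        try:
            overrides[name] = float(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"parameter {name!r} is not numeric: {value!r}") from exc
    if not allow_out_of_range:
        for name, value in overrides.items():
            lo, hi = RANGES[name]
            if not (lo <= value <= hi):
                raise ValueError(
                    f"{name}={value} outside published range [{lo}, {hi}]"
                )
    values = {**POINT_VALUES, **overrides}
    changed = tuple(
        name for name in PARAM_NAMES if values[name] != POINT_VALUES[name]
    )
    return ModelParams(**values, overridden=changed)


def load_config(path: str | Path) -> ModelParams:
    """Read a parameter config (JSON or YAML mapping of name -> value).

    Missing keys keep their published point values; unknown keys are an error.
    """
    text = Path(path).read_text()
    try:
        data = json.loads(text)  # YAML 1.1 resolvers mis-type literals like 1e-08
    except json.JSONDecodeError:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping of parameter -> value")
    return make_params(data)


def save_config(p: ModelParams, path: str | Path) -> None:
    """Write the full parameter set as JSON (readable by :func:`load_config`)."""
    Path(path).write_text(json.dumps(p.to_dict(), indent=2) + "\n")
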