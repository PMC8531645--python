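"""Seven-parameter CCI input space: marginal distributions and sampling.

All samplers work through a single unit-hypercube transform, so Sobol,
Latin-hypercube and plain Monte Carlo designs share one mapping from
[0,1]^7 to physical parameters:

* uniform marginals: affine stretch to [lower, upper];
* discrete marginals: equal-probability binning of the unit coordinate
  onto the level list (shape: [0, 0.5) -> 0, [0.5, 1] -> 1; diameter:
  four equal bins onto 5/10/15/20 mm);
* normal marginals: inverse CDF of the normal truncated at the bounds,
  with the stated experimental mean and sd = (upper - lower) / 6 so the
  bounds sit near +/- 3 sigma.

Parameters are treated as statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .params import (
    BOUNDS,
    DIAMETER_LEVELS,
    NOMINAL_FRICTION,
    NOMINAL_THICKNESS,
    PARAM_NAMES,
    SHAPE_LEVELS,
)

__all__ = [
    "DistributionSpec",
    "ParameterSpace",
    "default_space",
    "transform_unit",
    "sobol_design",
    "lhs_design",
    "mc_sample",
]


@dataclass(frozen=True)
class DistributionSpec:
    """Marginal distribution of one input parameter."""

    name: str
    lower: float
    upper: float
    family: str  # "discrete" | "uniform" | "normal"
    levels: tuple[float, ...] | None = None
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError(
                f"'{self.name}': lower bound {self.lower} must be < upper {self.upper}"
            )
        if self.family not in ("discrete", "uniform", "normal"):
            raise ValueError(f"'{self.name}': unknown family '{self.family}'")
        if self.family == "discrete":
            if self.levels is None or len(self.levels) < 2:
                raise ValueError(f"'{self.name}': discrete family needs >= 2 levels")
            if any(not (self.lower <= v <= self.upper) for v in self.levels):
                raise ValueError(f"'{self.name}': levels must lie within bounds")
        if self.family == "normal":
            if self.mean is None or self.sd is None:
                raise ValueError(f"'{self.name}': normal family needs mean and sd")
            if not (self.lower <= self.mean <= self.upper):
                raise ValueError(f"'{self.name}': mean must lie within bounds")
            if self.sd <= 0:
                raise ValueError(f"'{self.name}': sd must be positive")

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Map unit-interval coordinates to parameter values."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError(f"'{self.name}': unit coordinate outside [0, 1]")
        if self.family == "uniform":
            return self.lower + u * (self.upper - self.lower)
        if self.family == "discrete":
            levels = np.asarray(self.levels, dtype=float)
            idx = np.minimum((u * len(levels)).astype(int), len(levels) - 1)
            return levels[idx]
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


def _default_specs() -> tuple[DistributionSpec, ...]:
    def normal(name: str, mean: float) -> DistributionSpec:
        lo, hi = BOUNDS[name]
        return DistributionSpec(name, lo, hi, "normal", mean=mean, sd=(hi - lo) / 6.0)

    return (
        DistributionSpec("d_probe", *BOUNDS["d_probe"], "discrete", levels=DIAMETER_LEVELS),
        DistributionSpec("shape", *BOUNDS["shape"], "discrete", levels=SHAPE_LEVELS),
        DistributionSpec("v_ind", *BOUNDS["v_ind"], "uniform"),
        DistributionSpec("d_ind", *BOUNDS["d_ind"], "uniform"),
        DistributionSpec("theta", *BOUNDS["theta"], "uniform"),
        normal("mu_f", NOMINAL_FRICTION),
        normal("t_m", NOMINAL_THICKNESS),
    )


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered collection of the seven marginal distributions."""

    specs: tuple[DistributionSpec, ...] = field(default_factory=_default_specs)

    def __post_init__(self) -> None:
        if len(self.specs) != 7:
            raise ValueError(f"expected exactly 7 parameters, got {len(self.specs)}")
        names = tuple(s.name for s in self.specs)
        if names != PARAM_NAMES:
            raise ValueError(f"parameter order must be {PARAM_NAMES}, got {names}")

    def __getitem__(self, name: str) -> DistributionSpec:
        for spec in self.specs:
            if spec.name == name:
                return spec
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)


def default_space() -> ParameterSpace:
    return ParameterSpace()


def transform_unit(u, space: ParameterSpace | None = None) -> pd.DataFrame:
    """Push unit-hypercube points through the marginal transforms.

    ``u`` is an (n, 7) array (or a single 7-vector) with entries in [0, 1];
    the result is a canonical parameter DataFrame.
    """
    space = space or default_space()
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.shape[1] != 7:
        raise ValueError(f"expected 7 unit coordinates per point, got {u.shape[1]}")
    cols = {spec.name: spec.from_unit(u[:, j]) for j, spec in enumerate(space.specs)}
    return pd.DataFrame(cols)


def sobol_design(n: int, space: ParameterSpace | None = None) -> pd.DataFrame:
    """First ``n`` points of the unscrambled base-2 Sobol sequence mapped to
    the parameter space.

    The all-zeros leading point of the sequence is skipped, so the design
    starts from the first nonzero point; the design is deterministic (no
    seed) and bit-reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.Sobol(d=7, scramble=False)
    sampler.fast_forward(1)
    u = sampler.random(n)
    return transform_unit(u, space)


def lhs_design(n: int, space: ParameterSpace | None = None, seed: int = 0) -> pd.DataFrame:
    """Latin-hypercube design: one point per marginal stratum per dimension,
    reproducible under a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=7, seed=seed)
    u = sampler.random(n)
    return transform_unit(u, space)


def mc_sample(
    n: int,
    space: ParameterSpace | None = None,
    fixed: tuple[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """i.i.d. draws from the marginals, optionally with one parameter held
    constant at a value inside its bounds (conditional Monte Carlo)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    space = space or default_space()
    rng = np.random.default_rng(seed)
    u = rng.random((n, 7))
    frame = transform_unit(u, space)
    if fixed is not None:
        name, value = fixed
        spec = space[name]  # KeyError if unknown
        if not (spec.lower <= value <= spec.upper):
            raise ValueError(
                f"fixed value {value} for '{name}' outside bounds "
                f"[{spec.lower}, {spec.upper}]"
            )
        if spec.family == "discrete" and value not in spec.levels:
            raise ValueError(f"fixed value {value} for '{name}' not a level of {spec.levels}")
        frame[name] = value
    return frame
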