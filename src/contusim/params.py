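"""Canonical seven-parameter description of a controlled cortical impact.

The input space has a fixed order that defines the input-vector layout used
by every downstream component (samplers, surrogate, sensitivity analysis):

    d_probe  probe diameter (mm),          discrete {5, 10, 15, 20}
    shape    tip shape flag,               discrete {0 = cylindrical, 1 = hemispherical}
    v_ind    indentation velocity (m/s),   uniform [0.4, 4]
    d_ind    indentation depth (mm),       uniform [1.1, 12.6]
    theta    probe inclination (deg),      uniform [-15, 15]
    mu_f     DAM-probe friction (-),       truncated normal, mean 0.163
    t_m      DAM thickness (mm),           truncated normal, mean 0.736
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PARAM_NAMES",
    "BOUNDS",
    "DIAMETER_LEVELS",
    "SHAPE_LEVELS",
    "NOMINAL_FRICTION",
    "NOMINAL_THICKNESS",
    "ParameterSample",
    "samples_to_frame",
    "frame_to_samples",
]

PARAM_NAMES: tuple[str, ...] = ("d_probe", "shape", "v_ind", "d_ind", "theta", "mu_f", "t_m")

#: Lower/upper bounds of the admissible input space (units as in the module docstring).
BOUNDS: dict[str, tuple[float, float]] = {
    "d_probe": (5.0, 20.0),
    "shape": (0.0, 1.0),
    "v_ind": (0.4, 4.0),
    "d_ind": (1.1, 12.6),
    "theta": (-15.0, 15.0),
    "mu_f": (0.07, 0.26),
    "t_m": (0.413, 1.058),
}

DIAMETER_LEVELS: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
SHAPE_LEVELS: tuple[float, ...] = (0.0, 1.0)

#: Stated means of the experimentally measured (normal) parameters.
NOMINAL_FRICTION = 0.163
NOMINAL_THICKNESS = 0.736


@dataclass(frozen=True)
class ParameterSample:
    """One point of the seven-dimensional CCI input space."""

    d_probe: float
    shape: float
    v_ind: float
    d_ind: float
    theta: float
    mu_f: float
    t_m: float

    def validate(self, d_ind_lower: float | None = None) -> None:
        """Raise ValueError naming the first out-of-bounds field.

        ``d_ind_lower`` optionally relaxes the depth lower bound (the
        zero-depth boundary extension used in tests of the stand-in).
        """
        for name in PARAM_NAMES:
            lo, hi = BOUNDS[name]
            if name == "d_ind" and d_ind_lower is not None:
                lo = d_ind_lower
            value = getattr(self, name)
            if not (lo <= value <= hi):
                raise ValueError(
                    f"parameter '{name}' = {value} outside bounds [{lo}, {hi}]"
                )
        if self.shape not in (0.0, 1.0):
            raise ValueError(f"parameter 'shape' must be 0 or 1, got {self.shape}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)


def samples_to_frame(samples) -> pd.DataFrame:
    """Stack ParameterSamples (or a single one) into a canonical DataFrame."""
    if isinstance(samples, ParameterSample):
        samples = [samples]
    rows = np.atleast_2d([s.as_array() for s in samples])
    return pd.DataFrame(rows, columns=list(PARAM_NAMES))


def frame_to_samples(frame: pd.DataFrame) -> list[ParameterSample]:
    missing = [c for c in PARAM_NAMES if c not in frame.columns]
    if missing:
        raise ValueError(f"missing parameter columns: {missing}")
    return [
        ParameterSample(**{name: float(row[name]) for name in PARAM_NAMES})
        for _, row in frame.iterrows()
    ]
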