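"""Objective rating of a simulated vs a reference time-history curve,
combining a corridor method and a cross-correlation method into a [0,1]
score (the scheme used to grade simulated force-time responses against
experiment).

The corridor method scores each sample 1 inside an inner corridor
(reference +/- a0 * peak), 0 outside an outer corridor (+/- b0 * peak),
with a linear transition in between (exponent kG = 1), and time-averages.
The cross-correlation method combines three sub-scores with equal weights
(1/3): phase (best alignment shift within an allowed window), shape
(correlation coefficient at that shift) and amplitude (ratio of signal
magnitudes after alignment), each with a linear transition (kV = kP = 1).
The overall rating is the equal-weight combination G1 * corridor +
G2 * cross-correlation with G1 = G2 = 0.5.

Only the combination weights, sub-weights and linear transitions are fixed
by the validation protocol this mirrors; corridor half-widths, the allowed
phase window and the activity-based evaluation interval are configurable
defaults of this implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SignalCurve",
    "RatingConfig",
    "RatingReport",
    "corridor_score",
    "xcorr_score",
    "combine_scores",
    "overall_rating",
    "load_curve",
]


@dataclass(frozen=True)
class SignalCurve:
    """A sampled time history (time strictly increasing, in seconds)."""

    time: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("time and value must be equal-length 1-D sequences")
        if len(t) < 2:
            raise ValueError("a curve needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "value", v)


def load_curve(path: str | Path) -> SignalCurve:
    """Read a two-column (time, value) CSV curve."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError("curve CSV needs two columns: time, value")
    return SignalCurve(frame.iloc[:, 0].to_numpy(), frame.iloc[:, 1].to_numpy())


@dataclass(frozen=True)
class RatingConfig:
    """Weights and corridor geometry of the rating."""

    G1: float = 0.5  # corridor-method weight
    G2: float = 0.5  # cross-correlation-method weight
    w_amp: float = 1.0 / 3.0
    w_shape: float = 1.0 / 3.0
    w_phase: float = 1.0 / 3.0
    kV: float = 1.0  # shape transition exponent
    kP: float = 1.0  # phase transition exponent
    kG: float = 1.0  # corridor / amplitude transition exponent
    a0: float = 0.05  # inner corridor half-width, fraction of reference peak
    b0: float = 0.5  # outer corridor half-width, fraction of reference peak
    phase_window: float = 0.2  # allowed shift, fraction of evaluation interval
    activity_threshold: float = 0.05  # |ref| fraction defining the interval

    def __post_init__(self) -> None:
        if abs(self.G1 + self.G2 - 1.0) > 1e-12:
            raise ValueError("method weights G1 + G2 must sum to 1")
        if abs(self.w_amp + self.w_shape + self.w_phase - 1.0) > 1e-12:
            raise ValueError("cross-correlation sub-weights must sum to 1")
        if not (0.0 < self.a0 < self.b0):
            raise ValueError("corridor widths need 0 < a0 < b0")


@dataclass(frozen=True)
class RatingReport:
    corridor: float
    xcorr: float
    amplitude: float
    shape: float
    phase: float
    overall: float


def _common_base(ref: SignalCurve, test: SignalCurve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate the test curve onto the reference grid over the
    overlapping time support."""
    lo = max(ref.time[0], test.time[0])
    hi = min(ref.time[-1], test.time[-1])
    if lo >= hi:
        raise ValueError("curves have no overlapping time support")
    keep = (ref.time >= lo) & (ref.time <= hi)
    t = ref.time[keep]
    if len(t) < 2:
        raise ValueError("overlapping support contains fewer than 2 reference samples")
    return t, ref.value[keep], np.interp(t, test.time, test.value)


def _evaluation_slice(r: np.ndarray, threshold: float) -> slice:
    peak = np.max(np.abs(r))
    active = np.flatnonzero(np.abs(r) >= threshold * peak)
    if active.size == 0:
        return slice(0, len(r))
    return slice(int(active[0]), int(active[-1]) + 1)


def corridor_score(ref: SignalCurve, test: SignalCurve, cfg: RatingConfig | None = None) -> float:
    """Time-averaged corridor rating in [0, 1]."""
    cfg = cfg or RatingConfig()
    t, r, s = _common_base(ref, test)
    win = _evaluation_slice(r, cfg.activity_threshold)
    t, r, s = t[win], r[win], s[win]
    peak = np.max(np.abs(r))
    if peak == 0:
        raise ValueError("reference curve is identically zero on the interval")
    inner, outer = cfg.a0 * peak, cfg.b0 * peak
    dev = np.abs(s - r)
    pointwise = np.clip((outer - dev) / (outer - inner), 0.0, 1.0) ** cfg.kG
    if np.all(pointwise == 1.0):  # exact score for curves inside the inner corridor
        return 1.0
    return float(np.clip(np.trapezoid(pointwise, t) / (t[-1] - t[0]), 0.0, 1.0))


def xcorr_score(
    ref: SignalCurve, test: SignalCurve, cfg: RatingConfig | None = None
) -> tuple[float, dict[str, float]]:
    """Cross-correlation rating and its amplitude/shape/phase sub-scores.

    The phase shift is the sample offset (within the allowed window)
    maximizing the normalized cross-correlation; smaller shifts win ties.
    """
    cfg = cfg or RatingConfig()
    _, r, s = _common_base(ref, test)
    win = _evaluation_slice(r, cfg.activity_threshold)
    r, s = r[win], s[win]
    n = len(r)
    if np.all(r == 0) or np.all(s == 0):
        raise ValueError("zero-energy signal on the evaluation interval")
    max_shift = int(round(cfg.phase_window * n))

    def corr_at(shift: int) -> float:
        if shift >= 0:
            a, b = r[shift:], s[: n - shift]
        else:
            a, b = r[: n + shift], s[-shift:]
        denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
        return float(np.sum(a * b) / denom) if denom > 0 else 0.0

    best_shift, best_k = 0, corr_at(0)
    for shift in sorted(range(-max_shift, max_shift + 1), key=abs):
        k = corr_at(shift)
        if k > best_k + 1e-12:
            best_shift, best_k = shift, k

    phase = (
        ((max_shift - abs(best_shift)) / max_shift) ** cfg.kP if max_shift > 0 else 1.0
    )
    shape = float(np.clip(best_k, 0.0, 1.0) ** cfg.kV)
    if best_shift >= 0:
        a, b = r[best_shift:], s[: n - best_shift]
    else:
        a, b = r[: n + best_shift], s[-best_shift:]
    norm_r, norm_s = np.sqrt(np.sum(a**2)), np.sqrt(np.sum(b**2))
    amp = float((min(norm_r, norm_s) / max(norm_r, norm_s)) ** cfg.kG)
    score = cfg.w_amp * amp + cfg.w_shape * shape + cfg.w_phase * phase
    return score, {"amplitude": amp, "shape": shape, "phase": phase}


def combine_scores(corridor: float, xcorr: float, cfg: RatingConfig | None = None) -> float:
    """Equal-weight (by default) combination of the two method ratings."""
    cfg = cfg or RatingConfig()
    return cfg.G1 * corridor + cfg.G2 * xcorr


def overall_rating(
    ref: SignalCurve, test: SignalCurve, cfg: RatingConfig | None = None
) -> RatingReport:
    """Full rating report: corridor, cross-correlation (with sub-scores)
    and their weighted combination."""
    cfg = cfg or RatingConfig()
    c = corridor_score(ref, test, cfg)
    x, sub = xcorr_score(ref, test, cfg)
    return RatingReport(
        corridor=c,
        xcorr=x,
        amplitude=sub["amplitude"],
        shape=sub["shape"],
        phase=sub["phase"],
        overall=combine_scores(c, x, cfg),
    )
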