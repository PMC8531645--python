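"""Conditional Monte Carlo sweeps: uncertainty of the injury metrics with
one input fixed at a time.

The plan fixes each parameter in turn at a grid of levels — 2 for the tip
shape, 4 for the probe diameter (5/10/15/20 mm), 10 equally spaced values
(bounds inclusive) for each of the five remaining parameters — for a total
of 2 + 4 + 5 x 10 = 56 sweep entries. Each entry runs a Monte Carlo
simulation of ``n`` samples with the fixed parameter pinned and the other
six drawn from their marginals, and records the median and the 90%
interval (5th-95th percentiles) of every metric.

Reproducibility: one master seed; all entries sweeping the same parameter
share the spawn of ``numpy.random.SeedSequence(master_seed)`` indexed by
that parameter's canonical position, so any entry can be recomputed in
isolation and levels of one sweep use common random numbers for the
co-sampled parameters (a null parameter therefore yields an exactly flat
sweep).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .space import ParameterSpace, default_space, mc_sample
from .standin import METRIC_NAMES

__all__ = ["SweepPlan", "UncertaintyCurves", "build_sweep_plan", "run_mcs", "summarize"]

_CONTINUOUS_LEVELS = 10


@dataclass(frozen=True)
class SweepPlan:
    """Ordered list of (parameter name, fixed level) sweep entries."""

    entries: tuple[tuple[str, float], ...]

    def __len__(self) -> int:
        return len(self.entries)


def build_sweep_plan(space: ParameterSpace | None = None) -> SweepPlan:
    """56-entry conditional MCS plan over the canonical space."""
    space = space or default_space()
    entries: list[tuple[str, float]] = []
    for spec in space.specs:
        if spec.family == "discrete":
            levels = list(spec.levels)
        else:
            levels = list(np.linspace(spec.lower, spec.upper, _CONTINUOUS_LEVELS))
        entries.extend((spec.name, float(v)) for v in levels)
    plan = SweepPlan(entries=tuple(entries))
    if len(plan) != 56:
        raise AssertionError(f"canonical plan must have 56 entries, got {len(plan)}")
    return plan


@dataclass(frozen=True)
class UncertaintyCurves:
    """Per (parameter, level, metric) summary of the conditional MCS.

    ``table`` is long-format with columns parameter, level, metric, median,
    q05, q95, n.
    """

    table: pd.DataFrame
    n: int

    def for_parameter(self, name: str) -> pd.DataFrame:
        return self.table[self.table["parameter"] == name].reset_index(drop=True)


def run_mcs(
    model,
    plan: SweepPlan | None = None,
    n: int = 10_000,
    seed: int = 0,
    space: ParameterSpace | None = None,
) -> UncertaintyCurves:
    """Run the conditional Monte Carlo sweeps on a predict-capable model.

    ``model`` must expose ``predict(frame) -> metrics frame`` (the trained
    surrogate ensemble or the stand-in wrapper).
    """
    plan = plan or build_sweep_plan(space)
    space = space or default_space()
    param_order = tuple(s.name for s in space.specs)
    streams = np.random.SeedSequence(seed).spawn(len(param_order))
    param_seed = {
        name: int(stream.generate_state(1)[0] % (2**31))
        for name, stream in zip(param_order, streams)
    }
    rows = []
    for name, level in plan.entries:
        sub_seed = param_seed[name]
        samples = mc_sample(n, space, fixed=(name, level), seed=sub_seed)
        try:
            metrics = model.predict(samples)
        except Exception as exc:  # annotate with sweep context
            raise RuntimeError(
                f"model evaluation failed for sweep entry ({name} = {level})"
            ) from exc
        for metric in METRIC_NAMES:
            vals = metrics[metric].to_numpy(dtype=float)
            q05, med, q95 = np.percentile(vals, [5.0, 50.0, 95.0])
            rows.append(
                {
                    "parameter": name,
                    "level": level,
                    "metric": metric,
                    "median": med,
                    "q05": q05,
                    "q95": q95,
                    "n": n,
                }
            )
    return UncertaintyCurves(table=pd.DataFrame(rows), n=n)


def summarize(curves: UncertaintyCurves) -> pd.DataFrame:
    """Long-format tidy table (one row per parameter-level-metric)."""
    expected = {"parameter", "level", "metric", "median", "q05", "q95", "n"}
    if set(curves.table.columns) != expected:
        raise ValueError("incomplete uncertainty curves")
    return curves.table.copy()
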