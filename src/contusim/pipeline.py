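"""End-to-end pipeline: generate -> train -> mcs -> sensitivity -> injury
-> rate-curves, driven by one declarative YAML config.

Every stochastic stage takes its seed from the explicit master seed in the
config (no wall-clock defaults), and rerunning with an identical config
reproduces identical CSV/JSON artifacts. The stage outputs and seeds are
recorded in a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .mcs import build_sweep_plan, run_mcs, summarize
from .params import PARAM_NAMES
from .rating import RatingConfig, load_curve, overall_rating
from .risk import evaluate_all_metrics, summary_table
from .sensitivity import analyze, rank_parameters
from .space import DistributionSpec, ParameterSpace, default_space, sobol_design
from .standin import METRIC_NAMES, StandInConfig, StandInModel
from .surrogate import SurrogateEnsemble, TrainingConfig, build_ensemble

__all__ = ["RunConfig", "validate_config", "default_config_path", "run_pipeline"]

logger = logging.getLogger("contusim")

_STAGES = ("generate", "train", "mcs", "sensitivity", "injury", "rate_curves")

_KNOWN_TOP = {
    "seeds", "standin", "space", "training", "stages", "design_size",
    "mcs", "sensitivity", "rate_curves", "output_dir",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration with every default materialized."""

    master_seed: int
    output_dir: Path
    standin: StandInConfig
    space: ParameterSpace
    training: TrainingConfig
    stages: dict[str, bool]
    design_size: int = 80
    mcs_n: int = 10_000
    sensitivity_n: int = 10_000
    sensitivity_M: int = 48
    sensitivity_B: int = 100
    rate_ref: Path | None = None
    rate_test: Path | None = None
    raw: dict = field(default_factory=dict, repr=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config_path() -> Path:
    return Path(str(resources.files("contusim.data").joinpath("default_config.yaml")))


def _build_space(overrides: dict, errors: list[str]) -> ParameterSpace:
    base = default_space()
    if not overrides:
        return base
    specs = []
    for spec in base.specs:
        ov = overrides.get(spec.name)
        if ov is None:
            specs.append(spec)
            continue
        unknown = set(ov) - {"lower", "upper"}
        if unknown:
            errors.append(f"space.{spec.name}: unknown keys {sorted(unknown)}")
        lo = float(ov.get("lower", spec.lower))
        hi = float(ov.get("upper", spec.upper))
        try:
            if spec.family == "discrete":
                levels = tuple(v for v in spec.levels if lo <= v <= hi)
                specs.append(DistributionSpec(spec.name, lo, hi, "discrete", levels=levels))
            elif spec.family == "normal":
                specs.append(
                    DistributionSpec(
                        spec.name, lo, hi, "normal", mean=spec.mean, sd=(hi - lo) / 6.0
                    )
                )
            else:
                specs.append(DistributionSpec(spec.name, lo, hi, "uniform"))
        except ValueError as exc:
            errors.append(str(exc))
            specs.append(spec)
    for name in overrides:
        if name not in PARAM_NAMES:
            errors.append(f"space: unknown parameter '{name}'")
    try:
        return ParameterSpace(tuple(specs))
    except ValueError as exc:
        errors.append(str(exc))
        return base


def validate_config(path: str | Path) -> RunConfig:
    """Schema-check a YAML config; raises ValueError listing every
    offending key at once."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text()) or {}
    errors: list[str] = []

    unknown = set(data) - _KNOWN_TOP
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")

    seeds = data.get("seeds")
    master_seed = None
    if not isinstance(seeds, dict) or "master" not in seeds:
        errors.append("seeds.master is required (no silent randomness)")
    else:
        master_seed = int(seeds["master"])

    standin_cfg = StandInConfig()
    try:
        standin_cfg = StandInConfig(**(data.get("standin") or {}))
    except (TypeError, ValueError) as exc:
        errors.append(f"standin: {exc}")

    space = _build_space(data.get("space") or {}, errors)

    training_cfg = TrainingConfig()
    try:
        training_kwargs = dict(data.get("training") or {})
        if "architecture" in training_kwargs:
            training_kwargs["architecture"] = tuple(training_kwargs["architecture"])
        if master_seed is not None:
            training_kwargs.setdefault("base_seed", master_seed)
        training_cfg = TrainingConfig(**training_kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"training: {exc}")

    stages = {name: True for name in _STAGES}
    stages["rate_curves"] = False
    for name, enabled in (data.get("stages") or {}).items():
        if name not in _STAGES:
            errors.append(f"stages: unknown stage '{name}'")
        else:
            stages[name] = bool(enabled)

    rate = data.get("rate_curves") or {}
    rate_ref = Path(rate["ref"]) if "ref" in rate else None
    rate_test = Path(rate["test"]) if "test" in rate else None
    if stages["rate_curves"] and (rate_ref is None or rate_test is None):
        errors.append("rate_curves stage enabled but ref/test curve paths missing")
    for p in (rate_ref, rate_test):
        if p is not None and not p.exists():
            errors.append(f"rate_curves: path not found: {p}")

    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))

    mcs_opts = data.get("mcs") or {}
    sens_opts = data.get("sensitivity") or {}
    return RunConfig(
        master_seed=master_seed,
        output_dir=Path(data.get("output_dir", "contusim_out")),
        standin=standin_cfg,
        space=space,
        training=training_cfg,
        stages=stages,
        design_size=int(data.get("design_size", 80)),
        mcs_n=int(mcs_opts.get("n", 10_000)),
        sensitivity_n=int(sens_opts.get("n", 10_000)),
        sensitivity_M=int(sens_opts.get("M", 48)),
        sensitivity_B=int(sens_opts.get("B", 100)),
        rate_ref=rate_ref,
        rate_test=rate_test,
        raw=data,
    )


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([master, _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns (and writes)
    the run manifest. A stage failure halts the run with the stage named;
    artifacts of completed stages are retained."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "stages": {},
    }
    simulator = StandInModel(cfg.standin)
    model = simulator  # default target; replaced by the ensemble if trained
    current = None
    try:
        if cfg.stages["generate"]:
            current = "generate"
            design = sobol_design(cfg.design_size, cfg.space)
            metrics = simulator.predict(design)
            table = design.join(metrics)
            table.insert(0, "design_id", np.arange(len(table)))
            p = out / "design.csv"
            table.to_csv(p, index=False)
            manifest["stages"]["generate"] = {"design": str(p), "n": cfg.design_size}
            logger.info("generate: %d-point Sobol design -> %s", cfg.design_size, p)

        if cfg.stages["train"]:
            current = "train"
            design = sobol_design(cfg.design_size, cfg.space)
            ensemble, report = build_ensemble(design, simulator.predict, cfg.training)
            model = ensemble
            ens_dir = out / "ensemble"
            ensemble.save(ens_dir)
            rep_path = out / "validation_errors.json"
            rep_path.write_text(json.dumps(
                {"nmae": report.nmae, "nrmse": report.nrmse, "ae95": report.ae95},
                indent=2))
            manifest["stages"]["train"] = {
                "ensemble": str(ens_dir),
                "errors": str(rep_path),
                "seed": cfg.training.base_seed,
                "max_validation_error": report.max_error(),
            }
            logger.info("train: max validation error %.4f", report.max_error())

        if cfg.stages["mcs"]:
            current = "mcs"
            seed = _stage_seed(cfg.master_seed, "mcs")
            curves = run_mcs(model, build_sweep_plan(cfg.space), n=cfg.mcs_n,
                             seed=seed, space=cfg.space)
            p = out / "mcs_summary.csv"
            summarize(curves).to_csv(p, index=False)
            manifest["stages"]["mcs"] = {"summary": str(p), "n": cfg.mcs_n, "seed": seed}
            logger.info("mcs: 56 sweeps x %d samples -> %s", cfg.mcs_n, p)

        if cfg.stages["sensitivity"]:
            current = "sensitivity"
            seed = _stage_seed(cfg.master_seed, "sensitivity")
            result = analyze(model, cfg.space, n=cfg.sensitivity_n, seed=seed,
                             M=cfg.sensitivity_M, B=cfg.sensitivity_B)
            ranked_d = rank_parameters(result, "delta")[["output", "input", "rank"]]
            ranked_s = rank_parameters(result, "s1")[["output", "input", "rank"]]
            table = result.table.merge(
                ranked_d.rename(columns={"rank": "rank_delta"}), on=["input", "output"]
            ).merge(ranked_s.rename(columns={"rank": "rank_s1"}), on=["input", "output"])
            p = out / "sensitivity.csv"
            table.to_csv(p, index=False)
            manifest["stages"]["sensitivity"] = {
                "table": str(p), "n": cfg.sensitivity_n, "seed": seed,
            }
            logger.info("sensitivity: %d LHS samples -> %s", cfg.sensitivity_n, p)

        if cfg.stages["injury"]:
            current = "injury"
            evaluations = evaluate_all_metrics(model)
            table = summary_table(evaluations)
            p = out / "injury_risk.csv"
            table.to_csv(p, index=False)
            jp = out / "injury_risk.json"
            jp.write_text(table.set_index("metric").to_json(indent=2))
            manifest["stages"]["injury"] = {"summary": str(p), "json": str(jp)}
            logger.info("injury: predictor evaluation -> %s", p)

        if cfg.stages["rate_curves"]:
            current = "rate_curves"
            report = overall_rating(load_curve(cfg.rate_ref), load_curve(cfg.rate_test),
                                    RatingConfig())
            p = out / "curve_rating.json"
            p.write_text(json.dumps(asdict(report), indent=2))
            manifest["stages"]["rate_curves"] = {"report": str(p)}
            logger.info("rate_curves: overall %.3f -> %s", report.overall, p)
    except Exception as exc:
        manifest["failed_stage"] = current
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage '{current}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
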