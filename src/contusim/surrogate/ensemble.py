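"""Six-member MLP surrogate ensemble of the CCI simulator.

The ensemble maps the seven impact parameters to the four ROI injury
metrics. Each member is a 7:256:128:64:32:16:4 Softplus network with a
rectified output; members differ only in their initialization seed. After
training, member predictions are combined with non-negative weights on the
probability simplex chosen to minimize the validation mean squared error
(computed on [0,1]-normalized outputs so the four metrics contribute
comparably), which can never do worse than the best single member.

Inputs are min-max normalized to [0,1] with the *fixed* parameter-space
bounds (design-independent); outputs are min-max normalized with the
training-data range, frozen into the ensemble.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ..params import BOUNDS, PARAM_NAMES
from ..space import ParameterSpace, sobol_design
from ..standin import METRIC_NAMES
from ._mlp import MLP, huber_loss

__all__ = [
    "TrainingConfig",
    "ErrorReport",
    "SurrogateMember",
    "SurrogateEnsemble",
    "error_report",
    "train_member",
    "ensemble_weights",
    "build_ensemble",
    "sample_size_study",
]

_ARCHITECTURE = (7, 256, 128, 64, 32, 16, 4)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the surrogate ensemble."""

    architecture: tuple[int, ...] = _ARCHITECTURE
    huber_d: float = 0.1
    learning_rate: float = 1e-3
    l2_coefficient: float = 1e-6
    n_members: int = 6
    split: tuple[float, float] = (0.9, 0.1)
    base_seed: int = 0
    seeds: tuple[int, ...] | None = None
    max_epochs: int = 10000
    patience: int = 2000
    plateau_patience: int = 200
    plateau_factor: float = 0.5
    lr_floor: float = 1e-5

    def __post_init__(self) -> None:
        if self.huber_d <= 0:
            raise ValueError("huber_d must be positive")
        if self.n_members < 1:
            raise ValueError("need at least one ensemble member")
        if abs(sum(self.split) - 1.0) > 1e-12:
            raise ValueError("split fractions must sum to 1")
        if self.seeds is not None and len(self.seeds) != self.n_members:
            raise ValueError("seeds must have one entry per member")

    def member_seeds(self) -> tuple[int, ...]:
        if self.seeds is not None:
            return self.seeds
        ss = np.random.SeedSequence(self.base_seed)
        return tuple(int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(self.n_members))


@dataclass(frozen=True)
class ErrorReport:
    """Per-output normalized errors, as fractions of the [0,1]-normalized
    observed range: nMAE, nRMSE, and the 95th-percentile absolute error."""

    nmae: dict[str, float]
    nrmse: dict[str, float]
    ae95: dict[str, float]

    def max_error(self) -> float:
        return max(
            max(self.nmae.values()), max(self.nrmse.values()), max(self.ae95.values())
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"nmae": self.nmae, "nrmse": self.nrmse, "ae95": self.ae95}
        ).rename_axis("output")


def error_report(predicted: pd.DataFrame, observed: pd.DataFrame) -> ErrorReport:
    """Normalized error statistics, per output column.

    Each output's observed values are min-max normalized to [0,1]; the
    absolute prediction errors on that scale yield nMAE (mean), nRMSE
    (root mean square) and ae95 (95th percentile, linear-interpolation
    convention). A constant observed column is an error.
    """
    if len(predicted) != len(observed) or len(observed) == 0:
        raise ValueError("predicted and observed must be equal-length and non-empty")
    nmae, nrmse, ae95 = {}, {}, {}
    for col in observed.columns:
        obs = observed[col].to_numpy(dtype=float)
        rng = obs.max() - obs.min()
        if rng == 0:
            raise ValueError(f"observed range of output '{col}' is zero")
        err = np.abs(predicted[col].to_numpy(dtype=float) - obs) / rng
        nmae[col] = float(err.mean())
        nrmse[col] = float(np.sqrt(np.mean(err**2)))
        ae95[col] = float(np.percentile(err, 95.0))
    return ErrorReport(nmae=nmae, nrmse=nrmse, ae95=ae95)


def _input_bounds_arrays() -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([BOUNDS[n][0] for n in PARAM_NAMES])
    hi = np.array([BOUNDS[n][1] for n in PARAM_NAMES])
    return lo, hi


@dataclass
class SurrogateMember:
    """One trained network plus its frozen output normalization."""

    mlp: MLP
    out_min: np.ndarray
    out_range: np.ndarray
    seed: int

    def predict_normalized(self, frame: pd.DataFrame) -> np.ndarray:
        lo, hi = _input_bounds_arrays()
        X = frame[list(PARAM_NAMES)].to_numpy(dtype=float)
        return self.mlp.predict((X - lo) / (hi - lo))

    def predict(self, frame: pd.DataFrame) -> pd.DataFrame:
        Y = self.predict_normalized(frame) * self.out_range + self.out_min
        return pd.DataFrame(Y, columns=list(METRIC_NAMES), index=frame.index)


def train_member(
    train_x: pd.DataFrame,
    train_y: pd.DataFrame,
    val_x: pd.DataFrame,
    val_y: pd.DataFrame,
    cfg: TrainingConfig,
    seed: int,
) -> SurrogateMember:
    """Train one network; reproducible under a fixed seed."""
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("training and validation sets must be non-empty")
    lo, hi = _input_bounds_arrays()
    Xt = (train_x[list(PARAM_NAMES)].to_numpy(dtype=float) - lo) / (hi - lo)
    Xv = (val_x[list(PARAM_NAMES)].to_numpy(dtype=float) - lo) / (hi - lo)
    Yt_raw = train_y[list(METRIC_NAMES)].to_numpy(dtype=float)
    out_min = Yt_raw.min(axis=0)
    out_range = Yt_raw.max(axis=0) - out_min
    for j, name in enumerate(METRIC_NAMES):
        if out_range[j] == 0:
            raise ValueError(f"training output '{name}' is constant; cannot normalize")
    Yt = (Yt_raw - out_min) / out_range
    Yv = (val_y[list(METRIC_NAMES)].to_numpy(dtype=float) - out_min) / out_range

    mlp = MLP(cfg.architecture, seed=seed)
    mlp.fit(
        Xt,
        Yt,
        Xv,
        Yv,
        huber_d=cfg.huber_d,
        learning_rate=cfg.learning_rate,
        l2=cfg.l2_coefficient,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        plateau_patience=cfg.plateau_patience,
        plateau_factor=cfg.plateau_factor,
        lr_floor=cfg.lr_floor,
    )
    return SurrogateMember(mlp=mlp, out_min=out_min, out_range=out_range, seed=seed)


def ensemble_weights(
    members: list[SurrogateMember], val_x: pd.DataFrame, val_y: pd.DataFrame
) -> np.ndarray:
    """Simplex weights minimizing the validation MSE of the weighted
    prediction (on normalized outputs), ties broken toward uniform.

    A tiny quadratic pull toward the uniform vector (1e-10) selects the
    uniform-most optimum when several weightings are exactly tied; the
    resulting MSE still cannot exceed any single member's beyond numerical
    tolerance, since the simplex contains every vertex.
    """
    if not members:
        raise ValueError("need at least one member")
    k = len(members)
    if k == 1:
        return np.array([1.0])
    # stack normalized member predictions: (k, n_val, 4)
    m0 = members[0]
    Yv = (val_y[list(METRIC_NAMES)].to_numpy(dtype=float) - m0.out_min) / m0.out_range
    P = np.stack([m.predict_normalized(val_x) for m in members])

    def mse(w: np.ndarray) -> float:
        resid = np.tensordot(w, P, axes=1) - Yv
        return float(np.mean(resid**2))

    uniform = np.full(k, 1.0 / k)

    def objective(w: np.ndarray) -> float:
        return mse(w) + 1e-10 * float(np.sum((w - uniform) ** 2))

    res = minimize(
        objective,
        uniform,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: np.sum(w) - 1.0}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    # guard: never worse than the best vertex
    best_vertex = int(np.argmin([mse(np.eye(k)[i]) for i in range(k)]))
    if mse(w) > mse(np.eye(k)[best_vertex]) + 1e-12:
        w = np.eye(k)[best_vertex]
    return w


@dataclass
class SurrogateEnsemble:
    """Weighted ensemble of trained members."""

    members: list[SurrogateMember]
    weights: np.ndarray
    config: TrainingConfig = field(default_factory=TrainingConfig)

    def predict(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Weighted member average; non-negative, batch-order invariant.

        Warns (does not fail) on inputs mildly outside the training bounds.
        """
        lo, hi = _input_bounds_arrays()
        X = frame[list(PARAM_NAMES)].to_numpy(dtype=float)
        if np.any(X < lo) or np.any(X > hi):
            warnings.warn(
                "some inputs lie outside the parameter bounds; the surrogate "
                "is extrapolating",
                stacklevel=2,
            )
        out = np.zeros((len(frame), len(METRIC_NAMES)))
        for w, m in zip(self.weights, self.members):
            out += w * m.predict(frame).to_numpy()
        return pd.DataFrame(out, columns=list(METRIC_NAMES), index=frame.index)

    # -- serialization -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.members):
            np.savez(
                directory / f"member_{i}.npz",
                *m.mlp.W,
                *m.mlp.b,
                out_min=m.out_min,
                out_range=m.out_range,
            )
        manifest = {
            "weights": self.weights.tolist(),
            "architecture": list(self.config.architecture),
            "member_seeds": [m.seed for m in self.members],
            "huber_d": self.config.huber_d,
            "n_members": len(self.members),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "SurrogateEnsemble":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        arch = tuple(manifest["architecture"])
        n_layers = len(arch) - 1
        members = []
        for i in range(manifest["n_members"]):
            data = np.load(directory / f"member_{i}.npz")
            mlp = MLP(arch, seed=0)
            mlp.W = [data[f"arr_{j}"] for j in range(n_layers)]
            mlp.b = [data[f"arr_{n_layers + j}"] for j in range(n_layers)]
            members.append(
                SurrogateMember(
                    mlp=mlp,
                    out_min=data["out_min"],
                    out_range=data["out_range"],
                    seed=manifest["member_seeds"][i],
                )
            )
        cfg = TrainingConfig(
            architecture=arch,
            huber_d=manifest["huber_d"],
            n_members=manifest["n_members"],
        )
        return cls(members=members, weights=np.array(manifest["weights"]), config=cfg)


def _split_design(
    design_x: pd.DataFrame, design_y: pd.DataFrame, split: tuple[float, float]
):
    """Deterministic split: the last ceil(0.1 n) design points validate."""
    n = len(design_x)
    n_val = max(1, int(round(split[1] * n)))
    n_train = n - n_val
    return (
        design_x.iloc[:n_train],
        design_y.iloc[:n_train],
        design_x.iloc[n_train:],
        design_y.iloc[n_train:],
    )


def build_ensemble(
    design_x: pd.DataFrame,
    simulator,
    cfg: TrainingConfig | None = None,
    design_y: pd.DataFrame | None = None,
    min_design: int = 10,
) -> tuple[SurrogateEnsemble, ErrorReport]:
    """Train the full ensemble on a design and report validation errors.

    ``simulator`` is a callable mapping a parameter DataFrame to a metric
    DataFrame (e.g. ``StandInModel().predict``); precomputed outputs can be
    passed via ``design_y`` instead. ``min_design`` can be relaxed for
    cross-validation folds of the smallest study size.
    """
    cfg = cfg or TrainingConfig()
    if len(design_x) < min_design:
        raise ValueError(f"design must have at least {min_design} points")
    if design_y is None:
        design_y = simulator(design_x)
    tx, ty, vx, vy = _split_design(design_x, design_y, cfg.split)
    members = [
        train_member(tx, ty, vx, vy, cfg, seed) for seed in cfg.member_seeds()
    ]
    weights = ensemble_weights(members, vx, vy)
    ensemble = SurrogateEnsemble(members=members, weights=weights, config=cfg)
    try:
        report = error_report(ensemble.predict(vx), vy)
    except ValueError:
        # a validation split of a single point has no observed range
        report = None
    return ensemble, report


def sample_size_study(
    simulator,
    cfg: TrainingConfig | None = None,
    sizes: tuple[int, ...] = (10, 20, 40, 80),
    folds: int = 5,
    space: ParameterSpace | None = None,
    error_bar: float = 0.04,
) -> tuple[pd.DataFrame, int | None]:
    """K-fold cross-validated learning curve over design sizes.

    For each size, a Sobol design is simulated once and split into
    ``folds`` contiguous folds; each fold in turn is held out while an
    ensemble is trained on the rest (the last tenth of the training part
    serving as the members' validation split). Error reports are recorded
    for both roles (training fold and held-out fold). Returns the long
    table and the smallest size whose held-out errors are all below
    ``error_bar`` (None if no size qualifies).
    """
    cfg = cfg or TrainingConfig()
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be sorted ascending")
    rows = []
    selected: int | None = None
    for size in sizes:
        if size < folds:
            raise ValueError(f"size {size} smaller than fold count {folds}")
        design_x = sobol_design(size, space)
        design_y = simulator(design_x)
        fold_ids = np.arange(size) % folds
        worst_heldout = 0.0
        for fold in range(folds):
            held = fold_ids == fold
            tx, ty = design_x[~held], design_y[~held]
            hx, hy = design_x[held], design_y[held]
            ens, _ = build_ensemble(tx, None, cfg, design_y=ty, min_design=2)
            for role, x_, y_ in (("train", tx, ty), ("heldout", hx, hy)):
                rep = error_report(ens.predict(x_), y_)
                for out in METRIC_NAMES:
                    rows.append(
                        {
                            "size": size,
                            "fold": fold,
                            "role": role,
                            "output": out,
                            "nmae": rep.nmae[out],
                            "nrmse": rep.nrmse[out],
                            "ae95": rep.ae95[out],
                        }
                    )
                if role == "heldout":
                    worst_heldout = max(worst_heldout, rep.max_error())
        if selected is None and worst_heldout < error_bar:
            selected = size
    return pd.DataFrame(rows), selected
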