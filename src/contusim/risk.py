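"""Injury-risk evaluation of the four metrics against the in-vivo CCI
outcomes.

Fourteen controlled cortical impacts on porcine brain (packaged in
``data/table1_cases.csv``) carry a binary cortical-damage outcome. Each
case is pushed through a predict-capable model at its recorded depth and
velocity with the nominal probe (diameter 10 mm, hemispherical, zero
inclination, friction 0.163, DAM thickness 0.736 mm), and each metric is
evaluated as a contusion predictor with:

* an exact two-sided Wilcoxon rank-sum test (full enumeration of group
  labelings, mid-ranks for ties) between damaged and undamaged cases;
* a univariate logistic risk curve p(X) = 1 / (1 + exp(-(b0 + b1 X)))
  whose 50%-risk point -b0/b1 is the metric's injury threshold;
* leave-one-out cross-validation: accuracy / sensitivity / specificity at
  the 0.5 probability cutoff, the AUC of the pooled held-out predictions
  (testing) and the per-fold training AUCs (mean, sd, best, worst).

Note the model is deterministic, so the two cases with identical inputs
but opposite outcomes are forced onto identical predicted metrics: no
metric can separate them, at least one LOOCV misclassification is
structural, and the full-data logistic fit can never be completely
separated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from math import comb, log

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from .params import (
    NOMINAL_FRICTION,
    NOMINAL_THICKNESS,
    PARAM_NAMES,
    BOUNDS,
)
from .standin import METRIC_NAMES

__all__ = [
    "CaseRecord",
    "load_cases",
    "predict_cases",
    "wilcoxon_rank_sum_exact",
    "InjuryRiskModel",
    "fit_logistic",
    "risk_threshold",
    "roc_auc",
    "LoocvReport",
    "loocv_evaluate",
    "evaluate_all_metrics",
    "MetricEvaluation",
    "summary_table",
    "NOMINAL_CASE",
]

#: Nominal (non-case-specific) impact parameters used for every case.
NOMINAL_CASE = {
    "d_probe": 10.0,
    "shape": 1.0,
    "theta": 0.0,
    "mu_f": NOMINAL_FRICTION,
    "t_m": NOMINAL_THICKNESS,
}

_SEPARATION_CAP = 50.0  # |coefficient| cap on standardized x when separated


@dataclass(frozen=True)
class CaseRecord:
    """One in-vivo CCI case."""

    animal: str
    depth_mm: float
    velocity_mps: float
    damage: int

    def __post_init__(self) -> None:
        if self.damage not in (0, 1):
            raise ValueError(f"case {self.animal}: damage must be 0 or 1")
        for name, value in (("d_ind", self.depth_mm), ("v_ind", self.velocity_mps)):
            lo, hi = BOUNDS[name]
            if not (lo <= value <= hi):
                raise ValueError(
                    f"case {self.animal}: {name} = {value} outside [{lo}, {hi}]"
                )


def load_cases() -> list[CaseRecord]:
    """The 14 packaged CCI cases."""
    with resources.files("contusim.data").joinpath("table1_cases.csv").open() as fh:
        frame = pd.read_csv(fh)
    return [
        CaseRecord(
            animal=str(r["animal"]),
            depth_mm=float(r["depth_mm"]),
            velocity_mps=float(r["velocity_mps"]),
            damage=int(r["damage"]),
        )
        for _, r in frame.iterrows()
    ]


def predict_cases(
    model, cases: list[CaseRecord] | None = None, nominal: dict | None = None
) -> pd.DataFrame:
    """Evaluate the model at each case's depth/velocity with the nominal
    probe settings; order-preserving, one output row per case."""
    cases = cases if cases is not None else load_cases()
    if not cases:
        raise ValueError("no cases given")
    overrides = {**NOMINAL_CASE, **(nominal or {})}
    rows = []
    for case in cases:
        point = dict(overrides)
        point["d_ind"] = case.depth_mm
        point["v_ind"] = case.velocity_mps
        rows.append([point[name] for name in PARAM_NAMES])
    frame = pd.DataFrame(rows, columns=list(PARAM_NAMES))
    try:
        metrics = model.predict(frame)
    except ValueError as exc:
        raise ValueError(f"case evaluation failed: {exc}") from exc
    metrics = metrics.copy()
    metrics.insert(0, "animal", [c.animal for c in cases])
    metrics["damage"] = [c.damage for c in cases]
    return metrics


def wilcoxon_rank_sum_exact(a, b) -> float:
    """Exact two-sided rank-sum p-value by full enumeration.

    Mid-ranks are assigned on the pooled observed values; the p-value is
    the null probability that the first group's rank sum deviates from its
    expectation at least as much as observed. Enumeration covers
    C(n_a + n_b, min group) labelings (intended for min group <= 12 and
    combined n <= 25).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n = a.size, a.size + b.size
    if n > 25 or min(n_a, n - n_a) > 12:
        raise ValueError("exact enumeration limited to combined n <= 25, min group <= 12")
    ranks = rankdata(np.concatenate([a, b]))  # mid-ranks for ties
    t_obs = ranks[:n_a].sum()
    expect = n_a * (n + 1) / 2.0
    dev = abs(t_obs - expect)
    total = comb(n, n_a)
    hits = sum(
        1
        for subset in combinations(range(n), n_a)
        if abs(ranks[list(subset)].sum() - expect) >= dev - 1e-9
    )
    return hits / total


@dataclass(frozen=True)
class InjuryRiskModel:
    """Univariate logistic injury-risk curve for one metric."""

    metric: str
    b0: float
    b1: float
    converged: bool
    separation: bool

    def probability(self, x) -> np.ndarray:
        z = self.b0 + self.b1 * np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))

    @property
    def threshold50(self) -> float:
        return risk_threshold(self)


def fit_logistic(x, y, metric: str = "") -> InjuryRiskModel:
    """Maximum-likelihood univariate logistic fit (IRLS).

    Degenerate constant x gives the no-information fit (b1 = 0, b0 the
    log-odds of prevalence). Complete separation is detected and the
    coefficients are capped at |b| = 50 on standardized x, with the model
    flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcomes must contain both classes")
    if np.ptp(x) == 0:
        prevalence = y.mean()
        return InjuryRiskModel(metric, log(prevalence / (1 - prevalence)), 0.0,
                               converged=True, separation=False)
    # standardize for numeric conditioning; back-transform afterwards
    mu, sd = x.mean(), x.std()
    xs = (x - mu) / sd
    X = sm.add_constant(xs)
    # complete separation: the two classes occupy disjoint x half-lines
    pos, neg = x[y == 1], x[y == 0]
    separation = bool(pos.min() > neg.max() or pos.max() < neg.min())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            c0, c1 = float(res.params[0]), float(res.params[1])
            converged = bool(res.converged)
        except Exception:
            c0, c1, converged = 0.0, 0.0, False
    if abs(c0) > _SEPARATION_CAP or abs(c1) > _SEPARATION_CAP or not converged:
        separation = True
    if separation:
        c0 = float(np.clip(c0, -_SEPARATION_CAP, _SEPARATION_CAP))
        c1 = float(np.clip(c1, -_SEPARATION_CAP, _SEPARATION_CAP))
    # un-standardize: z = c0 + c1 (x - mu)/sd = (c0 - c1 mu/sd) + (c1/sd) x
    b1 = c1 / sd
    b0 = c0 - c1 * mu / sd
    return InjuryRiskModel(metric, b0, b1, converged=converged, separation=separation)


def risk_threshold(model: InjuryRiskModel) -> float:
    """Metric value at 50% injury risk, -b0/b1."""
    if model.b1 == 0:
        raise ValueError("threshold undefined: flat risk curve (b1 = 0)")
    if model.separation:
        raise ValueError("threshold unreliable: complete separation flagged")
    return -model.b0 / model.b1


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney formulation; ties get half
    credit)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class LoocvReport:
    """Leave-one-out cross-validation scores at the 0.5 cutoff."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc_testing: float
    auc_training_mean: float
    auc_training_sd: float
    auc_training_best: float
    auc_training_worst: float
    n_folds: int
    skipped_folds: int


def loocv_evaluate(x, y, metric: str = "") -> tuple[LoocvReport, list[InjuryRiskModel]]:
    """LOOCV of the univariate logistic classifier.

    Each fold fits on n-1 cases and predicts the held-out probability;
    folds whose training data lose a class are flagged and skipped with a
    warning. Returns the score report and the per-fold risk curves.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(x)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 cases")
    held_prob = np.full(n, np.nan)
    train_aucs = []
    fold_models: list[InjuryRiskModel] = []
    skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(set(y[mask].tolist())) < 2:
            warnings.warn(f"fold {i}: single-class training data, skipped", stacklevel=2)
            skipped += 1
            continue
        fold = fit_logistic(x[mask], y[mask], metric=metric)
        fold_models.append(fold)
        held_prob[i] = fold.probability(x[i])
        train_aucs.append(roc_auc(fold.probability(x[mask]), y[mask]))
    valid = ~np.isnan(held_prob)
    pred = (held_prob[valid] >= 0.5).astype(int)
    truth = y[valid]
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    train_aucs = np.asarray(train_aucs)
    report = LoocvReport(
        accuracy=(tp + tn) / max(len(truth), 1),
        sensitivity=tp / max(tp + fn, 1),
        specificity=tn / max(tn + fp, 1),
        auc_testing=roc_auc(held_prob[valid], truth),
        auc_training_mean=float(train_aucs.mean()),
        auc_training_sd=float(train_aucs.std(ddof=1)) if len(train_aucs) > 1 else 0.0,
        auc_training_best=float(train_aucs.max()),
        auc_training_worst=float(train_aucs.min()),
        n_folds=n,
        skipped_folds=skipped,
    )
    return report, fold_models


@dataclass(frozen=True)
class MetricEvaluation:
    """Full evaluation of one injury metric as a contusion predictor."""

    metric: str
    wilcoxon_p: float
    risk_model: InjuryRiskModel
    loocv: LoocvReport
    fold_models: list[InjuryRiskModel]


def evaluate_all_metrics(
    model, cases: list[CaseRecord] | None = None
) -> dict[str, MetricEvaluation]:
    """Run the full predictor-evaluation pipeline for all four metrics."""
    table = predict_cases(model, cases)
    y = table["damage"].to_numpy(dtype=int)
    out: dict[str, MetricEvaluation] = {}
    for name in METRIC_NAMES:
        x = table[name].to_numpy(dtype=float)
        p = wilcoxon_rank_sum_exact(x[y == 1], x[y == 0])
        risk = fit_logistic(x, y, metric=name)
        loocv, folds = loocv_evaluate(x, y, metric=name)
        out[name] = MetricEvaluation(
            metric=name, wilcoxon_p=p, risk_model=risk, loocv=loocv, fold_models=folds
        )
    return out


def summary_table(evaluations: dict[str, "MetricEvaluation"]) -> pd.DataFrame:
    """One row per metric: Wilcoxon p, logistic coefficients, 50%-risk
    threshold (NaN when undefined), and the LOOCV scores."""
    rows = []
    for name, ev in evaluations.items():
        try:
            thr = risk_threshold(ev.risk_model)
        except ValueError:
            thr = np.nan
        rows.append(
            {
                "metric": name,
                "wilcoxon_p": ev.wilcoxon_p,
                "b0": ev.risk_model.b0,
                "b1": ev.risk_model.b1,
                "threshold50": thr,
                "accuracy": ev.loocv.accuracy,
                "sensitivity": ev.loocv.sensitivity,
                "specificity": ev.loocv.specificity,
                "auc_testing": ev.loocv.auc_testing,
                "auc_training_mean": ev.loocv.auc_training_mean,
                "auc_training_sd": ev.loocv.auc_training_sd,
                "auc_training_best": ev.loocv.auc_training_best,
                "auc_training_worst": ev.loocv.auc_training_worst,
            }
        )
    return pd.DataFrame(rows)
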