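"""Classifier training, validation protocols and imbalance-aware metrics.

Three lightweight classifier families are supported — SVM, k-nearest
neighbors and a boosted-tree ensemble — each tuned by a small sequential
model-based (Bayesian) optimizer that minimizes stratified 5-fold
misclassification over a declared hyperparameter space.

Two validation protocols mirror the study design:

* subject-dependent: per-subject stratified k-fold cross-validation,
  reporting fold-averaged validation metrics;
* subject-independent: leave-one-subject-out (LOSO) — the held-out
  subject never influences scaling statistics computed across subjects,
  hyperparameter choice or the model fit.

Metrics are accuracy, AUC (the probability that a positive instance
outscores a negative one, ties credited 0.5), Gmean (geometric mean of
sensitivity and specificity) and F1; per-model results aggregate as the
mean and the mean absolute deviation (MAD) around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .io import ValidationError

ALGORITHMS = ("svm", "knn", "ens")
METRIC_NAMES = ("acc", "auc", "gmean", "f1")


# ---------------------------------------------------------------------------
# Confusion matrix and metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion matrix counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class MetricSet:
    acc: float
    auc: float
    gmean: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "auc": self.auc, "gmean": self.gmean, "f1": self.f1}


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """P(score of a positive > score of a negative), ties credited 0.5.

    A constant scorer therefore gets 0.5.  Requires both classes present.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(y_true) == 0:
        raise ValidationError("empty truth vector")
    if len(np.unique(y_true)) < 2:
        warnings.warn("AUC undefined with a single-class truth; returning 0.5", stacklevel=2)
        return 0.5
    return float(roc_auc_score(y_true, scores))


def compute_metrics(
    cm: ConfusionMatrix, scores: np.ndarray | None = None, y_true: np.ndarray | None = None
) -> MetricSet:
    """ACC, AUC, Gmean and F1 from a confusion matrix plus decision scores.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); a class absent from
    the truth makes its rate 0 (and F1 is 0 when TP = 0 with errors
    present).  AUC needs ``scores`` and ``y_true``; without them it is
    computed as NaN.
    """
    acc = (cm.tp + cm.tn) / cm.total
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else 0.0
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else 0.0
    gmean = float(np.sqrt(sens * spec))
    denom = 2 * cm.tp + cm.fp + cm.fn
    f1 = 2 * cm.tp / denom if denom > 0 else 0.0
    auc = auc_score(y_true, scores) if scores is not None and y_true is not None else float("nan")
    return MetricSet(acc=float(acc), auc=float(auc), gmean=gmean, f1=float(f1))


def confusion_report(cm: ConfusionMatrix) -> dict:
    """3x3 annotated confusion layout (rows = predicted, columns = true).

    Cells: [TN, FP, false omission rate], [FN, TP, precision],
    [false negative rate, specificity, accuracy].  Rates are fractions.
    """

    def _rate(num: int, den: int) -> float:
        return num / den if den > 0 else 0.0

    false_omission = _rate(cm.fn, cm.fn + cm.tn)
    precision = _rate(cm.tp, cm.tp + cm.fp)
    fnr = _rate(cm.fn, cm.fn + cm.tp)
    specificity = _rate(cm.tn, cm.tn + cm.fp)
    accuracy = (cm.tp + cm.tn) / cm.total
    grid = [
        [cm.tn, cm.fp, false_omission],
        [cm.fn, cm.tp, precision],
        [fnr, specificity, accuracy],
    ]
    text = (
        f"            true 0    true 1\n"
        f"pred 0    {cm.tn:8d}  {cm.fp:8d}   FOR={false_omission:.2%}\n"
        f"pred 1    {cm.fn:8d}  {cm.tp:8d}   PPV={precision:.2%}\n"
        f"          FNR={fnr:.2%}  SPC={specificity:.2%}  ACC={accuracy:.2%}"
    )
    return {"grid": grid, "text": text, "counts": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn}}


def aggregate_models(metric_sets: Sequence[MetricSet]) -> dict[str, dict[str, float]]:
    """Mean and mean absolute deviation (around the mean) per metric."""
    if not metric_sets:
        raise ValidationError("no models to aggregate")
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in metric_sets], dtype=float)
        mean = float(np.mean(vals))
        out[name] = {"mean": mean, "mad": float(np.mean(np.abs(vals - mean)))}
    return out


# ---------------------------------------------------------------------------
# Normalization and splits


def zscore_by_subject(table: pd.DataFrame, feature_cols: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-subject, per-feature z-scoring: (x - subject mean) / subject SD.

    Zero-SD features within a subject pass through as 0 with a warning;
    a single-sample subject is an error.
    """
    if feature_cols is None:
        feature_cols = [
            c
            for c in table.columns
            if c not in ("subject_id", "trial_id", "window_index", "fear_label")
        ]
    sizes = table.groupby("subject_id").size()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValidationError(f"subjects with a single sample cannot be z-scored: {bad}")
    out = table.copy()

    def _z(g: pd.DataFrame) -> pd.DataFrame:
        mu = g.mean()
        sd = g.std(ddof=1)
        zero = sd == 0
        if zero.any():
            warnings.warn(
                f"zero-variance features pass through as 0: {list(sd.index[zero])}",
                stacklevel=3,
            )
        z = (g - mu) / sd.where(~zero, 1.0)
        if zero.any():
            z.loc[:, list(sd.index[zero])] = 0.0
        return z

    out[list(feature_cols)] = (
        table.groupby("subject_id", group_keys=False)[list(feature_cols)].apply(_z)
    )
    return out


@dataclass(frozen=True)
class SplitPlan:
    scheme: str  # "stratified_kfold" | "loso"
    k: int = 5
    seed: int = 0
    held_out_subject: str | None = None


def make_splits(table: pd.DataFrame, plan: SplitPlan) -> list[dict]:
    """Index sets for a validation plan over a feature table.

    ``stratified_kfold`` yields ``k`` train/validation splits preserving
    the class ratio.  ``loso`` yields one plan per subject (or only
    ``held_out_subject``): the held-out subject's rows form the test set
    and appear nowhere in training.
    """
    y = table["fear_label"].to_numpy()
    idx = np.arange(len(table))
    if plan.scheme == "stratified_kfold":
        counts = np.bincount(y, minlength=2)
        if counts.min() < plan.k:
            raise ValidationError(
                f"minority class has {counts.min()} samples; cannot stratify into {plan.k} folds"
            )
        skf = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
        return [
            {"train": idx[tr], "validation": idx[va]} for tr, va in skf.split(idx.reshape(-1, 1), y)
        ]
    if plan.scheme == "loso":
        subjects = table["subject_id"].unique()
        if len(subjects) < 3:
            raise ValidationError("LOSO needs at least 3 subjects")
        targets = [plan.held_out_subject] if plan.held_out_subject is not None else list(subjects)
        plans = []
        for s in targets:
            test = idx[table["subject_id"].to_numpy() == s]
            train = idx[table["subject_id"].to_numpy() != s]
            plans.append({"subject": s, "train": train, "test": test})
        return plans
    raise ValidationError(f"unknown split scheme {plan.scheme!r}")


# ---------------------------------------------------------------------------
# Sequential model-based (Bayesian) hyperparameter optimization


@dataclass(frozen=True)
class Real:
    name: str
    low: float
    high: float
    log: bool = False

    def decode(self, u: float) -> float:
        if self.log:
            return float(self.low * (self.high / self.low) ** u)
        return float(self.low + u * (self.high - self.low))


@dataclass(frozen=True)
class Integer:
    name: str
    low: int
    high: int

    def decode(self, u: float) -> int:
        return int(np.clip(round(self.low + u * (self.high - self.low)), self.low, self.high))


@dataclass(frozen=True)
class Categorical:
    name: str
    choices: tuple

    def decode(self, u: float) -> object:
        i = min(int(u * len(self.choices)), len(self.choices) - 1)
        return self.choices[i]


def _decode(space: Sequence, u: np.ndarray) -> dict:
    return {dim.name: dim.decode(float(v)) for dim, v in zip(space, u)}


def smbo_minimize(
    objective: Callable[[dict], float],
    space: Sequence,
    n_calls: int = 30,
    n_initial: int = 8,
    seed: int = 0,
    n_candidates: int = 256,
) -> dict:
    """Sequential model-based optimization with a GP surrogate and EI.

    Random exploration for ``n_initial`` evaluations, then a Matern-5/2
    Gaussian-process surrogate on the unit cube proposes the
    expected-improvement maximizer among random candidates.  Deterministic
    given ``seed``.  Returns the best parameters, value and full history.
    """
    rng = np.random.default_rng(seed)
    d = len(space)
    n_initial = min(n_initial, n_calls)
    U: list[np.ndarray] = []
    Y: list[float] = []
    for _ in range(n_initial):
        u = rng.random(d)
        U.append(u)
        Y.append(float(objective(_decode(space, u))))
    kernel = Matern(length_scale=np.full(d, 0.25), nu=2.5) + WhiteKernel(1e-6, (1e-8, 1e-1))
    while len(Y) < n_calls:
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31 - 1))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.vstack(U), np.array(Y))
        cand = rng.random((n_candidates, d))
        mu, sigma = gp.predict(cand, return_std=True)
        best = min(Y)
        sigma = np.maximum(sigma, 1e-12)
        imp = best - mu
        z = imp / sigma
        ei = imp * norm.cdf(z) + sigma * norm.pdf(z)
        u = cand[int(np.argmax(ei))]
        U.append(u)
        Y.append(float(objective(_decode(space, u))))
    i_best = int(np.argmin(Y))
    return {
        "best_params": _decode(space, U[i_best]),
        "best_value": Y[i_best],
        "history": [(_decode(space, u), y) for u, y in zip(U, Y)],
    }


def _space_and_factory(algorithm: str, seed: int, max_neighbors: int | None = None):
    if algorithm == "svm":
        space = [
            Categorical("kernel", ("rbf", "linear")),
            Real("C", 1e-3, 1e3, log=True),
            Real("gamma", 1e-3, 1e1, log=True),
        ]

        def factory(p):
            return SVC(kernel=p["kernel"], C=p["C"], gamma=p["gamma"], random_state=seed)

    elif algorithm == "knn":
        space = [
            Integer("n_neighbors", 1, 30),
            Categorical("metric", ("euclidean", "cityblock")),
            Categorical("weights", ("uniform", "distance")),
        ]

        def factory(p):
            k = p["n_neighbors"] if max_neighbors is None else min(p["n_neighbors"], max_neighbors)
            return KNeighborsClassifier(n_neighbors=k, metric=p["metric"], weights=p["weights"])

    elif algorithm == "ens":
        space = [
            Integer("n_estimators", 10, 300),
            Integer("max_depth", 1, 8),
            Real("learning_rate", 0.01, 1.0, log=True),
        ]

        def factory(p):
            return GradientBoostingClassifier(
                n_estimators=p["n_estimators"],
                max_depth=p["max_depth"],
                learning_rate=p["learning_rate"],
                random_state=seed,
            )

    else:
        raise ValidationError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return space, factory


@dataclass
class TrainedModel:
    algorithm: str
    estimator: object
    params: dict
    cv_error: float
    seed: int

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous decision values for AUC (probability of the positive class
        where available, otherwise the decision function)."""
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X)[:, 1]
        return self.estimator.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


def tune_and_train(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str = "svm",
    budget: int = 30,
    seed: int = 0,
    cv_folds: int = 5,
) -> TrainedModel:
    """Tune hyperparameters by SMBO over stratified CV misclassification, then fit.

    The objective is the mean stratified ``cv_folds``-fold misclassification
    rate on the training data; the search is deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both classes")
    # a CV fold trains on (cv_folds-1)/cv_folds of the data; neighbors must fit
    max_neighbors = max(1, len(y) * (cv_folds - 1) // cv_folds - 1)
    space, factory = _space_and_factory(algorithm, seed, max_neighbors=max_neighbors)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)

    def objective(params: dict) -> float:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                acc = cross_val_score(factory(params), X, y, cv=skf, scoring="accuracy")
            return float(1.0 - acc.mean())
        except Exception:
            return 1.0  # infeasible configuration (e.g., k > fold size)

    result = smbo_minimize(objective, space, n_calls=budget, seed=seed)
    est = factory(result["best_params"])
    est.fit(X, y)
    return TrainedModel(
        algorithm=algorithm,
        estimator=est,
        params=result["best_params"],
        cv_error=result["best_value"],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Validation protocols


def _feature_matrix(table: pd.DataFrame, feature_cols: Sequence[str] | None = None):
    if feature_cols is None:
        feature_cols = [
            c
            for c in table.columns
            if c not in ("subject_id", "trial_id", "window_index", "fear_label")
        ]
    X = table[list(feature_cols)].to_numpy(dtype=float)
    y = table["fear_label"].to_numpy().astype(int)
    return X, y


def subject_dependent_eval(
    table: pd.DataFrame,
    algorithm: str = "ens",
    k: int = 5,
    budget: int = 30,
    seed: int = 0,
    feature_cols: Sequence[str] | None = None,
) -> dict:
    """Per-subject stratified k-fold validation with tuned hyperparameters.

    For each subject, hyperparameters are tuned on that subject's data via
    internal stratified CV, then metrics are computed on each validation
    fold and averaged over folds.  Returns per-subject results plus the
    mean/MAD aggregate across subjects.
    """
    per_subject = []
    metric_sets = []
    for subject, g in table.groupby("subject_id", sort=False):
        X, y = _feature_matrix(g, feature_cols)
        model = tune_and_train(X, y, algorithm, budget=budget, seed=seed)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_metrics = []
        counts = np.zeros(4, dtype=int)  # tp, tn, fp, fn
        for tr, va in skf.split(X, y):
            est = clone(model.estimator)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[va])
            fold_model = TrainedModel(algorithm, est, model.params, model.cv_error, seed)
            sc = fold_model.scores(X[va])
            cm = ConfusionMatrix.from_predictions(y[va], pred)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fold_metrics.append(compute_metrics(cm, sc, y[va]))
            counts += np.array([cm.tp, cm.tn, cm.fp, cm.fn])
        mean_metrics = MetricSet(
            **{
                name: float(np.mean([getattr(m, name) for m in fold_metrics]))
                for name in METRIC_NAMES
            }
        )
        metric_sets.append(mean_metrics)
        per_subject.append(
            {
                "subject": subject,
                "metrics": mean_metrics,
                "cm": ConfusionMatrix(*counts),
                "params": model.params,
            }
        )
    return {
        "mode": "subject_dependent",
        "algorithm": algorithm,
        "seed": seed,
        "per_model": per_subject,
        "aggregate": aggregate_models(metric_sets),
    }


def loso_eval(
    table: pd.DataFrame,
    algorithm: str = "ens",
    budget: int = 30,
    seed: int = 0,
    zscore: bool = True,
    feature_cols: Sequence[str] | None = None,
) -> dict:
    """Leave-one-subject-out evaluation of subject-independent models.

    Optionally z-scores each subject against its own statistics first
    (a per-subject transform, so the held-out subject never contributes to
    any cross-subject statistic).  For each subject, hyperparameters are
    tuned and the model fitted on the remaining subjects only, then tested
    on the unseen subject.
    """
    if zscore:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = zscore_by_subject(table, feature_cols)
    plans = make_splits(table, SplitPlan(scheme="loso", seed=seed))
    per_model = []
    metric_sets = []
    for plan in plans:
        train, test = table.iloc[plan["train"]], table.iloc[plan["test"]]
        Xtr, ytr = _feature_matrix(train, feature_cols)
        Xte, yte = _feature_matrix(test, feature_cols)
        model = tune_and_train(Xtr, ytr, algorithm, budget=budget, seed=seed)
        pred = model.predict(Xte)
        sc = model.scores(Xte)
        cm = ConfusionMatrix.from_predictions(yte, pred)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = compute_metrics(cm, sc, yte)
        metric_sets.append(metrics)
        per_model.append(
            {"subject": plan["subject"], "metrics": metrics, "cm": cm, "params": model.params}
        )
    return {
        "mode": "subject_independent",
        "algorithm": algorithm,
        "seed": seed,
        "per_model": per_model,
        "aggregate": aggregate_models(metric_sets),
    }
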