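"""Classifier families, cross-validated evaluation, and model selection.

The classifier registry holds the nine configurations compared in this
pipeline: a Gini decision tree capped at 100 splits, linear and quadratic
discriminant analysis, k-nearest neighbors with Euclidean distance (k = 1
and k = 10), support vector machines with linear and quadratic kernels
(box constraint 1), a kernel-density naive Bayes (Gaussian kernel), and
bagged trees (30 fully grown Gini trees on bootstrap resamples).

Evaluation pools out-of-fold predictions from a stratified 10-fold
cross-validation into a single confusion matrix, from which accuracy,
per-class true rates (THR/TMR/TLR), one-vs-rest ROC/AUC, and Cohen's kappa
with its Landis–Koch interpretation band are derived.  Distance- and
kernel-based models receive per-feature standardization fitted on the
training folds only; tree models are scale-free and take raw features.

By default folds are stratified over windows, which can place windows of
the same subject in both train and test folds; pass ``groups`` (subject
ids) for leakage-safe grouped folding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASS_ORDER",
    "ClassifierConfig",
    "default_configs",
    "KernelDensityNB",
    "FittedModel",
    "ModelDegeneracyError",
    "train",
    "kfold_cv",
    "cohens_kappa",
    "KappaResult",
    "landis_koch_band",
    "per_class_rates",
    "roc_curves",
    "EvaluationReport",
    "sequential_forward_selection",
    "ModelCandidate",
    "select_models",
    "save_model",
    "load_model",
]

#: canonical class order for confusion matrices and reports
CLASS_ORDER = ("low", "medium", "high")

FAMILIES = ("decision_tree", "lda", "qda", "knn", "svm", "naive_bayes", "bagged_trees")


class ModelDegeneracyError(ValueError):
    """A model cannot be fitted on this data (e.g. singular class covariance)."""


@dataclass(frozen=True)
class ClassifierConfig:
    """One classifier family with its hyperparameters.

    ``metadata`` records printed options that are inert for the actual
    algorithm (e.g. a learning rate for bagging) without applying them.
    """

    family: str
    params: Mapping = field(default_factory=dict)
    metadata: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def name(self) -> str:
        bits = "_".join(f"{k}-{v}" for k, v in sorted(self.params.items()))
        return f"{self.family}{('_' + bits) if bits else ''}"


def default_configs() -> list[ClassifierConfig]:
    """The nine enumerated classifier configurations."""
    return [
        ClassifierConfig("decision_tree", {"max_splits": 100, "criterion": "gini"}),
        ClassifierConfig("lda"),
        ClassifierConfig("qda"),
        ClassifierConfig("knn", {"k": 1}),
        ClassifierConfig("knn", {"k": 10}),
        ClassifierConfig("svm", {"kernel": "linear", "box_constraint": 1.0}),
        ClassifierConfig("svm", {"kernel": "quadratic", "box_constraint": 1.0}),
        ClassifierConfig("naive_bayes", {"kernel": "gaussian"}),
        ClassifierConfig(
            "bagged_trees", {"n_learners": 30},
            metadata={"learning_rate": 0.1, "subspace_dimension": 1},
        ),
    ]


class KernelDensityNB(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel density class conditionals.

    Each feature's class-conditional density is a kernel density estimate
    over the training values with a Silverman-rule bandwidth; class
    posteriors multiply the per-feature densities with the empirical prior.
    """

    def __init__(self, bandwidth_floor: float = 1e-3):
        self.bandwidth_floor = bandwidth_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._train = {}
        self._bandwidth = {}
        self._log_prior = {}
        n = len(y)
        for c in self.classes_:
            Xc = X[y == c]
            m = len(Xc)
            sd = np.std(Xc, axis=0, ddof=1) if m > 1 else np.zeros(X.shape[1])
            iqr = np.subtract(*np.percentile(Xc, [75, 25], axis=0)) / 1.34 if m > 1 else sd
            spread = np.where((iqr > 0) & (iqr < sd), iqr, sd)
            h = 0.9 * spread * m ** (-1 / 5)
            self._train[c] = Xc
            self._bandwidth[c] = np.maximum(h, self.bandwidth_floor)
            self._log_prior[c] = math.log(m / n)
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), len(self.classes_)))
        for j, c in enumerate(self.classes_):
            Xc, h = self._train[c], self._bandwidth[c]
            # (n_test, n_train, n_feat) Gaussian kernels, mean over train points
            z = (X[:, None, :] - Xc[None, :, :]) / h
            dens = np.exp(-0.5 * z * z).mean(axis=1) / (h * math.sqrt(2 * math.pi))
            out[:, j] = np.sum(np.log(np.maximum(dens, 1e-300)), axis=1) + self._log_prior[c]
        return out

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


def build_estimator(config: ClassifierConfig, seed: Optional[int] = None):
    """sklearn estimator (wrapped in a standardizing pipeline where the
    family is distance- or kernel-based)."""
    p = config.params
    scale = False
    if config.family == "decision_tree":
        est = DecisionTreeClassifier(
            criterion=p.get("criterion", "gini"),
            max_leaf_nodes=p.get("max_splits", 100) + 1,
            random_state=seed,
        )
    elif config.family == "lda":
        est = LinearDiscriminantAnalysis()
    elif config.family == "qda":
        est = QuadraticDiscriminantAnalysis(reg_param=p.get("reg_param", 0.0))
    elif config.family == "knn":
        est = KNeighborsClassifier(n_neighbors=p.get("k", 1), metric="euclidean")
        scale = True
    elif config.family == "svm":
        kernel = p.get("kernel", "linear")
        if kernel == "quadratic":
            est = SVC(kernel="poly", degree=2, coef0=1.0, C=p.get("box_constraint", 1.0),
                      probability=True, random_state=seed)
        else:
            est = SVC(kernel="linear", C=p.get("box_constraint", 1.0),
                      probability=True, random_state=seed)
        scale = True
    elif config.family == "naive_bayes":
        est = KernelDensityNB()
        scale = True
    elif config.family == "bagged_trees":
        est = BaggingClassifier(
            estimator=DecisionTreeClassifier(criterion="gini", random_state=seed),
            n_estimators=p.get("n_learners", 30),
            random_state=seed,
        )
    else:  # pragma: no cover - guarded by ClassifierConfig
        raise ValueError(config.family)
    if scale:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class FittedModel:
    """A trained classifier plus everything needed to apply it."""

    config: ClassifierConfig
    estimator: object
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    version: str = "1"

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float)))

    def predict_scores(self, X) -> pd.DataFrame:
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        return pd.DataFrame(proba, columns=list(self.estimator.classes_))


def _class_order(labels) -> list[str]:
    present = set(labels)
    ordered = [c for c in CLASS_ORDER if c in present]
    ordered += sorted(present - set(CLASS_ORDER))
    return ordered


def train(config: ClassifierConfig, X, y, seed: Optional[int] = None) -> FittedModel:
    """Fit one classifier; deterministic given ``seed``."""
    X = pd.DataFrame(X)
    y = np.asarray(y)
    classes = _class_order(y)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if config.family == "qda":
        counts = pd.Series(y).value_counts()
        if counts.min() <= X.shape[1]:
            raise ModelDegeneracyError(
                "QDA class covariance is singular (a class has no more observations "
                "than features); consider params={'reg_param': ...}"
            )
    est = build_estimator(config, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            est.fit(X.to_numpy(dtype=float), y)
        except np.linalg.LinAlgError as exc:
            raise ModelDegeneracyError(
                f"{config.family} fit failed on singular data: {exc}; "
                "consider regularization"
            ) from exc
    return FittedModel(config=config, estimator=est,
                       feature_names=tuple(X.columns.astype(str)),
                       classes=tuple(classes))


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class KappaResult:
    value: float
    band: str


def landis_koch_band(kappa: float) -> str:
    """Landis–Koch interpretation: left-open bands at 0.20/0.40/0.60/0.80."""
    if kappa < 0:
        return "no agreement"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def cohens_kappa(confusion) -> KappaResult:
    """Cohen's kappa from a confusion matrix (rows = true class).

    κ = (p_o − p_e)/(1 − p_e) with chance agreement p_e from the marginal
    products.  A degenerate single-cell matrix (p_e = 1) is defined as κ = 0
    with a warning.
    """
    M = np.asarray(confusion, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(M < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = M.sum()
    if total <= 0:
        raise ValueError("confusion matrix total must be positive")
    p_o = np.trace(M) / total
    p_e = float(np.sum(M.sum(axis=0) * M.sum(axis=1))) / total**2
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("degenerate confusion matrix (chance agreement = 1); kappa set to 0")
        kappa = 0.0
    else:
        kappa = float((p_o - p_e) / (1.0 - p_e))
    return KappaResult(value=kappa, band=landis_koch_band(kappa))


def per_class_rates(confusion, classes: Sequence[str]) -> dict[str, float]:
    """Per-class true rates (recall: diagonal over row sum); NaN for an
    empty true class."""
    M = np.asarray(confusion, dtype=float)
    rates = {}
    for i, c in enumerate(classes):
        row = M[i].sum()
        rates[c] = float(M[i, i] / row) if row > 0 else math.nan
    return rates


def per_class_precision(confusion, classes: Sequence[str]) -> dict[str, float]:
    M = np.asarray(confusion, dtype=float)
    out = {}
    for i, c in enumerate(classes):
        col = M[:, i].sum()
        out[c] = float(M[i, i] / col) if col > 0 else math.nan
    return out


def roc_curves(
    y_true,
    scores: pd.DataFrame,
    classes: Optional[Sequence[str]] = None,
    predictions=None,
) -> dict[str, dict]:
    """One-vs-rest ROC per class with trapezoidal AUC.

    When hard ``predictions`` are given, the operating point (FPR, TPR) of
    the discrete classifier is attached to each curve.
    """
    y_true = np.asarray(y_true)
    classes = list(classes) if classes is not None else _class_order(y_true)
    out = {}
    for c in classes:
        truth = (y_true == c).astype(int)
        fpr, tpr, thr = _roc_curve(truth, np.asarray(scores[c], dtype=float))
        entry = {"fpr": fpr, "tpr": tpr, "thresholds": thr, "auc": float(_auc(fpr, tpr))}
        if predictions is not None:
            pred = (np.asarray(predictions) == c).astype(int)
            tp = int(np.sum((pred == 1) & (truth == 1)))
            fp = int(np.sum((pred == 1) & (truth == 0)))
            p, n = int(truth.sum()), int(len(truth) - truth.sum())
            entry["operating_point"] = (fp / n if n else math.nan, tp / p if p else math.nan)
        out[c] = entry
    return out


@dataclass
class EvaluationReport:
    """Pooled cross-validation outcome.

    All scalar metrics are recomputable from ``confusion`` alone (see
    :meth:`recompute`); ROC curves additionally use the pooled class scores.
    """

    classes: tuple[str, ...]
    confusion: np.ndarray  # rows = true class, canonical order
    accuracy: float
    true_rates: dict[str, float]  # per-class recall (THR/TMR/TLR)
    precision: dict[str, float]
    kappa: float
    kappa_band: str
    roc: dict[str, dict] = field(default_factory=dict)
    n_obs: int = 0

    @classmethod
    def from_predictions(cls, y_true, y_pred, scores: Optional[pd.DataFrame] = None
                         ) -> "EvaluationReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        classes = _class_order(y_true)
        index = {c: i for i, c in enumerate(classes)}
        M = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            M[index[t], index[p]] += 1
        kap = cohens_kappa(M)
        roc = roc_curves(y_true, scores, classes, predictions=y_pred) if scores is not None else {}
        return cls(
            classes=tuple(classes),
            confusion=M,
            accuracy=float(np.trace(M) / M.sum()),
            true_rates=per_class_rates(M, classes),
            precision=per_class_precision(M, classes),
            kappa=kap.value,
            kappa_band=kap.band,
            roc=roc,
            n_obs=int(M.sum()),
        )

    def recompute(self) -> "EvaluationReport":
        """Self-consistency: rebuild all scalar metrics from the confusion matrix."""
        kap = cohens_kappa(self.confusion)
        return EvaluationReport(
            classes=self.classes,
            confusion=self.confusion,
            accuracy=float(np.trace(self.confusion) / self.confusion.sum()),
            true_rates=per_class_rates(self.confusion, self.classes),
            precision=per_class_precision(self.confusion, self.classes),
            kappa=kap.value,
            kappa_band=kap.band,
            roc=self.roc,
            n_obs=int(self.confusion.sum()),
        )

    def to_json_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "true_rates": self.true_rates,
            "precision": self.precision,
            "kappa": self.kappa,
            "kappa_band": self.kappa_band,
            "auc": {c: r["auc"] for c, r in self.roc.items()},
            "n_obs": self.n_obs,
        }


def kfold_cv(
    config: ClassifierConfig,
    X,
    y,
    k: int = 10,
    seed: Optional[int] = None,
    groups: Optional[Sequence] = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with pooled out-of-fold predictions.

    ``groups`` switches to grouped folding (no subject in both train and
    test of a fold) at the cost of stratification.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} observations, got {n}")
    counts = pd.Series(y).value_counts()
    stratifiable = counts.min() >= k
    if not stratifiable:
        warnings.warn(
            f"class {counts.idxmin()!r} has {counts.min()} < k={k} members; "
            "per-fold class presence not guaranteed"
        )
    classes = _class_order(y)
    if groups is not None:
        splitter = GroupKFold(n_splits=k)
        splits = splitter.split(X, y, groups=np.asarray(groups))
    elif stratifiable:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)

    oof_pred = np.empty(n, dtype=object)
    oof_scores = np.zeros((n, len(classes)))
    for tr, te in splits:
        model = train(config, X.iloc[tr], y[tr], seed)
        Xte = X.iloc[te].to_numpy(dtype=float)
        oof_pred[te] = model.predict(Xte)
        proba = model.predict_scores(Xte)
        for j, c in enumerate(classes):
            oof_scores[te, j] = proba[c] if c in proba.columns else 0.0
    scores = pd.DataFrame(oof_scores, columns=classes)
    return EvaluationReport.from_predictions(y, oof_pred, scores)


# ---------------------------------------------------------------------------
# Feature selection and model selection


def sequential_forward_selection(
    config: ClassifierConfig,
    X,
    y,
    seed: Optional[int] = None,
    k: int = 10,
) -> list[str]:
    """Greedy forward wrapper selection by cross-validated accuracy.

    Starts empty (reference level: the majority-class share) and adds the
    candidate feature with the best CV accuracy while the improvement is
    strict; deterministic given ``seed`` (candidates scanned in column
    order, ties keep the earliest)."""
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("sequential selection needs at least two features")
    y = np.asarray(y)
    best_acc = pd.Series(y).value_counts().max() / len(y)
    selected: list[str] = []
    remaining = list(X.columns)
    while remaining:
        best_cand, best_cand_acc = None, best_acc
        for cand in remaining:
            rep = kfold_cv(config, X[selected + [cand]], y, k=k, seed=seed)
            if rep.accuracy > best_cand_acc:
                best_cand, best_cand_acc = cand, rep.accuracy
        if best_cand is None:
            break
        selected.append(best_cand)
        remaining.remove(best_cand)
        best_acc = best_cand_acc
    return selected


@dataclass(frozen=True)
class ModelCandidate:
    config: ClassifierConfig
    features: tuple[str, ...]
    approach: str
    report: EvaluationReport


def select_models(
    candidates: Sequence[ModelCandidate],
    balance_threshold: float = 0.25,
) -> list[ModelCandidate]:
    """Rank candidates: balanced per-class rates first (spread of true rates
    at most ``balance_threshold``), then accuracy, then fewer features."""

    def spread(c: ModelCandidate) -> float:
        rates = [r for r in c.report.true_rates.values() if not math.isnan(r)]
        return (max(rates) - min(rates)) if rates else math.inf

    def key(c: ModelCandidate):
        return (spread(c) > balance_threshold, -c.report.accuracy, len(c.features))

    return sorted(candidates, key=key)


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: FittedModel, path) -> None:
    import joblib

    joblib.dump(
        {
            "config": {"family": model.config.family, "params": dict(model.config.params),
                       "metadata": dict(model.config.metadata)},
            "estimator": model.estimator,
            "feature_names": list(model.feature_names),
            "classes": list(model.classes),
            "version": model.version,
        },
        path,
    )


def load_model(path) -> FittedModel:
    import joblib

    blob = joblib.load(path)
    return FittedModel(
        config=ClassifierConfig(**blob["config"]),
        estimator=blob["estimator"],
        feature_names=tuple(blob["feature_names"]),
        classes=tuple(blob["classes"]),
        version=blob.get("version", "1"),
    )
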