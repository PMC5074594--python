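"""Logistic animal/plant classification of pre-miRNA hairpins.

Houses the published four-feature logistic model

    Logit(P) = 6.1436 + 0.0893*x1 - 0.0691*x2 - 0.0241*x3 + 0.0263*x4

where P is the probability that a hairpin is an animal pre-miRNA, x1 the
helix number, x2 the stack number, x3 the precursor length and x4 the
minimum free energy — plus de-novo maximum-likelihood training (IRLS),
the ZeroR majority-class baseline, and stratified k-fold cross-validated
evaluation with Weka-style class-size-weighted metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES, FeatureTable

__all__ = [
    "LogisticModel",
    "ZeroRModel",
    "FitResult",
    "EvalReport",
    "PerfectSeparationError",
    "published_model",
    "PUBLISHED_FEATURES",
    "predict",
    "train_logistic",
    "zero_r",
    "cross_validate",
    "roc_area",
    "read_model",
    "write_model",
]

#: the four features of the published model, in x1..x4 order
PUBLISHED_FEATURES = ("n_helix", "n_stack", "length", "MFE")


class PerfectSeparationError(RuntimeError):
    """IRLS diverged because the classes are linearly separable."""


@dataclass
class LogisticModel:
    """Logistic model: P(positive) = 1 / (1 + exp(-(b0 + sum b_i x_i)))."""

    intercept: float
    coefficients: dict[str, float]
    positive_label: str = "animal"
    negative_label: str = "plant"

    def __post_init__(self) -> None:
        unknown = [n for n in self.coefficients if n not in FEATURE_NAMES]
        if unknown:
            raise ValueError(f"coefficients for unknown features: {unknown}")
        values = [self.intercept, *self.coefficients.values()]
        if not all(math.isfinite(v) for v in values):
            raise ValueError("non-finite model parameters")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def linear_predictor(self, fv) -> float:
        """Logit of one feature vector (mapping or pandas Series)."""
        z = self.intercept
        for name, beta in self.coefficients.items():
            if name not in fv:
                raise KeyError(f"feature vector is missing model feature {name!r}")
            x = float(fv[name])
            if math.isnan(x):
                raise ValueError(f"model feature {name!r} is missing (NaN)")
            z += beta * x
        return z

    def predict_proba(self, fv) -> float:
        """P(positive label) for one feature vector."""
        return 1.0 / (1.0 + math.exp(-self.linear_predictor(fv)))

    def predict_label(self, fv, threshold: float = 0.5) -> str:
        return self.positive_label if self.predict_proba(fv) >= threshold else self.negative_label

    def predict_proba_table(self, values: pd.DataFrame) -> np.ndarray:
        X = values[list(self.features)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing values in model feature columns")
        z = self.intercept + X @ np.array(list(self.coefficients.values()))
        return 1.0 / (1.0 + np.exp(-z))


def published_model() -> LogisticModel:
    """The published four-feature animal-vs-plant logistic model.

    Intercept 6.1436; coefficients +0.0893 (helix number), -0.0691 (stack
    number), -0.0241 (precursor length), +0.0263 (MFE).  P is the
    probability of the animal class.
    """
    return LogisticModel(
        intercept=6.1436,
        coefficients={
            "n_helix": 0.0893,
            "n_stack": -0.0691,
            "length": -0.0241,
            "MFE": 0.0263,
        },
        positive_label="animal",
        negative_label="plant",
    )


def predict(model: LogisticModel, fv) -> float:
    """Probability of the model's positive label for one feature vector."""
    return model.predict_proba(fv)


# ---------------------------------------------------------------------------
# Training


@dataclass
class FitResult:
    model: LogisticModel
    standard_errors: np.ndarray  # intercept first, then coefficients in order
    n_iter: int
    converged: bool
    log_likelihood: float


def _irls(X: np.ndarray, y: np.ndarray, tol: float, max_iter: int, ridge: float):
    n, p = X.shape
    beta = np.zeros(p)
    penalty = ridge * np.eye(p)
    penalty[0, 0] = 0.0  # intercept unpenalised
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        xtwx = X.T @ (w[:, None] * X)
        try:
            beta_new = np.linalg.solve(xtwx + penalty, X.T @ (w * z))
        except np.linalg.LinAlgError as exc:
            raise PerfectSeparationError(
                "singular weighted design (likely separation); retry with ridge>0"
            ) from exc
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
        if ridge == 0 and np.max(np.abs(beta)) > 1e4:
            raise PerfectSeparationError(
                "coefficients diverging: classes appear perfectly separable; "
                "retry with ridge (e.g. 1e-6)"
            )
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    if ridge == 0 and np.allclose(mu, y, atol=1e-8):
        raise PerfectSeparationError(
            "perfect prediction: classes are linearly separable; "
            "retry with ridge (e.g. 1e-6)"
        )
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    xtwx = X.T @ (w[:, None] * X)
    cov = np.linalg.pinv(xtwx)
    se = np.sqrt(np.diag(cov))
    ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) + (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
    return beta, se, it, converged, ll


def train_logistic(
    table: FeatureTable,
    features,
    positive_label: str = "animal",
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> FitResult:
    """Maximum-likelihood logistic fit by iteratively reweighted least
    squares (IRLS).

    Converges when the largest coefficient change drops below ``tol``
    (default 1e-8, at most ``max_iter`` = 100 iterations); deterministic.
    Perfectly separable classes raise :class:`PerfectSeparationError`
    unless a small ridge (e.g. 1e-6) is supplied.
    """
    features = list(features)
    labels = table.class_labels()
    if len(labels) != 2:
        raise ValueError(f"training needs exactly two classes, got {labels}")
    if positive_label not in labels:
        raise ValueError(f"positive label {positive_label!r} not among {labels}")
    negative_label = next(l for l in labels if l != positive_label)

    sub = table.values[features]
    if sub.isna().any().any():
        raise ValueError("missing values in training feature columns")
    X = np.column_stack([np.ones(len(sub)), sub.to_numpy(dtype=float)])
    y = (table.labels == positive_label).to_numpy(dtype=float)
    if len(y) <= len(features) + 1:
        raise ValueError("need more observations than parameters")

    beta, se, n_iter, converged, ll = _irls(X, y, tol=tol, max_iter=max_iter, ridge=ridge)
    model = LogisticModel(
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(features, beta[1:])},
        positive_label=positive_label,
        negative_label=negative_label,
    )
    return FitResult(model=model, standard_errors=se, n_iter=n_iter, converged=converged,
                     log_likelihood=ll)


# ---------------------------------------------------------------------------
# Baseline and evaluation


@dataclass
class ZeroRModel:
    """Majority-class baseline: constant probability = majority fraction."""

    majority_label: str
    minority_label: str
    majority_fraction: float

    def predict_proba_table(self, values: pd.DataFrame) -> np.ndarray:
        return np.full(len(values), self.majority_fraction)

    def predict_label(self, fv=None) -> str:
        return self.majority_label


def zero_r(table: FeatureTable) -> ZeroRModel:
    """Fit the ZeroR baseline; a tie picks the lexicographically first label."""
    counts = table.labels.value_counts()
    labels = sorted(counts.index)
    if len(labels) != 2:
        raise ValueError(f"ZeroR needs exactly two classes, got {labels}")
    la, lb = labels
    majority = la if counts[la] >= counts[lb] else lb
    minority = lb if majority == la else la
    return ZeroRModel(
        majority_label=majority,
        minority_label=minority,
        majority_fraction=float(counts[majority] / counts.sum()),
    )


def roc_area(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC area via the Mann-Whitney rank statistic (ties share ranks).

    Equals the probability that a random positive is scored above a
    random negative (ties counted half), and equals trapezoidal
    integration of the empirical ROC curve.
    """
    y_true = np.asarray(y_true, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC area needs both classes")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[y_true].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvalReport:
    """Cross-validation report with Weka-style weighted metrics.

    ``tp_rate``/``recall`` and ``precision`` are class-size-weighted
    averages of the per-class values; ``roc_area`` is the rank-statistic
    AUC of the pooled out-of-fold probabilities (identical for either
    orientation of a two-class problem, hence also its weighted average).
    """

    tp_rate: float
    precision: float
    recall: float
    roc_area: float
    confusion: dict[str, dict[str, int]]
    per_fold: list[dict] = field(default_factory=list)
    n: int = 0


def _weighted_metrics(y_true: np.ndarray, y_pred: np.ndarray, labels: list[str]):
    n = len(y_true)
    tp_rate = precision = 0.0
    confusion = {t: {p: 0 for p in labels} for t in labels}
    for t, p in zip(y_true, y_pred):
        confusion[t][p] += 1
    for cls in labels:
        weight = (y_true == cls).sum() / n
        tp = confusion[cls][cls]
        actual = (y_true == cls).sum()
        predicted = (y_pred == cls).sum()
        rec_c = tp / actual if actual else 0.0
        prec_c = tp / predicted if predicted else 0.0
        tp_rate += weight * rec_c
        precision += weight * prec_c
    return tp_rate, precision, confusion


def cross_validate(
    table: FeatureTable,
    features,
    model_spec: str = "logistic",
    k: int = 10,
    seed: int = 1,
    threshold: float = 0.5,
    ridge_fallback: float = 1e-6,
) -> EvalReport:
    """Stratified k-fold cross-validation of a classifier on ``table``.

    ``model_spec`` is ``"logistic"``, ``"zero_r"``, or a callable
    ``f(train_table, features) -> model`` exposing ``predict_proba_table``
    (the hook through which external classifiers plug in).  Out-of-fold
    probabilities are pooled before computing the weighted metrics and
    the rank-statistic ROC area.  A separable training fold falls back to
    a tiny ridge instead of failing.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    features = list(features)
    labels = table.class_labels()
    if len(labels) != 2:
        raise ValueError(f"evaluation needs exactly two classes, got {labels}")
    counts = table.labels.value_counts()
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) has fewer members than k={k}")

    if model_spec == "logistic":
        positive = "animal" if "animal" in labels else labels[1]

        def fit(train):
            try:
                return train_logistic(train, features, positive_label=positive).model
            except PerfectSeparationError:
                return train_logistic(
                    train, features, positive_label=positive, ridge=ridge_fallback
                ).model

    elif model_spec == "zero_r":
        positive = "animal" if "animal" in labels else labels[1]

        def fit(train):
            return zero_r(train)

    elif callable(model_spec):
        positive = "animal" if "animal" in labels else labels[1]
        fit = lambda train: model_spec(train, features)  # noqa: E731
    else:
        raise ValueError(f"unknown model_spec {model_spec!r}")
    negative = next(l for l in labels if l != positive)

    y_all = table.labels.to_numpy(dtype=object)
    proba = np.full(len(table.values), np.nan)
    pred = np.empty(len(table.values), dtype=object)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for fold_i, (tr, te) in enumerate(skf.split(table.values, y_all)):
        train = FeatureTable(
            values=table.values.iloc[tr], labels=table.labels.iloc[tr]
        )
        model = fit(train)
        p = model.predict_proba_table(table.values.iloc[te])
        proba[te] = p
        if isinstance(model, ZeroRModel):
            pred[te] = model.majority_label
        else:
            pred[te] = np.where(p >= threshold, positive, negative)
        fold_true = y_all[te]
        fold_acc = float((pred[te] == fold_true).mean())
        per_fold.append({"fold": fold_i, "n_test": len(te), "accuracy": fold_acc})

    tp_rate, precision, confusion = _weighted_metrics(y_all, pred, labels)
    auc = roc_area(y_all == positive, proba)
    return EvalReport(
        tp_rate=tp_rate,
        precision=precision,
        recall=tp_rate,
        roc_area=auc,
        confusion=confusion,
        per_fold=per_fold,
        n=len(y_all),
    )


# ---------------------------------------------------------------------------
# Model files: flat text, one "feature<TAB>coefficient" line per feature


def write_model(model: LogisticModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"__intercept__\t{model.intercept:.12g}\n")
        fh.write(f"__positive_label__\t{model.positive_label}\n")
        fh.write(f"__negative_label__\t{model.negative_label}\n")
        for name, beta in model.coefficients.items():
            fh.write(f"{name}\t{beta:.12g}\n")


def read_model(path) -> LogisticModel:
    intercept = None
    positive = "animal"
    negative = "plant"
    coeffs: dict[str, float] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        key, value = ln.split("\t")
        if key == "__intercept__":
            intercept = float(value)
        elif key == "__positive_label__":
            positive = value
        elif key == "__negative_label__":
            negative = value
        else:
            coeffs[key] = float(value)
    if intercept is None:
        raise ValueError(f"{path}: missing __intercept__ line")
    return LogisticModel(
        intercept=intercept, coefficients=coeffs,
        positive_label=positive, negative_label=negative,
    )
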