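"""Linear-SVM discrimination of AD vs HC with LOOCV and permutation testing.

Features are regional AI/CFH summaries (cluster means by default, peak
spheres optionally).  Each leave-one-out fold standardizes features with
the training fold's mean and standard deviation only — no information from
the held-out subject leaks into scaling — then fits a linear-kernel
maximum-margin classifier at fixed cost C and records the held-out
subject's signed decision value.  Accuracy, sensitivity and specificity
come from the pooled predictions (AD is the positive class); AUC ranks the
pooled decision values against the true labels.

Significance of the observed accuracy uses a label-permutation test: labels
are shuffled, the complete LOOCV is rerun, and

    p = (1 + #{null accuracy >= observed}) / (n_perm + 1).

Because fold standardization and Gram matrices depend only on the features,
they are precomputed once and shared across permutations.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from sklearn.metrics import roc_auc_score

from ._svm import loocv_decisions, permuted_loocv_accuracies, smo_fit

__all__ = [
    "FeatureMatrix",
    "ClassificationReport",
    "svm_loocv_classify",
    "label_permutation_test",
]

POSITIVE_CLASS = "AD"
SD_FLOOR = 1e-12


@dataclasses.dataclass
class FeatureMatrix:
    """n_subjects x n_features values with AD/HC labels and feature names."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("values must be n x d with d >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features contain missing values")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels must align with rows")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names must align with columns")
        classes = set(map(str, self.labels))
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {classes}")

    @property
    def y_signed(self) -> np.ndarray:
        """+1 for the positive class (AD if present), -1 otherwise."""
        labels = self.labels.astype(str)
        pos = POSITIVE_CLASS if POSITIVE_CLASS in set(labels) else sorted(set(labels))[0]
        return np.where(labels == pos, 1.0, -1.0)

    @property
    def positive_class(self) -> str:
        labels = set(self.labels.astype(str))
        return POSITIVE_CLASS if POSITIVE_CLASS in labels else sorted(labels)[0]


@dataclasses.dataclass
class ClassificationReport:
    """LOOCV summary plus the per-fold raw material to recompute it."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    predicted_labels: list[str]
    decision_values: np.ndarray
    true_labels: list[str]
    positive_class: str
    c_param: float
    permutation_p: float | None = None
    n_perm: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["decision_values"] = list(map(float, self.decision_values))
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _fold_kernels(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold standardized training Gram matrices and test kernel rows.

    Standardization uses the training fold's mean/sd with a floor of
    ``SD_FLOOR`` (a constant training feature standardizes to zero).
    These depend only on the features, never on labels.
    """
    n, d = x.shape
    k_folds = np.empty((n, n - 1, n - 1))
    k_test = np.empty((n, n - 1))
    idx = np.arange(n)
    for f in range(n):
        tr = idx[idx != f]
        xt = x[tr]
        mu = xt.mean(axis=0)
        sd = xt.std(axis=0)
        sd = np.maximum(sd, SD_FLOOR)
        xs = (xt - mu) / sd
        xe = (x[f] - mu) / sd
        k_folds[f] = xs @ xs.T
        k_test[f] = xs @ xe
    return k_folds, k_test


def svm_loocv_classify(
    features: FeatureMatrix, c_param: float = 1.0
) -> ClassificationReport:
    """Leave-one-out linear-SVM classification; deterministic given inputs."""
    y = features.y_signed
    if (y > 0).sum() < 2 or (y < 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    k_folds, k_test = _fold_kernels(features.values)
    decisions = loocv_decisions(k_folds, k_test, y, float(c_param))
    pred = np.where(decisions > 0, 1.0, -1.0)
    pos = features.positive_class
    neg = sorted(set(features.labels.astype(str)) - {pos})[0]
    tp = int(((pred > 0) & (y > 0)).sum())
    tn = int(((pred < 0) & (y < 0)).sum())
    fp = int(((pred > 0) & (y < 0)).sum())
    fn = int(((pred < 0) & (y > 0)).sum())
    accuracy = (tp + tn) / y.shape[0]
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    auc = float(roc_auc_score(y > 0, decisions))
    return ClassificationReport(
        accuracy=float(accuracy),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        auc=auc,
        predicted_labels=[pos if p > 0 else neg for p in pred],
        decision_values=np.asarray(decisions),
        true_labels=list(features.labels.astype(str)),
        positive_class=pos,
        c_param=float(c_param),
    )


def label_permutation_test(
    features: FeatureMatrix,
    n_perm: int = 5000,
    seed: int = 0,
    c_param: float = 1.0,
    observed_accuracy: float | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for the LOOCV accuracy.

    Each permutation shuffles the subject labels and reruns the complete
    LOOCV (fold kernels are label-independent and reused).  Returns
    (p, null accuracy vector); reproducible given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    y = features.y_signed
    if observed_accuracy is None:
        observed_accuracy = svm_loocv_classify(features, c_param=c_param).accuracy
    k_folds, k_test = _fold_kernels(features.values)
    rng = np.random.default_rng(seed)
    y_perms = np.empty((n_perm, y.shape[0]))
    for p in range(n_perm):
        y_perms[p] = y[rng.permutation(y.shape[0])]
    null_acc = permuted_loocv_accuracies(k_folds, k_test, y_perms, float(c_param))
    p_value = (1.0 + int((null_acc >= observed_accuracy - 1e-12).sum())) / (n_perm + 1.0)
    return float(p_value), null_acc


def linear_svm_decision(
    x_train: np.ndarray, y_signed: np.ndarray, x_eval: np.ndarray, c_param: float = 1.0
) -> np.ndarray:
    """Fit on (x_train, y) and return decision values for ``x_eval``.

    Exposed mainly for cross-checking the SMO solver against independent
    SVM implementations; no standardization is applied here.
    """
    k = x_train @ x_train.T
    alpha, b = smo_fit(k, np.asarray(y_signed, dtype=float), float(c_param))
    w = x_train.T @ (alpha * y_signed)
    return x_eval @ w + b
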