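"""End-to-end recurrence-feature classifier.

Pipeline per subject: per-channel z-scale the raw multi-channel series,
compute the pairwise Euclidean distance matrix (no delay embedding — the
traces are already a state-space sample), apply the LoTRA transform, keep
the high-curvature code band (64–191) as a binary sparse matrix, and reduce
it to the 9-statistic recurrence feature vector.  Feature tables are
classified with an RBF support vector machine evaluated by nested
leave-one-out cross-validation: the outer loop holds out one subject, the
inner leave-one-out loop over the remaining subjects selects (C, gamma) by
inner accuracy, and feature standardization is fitted inside the training
split only, so the held-out subject never leaks into model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .core import HIGH_CURVATURE_BAND, code_band_mask, distance_matrix, lotra_transform
from .embedding import TimeSeries, Trajectory
from .rqa import FEATURE_NAMES, RQAFeatures, rqa_features

__all__ = [
    "FeatureTable",
    "ClassifierReport",
    "DEFAULT_GRID",
    "extract_features",
    "build_feature_table",
    "nested_loocv",
    "classification_metrics",
]

#: Default hyperparameter grid for the RBF SVM (applied to standardized features).
DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "C": (0.1, 1.0, 10.0, 100.0),
    "gamma": (0.01, 0.1, 1.0, 10.0),
}


@dataclass
class FeatureTable:
    """One 9-feature row per subject with binary labels."""

    features: np.ndarray
    labels: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if f.ndim != 2 or f.shape[0] != y.shape[0]:
            raise ValueError("features must be 2-D with one row per label")
        if not np.all(np.isfinite(f)):
            raise ValueError("features contain missing or non-finite values")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if self.subject_ids is None:
            self.subject_ids = [f"s{i:03d}" for i in range(f.shape[0])]
        self.features = f
        self.labels = y

    @property
    def n(self) -> int:
        return self.features.shape[0]


@dataclass
class ClassifierReport:
    """Confusion counts, derived rates and per-fold chosen hyperparameters."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = 0.0
    sensitivity: float = 0.0
    specificity: float = 0.0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    fold_hyperparams: list[dict] = field(default_factory=list)
    predictions: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "fold_hyperparams": self.fold_hyperparams,
            "notes": self.notes,
        }


def _zscale_channels(x: TimeSeries) -> np.ndarray:
    v = x.values
    sd = v.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance input")
    return (v - v.mean(axis=0)) / sd


def extract_features(
    x: TimeSeries,
    band: tuple[int, int] = HIGH_CURVATURE_BAND,
    l_min: int = 2,
    v_min: int = 2,
) -> RQAFeatures:
    """Series -> z-scale -> distances -> LoTRA -> band mask -> 9 features."""
    if x.n < 3:
        raise ValueError("need at least 3 samples")
    z = _zscale_channels(x)
    D = distance_matrix(Trajectory(points=z))
    codes = lotra_transform(D)
    mask = code_band_mask(codes, *band)
    return rqa_features(mask, l_min=l_min, v_min=v_min)


def build_feature_table(
    series: list[TimeSeries],
    labels,
    band: tuple[int, int] = HIGH_CURVATURE_BAND,
    subject_ids: list[str] | None = None,
) -> FeatureTable:
    """Extract the feature vector of every subject into one table."""
    rows = np.stack([extract_features(s, band=band).to_array() for s in series])
    return FeatureTable(features=rows, labels=np.asarray(labels), subject_ids=subject_ids)


def _standardize(train: np.ndarray, *others: np.ndarray):
    """Z-scale by the training split's mean/sd (constant columns left as-is)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return tuple((arr - mu) / sd for arr in (train, *others))


def nested_loocv(
    table: FeatureTable,
    grid: dict[str, tuple[float, ...]] | None = None,
    seed: int = 0,
) -> ClassifierReport:
    """Nested leave-one-out cross-validation of the RBF SVM.

    Outer loop: leave one subject out.  Inner loop: leave-one-out over the
    remaining subjects scores every (C, gamma) pair; the best inner accuracy
    wins, ties broken toward the smallest C then the smallest gamma.  The
    winning pair is refitted on all outer-training subjects (standardization
    refitted there too) to predict the held-out subject; outer predictions
    aggregate into the confusion matrix.
    """
    if grid is None:
        grid = DEFAULT_GRID
    X, y = table.features, table.labels
    n = table.n
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise ValueError("need at least 2 subjects per class")
    candidates = [(C, g) for C in sorted(grid["C"]) for g in sorted(grid["gamma"])]
    preds = np.empty(n, dtype=int)
    fold_params: list[dict] = []
    for i in range(n):
        train = np.arange(n) != i
        X_tr, y_tr = X[train], y[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("degenerate fold: a class is absent from a training fold")
        hits = np.zeros(len(candidates))
        for j in range(n - 1):
            inner = np.arange(n - 1) != j
            y_in = y_tr[inner]
            if len(np.unique(y_in)) < 2:
                raise ValueError("degenerate fold: a class is absent from an inner fold")
            X_in, x_val = _standardize(X_tr[inner], X_tr[j])
            for k, (C, g) in enumerate(candidates):
                clf = SVC(C=C, gamma=g, kernel="rbf", random_state=seed)
                clf.fit(X_in, y_in)
                hits[k] += clf.predict(x_val[None])[0] == y_tr[j]
        # argmax takes the first maximum; candidates are sorted by (C, gamma),
        # so ties break toward the smallest C, then the smallest gamma.
        C, g = candidates[int(np.argmax(hits))]
        X_fit, x_test = _standardize(X_tr, X[i])
        model = SVC(C=C, gamma=g, kernel="rbf", random_state=seed).fit(X_fit, y_tr)
        preds[i] = int(model.predict(x_test[None])[0])
        fold_params.append({"held_out": table.subject_ids[i], "C": C, "gamma": g})
    tp = int(np.sum((preds == 1) & (y == 1)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    report = classification_metrics(tp, fp, tn, fn)
    report.fold_hyperparams = fold_params
    report.predictions = preds
    return report


def classification_metrics(tp: int, fp: int, tn: int, fn: int) -> ClassifierReport:
    """Diagnostic rates from a confusion matrix.

    Rates with empty denominators are reported as 0 with an explanatory note.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion matrix is empty")
    notes: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            notes.append(f"{name} undefined (empty denominator), reported as 0")
            return 0.0
        return num / den

    accuracy = (tp + tn) / total
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if (precision + sensitivity) > 0
        else 0.0
    )
    if precision + sensitivity == 0:
        notes.append("f1 undefined (precision + recall = 0), reported as 0")
    return ClassifierReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        recall=sensitivity,
        f1=f1,
        notes=notes,
    )
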