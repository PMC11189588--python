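"""Edge-feature SVM classification with shuffle-split validation.

Subject-level connectivity matrices (ATM or imaginary coherence) are
flattened into edge-feature vectors and fed to a support vector machine.
Validation follows a repeated stratified shuffle split (80% train / 20%
test, 50 iterations by default); within each training partition a 5-fold
grid search selects the kernel (linear or RBF) and the regularization
constant C. Feature standardization uses training-set statistics only.
Edge importance is the median over splits of the absolute linear-SVM
coefficients; node importance aggregates incident edges.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .avalanches import TransitionMatrix, binarize, compute_atm, detect_avalanches
from .connectivity import ConnectivityMatrix
from .containers import RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "ClassifierConfig",
    "SplitResult",
    "ClassificationReport",
    "ImportanceMap",
    "vectorize",
    "fit_predict_splits",
    "importance",
    "atm_features",
    "optimize_avalanche_params",
]

METRICS = ("accuracy", "roc_auc", "f1", "precision", "sensitivity", "specificity")


@dataclass
class FeatureSet:
    """Subjects-by-edges design matrix with its edge bookkeeping.

    For directed (ATM) features ``edge_index`` holds all ordered off-
    diagonal ROI pairs; for symmetric (ImCoh) features the unordered
    upper-triangle pairs. ``labels`` is one group label per subject and
    must contain exactly two classes.
    """

    matrix: np.ndarray
    edge_index: list[tuple[int, int]]
    labels: list[str]
    feature_kind: str
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D (subjects x edges)")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains missing/non-finite values")
        if len(self.edge_index) != self.matrix.shape[1]:
            raise ValueError("edge_index length must equal n_edges")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("one label per subject is required")
        if len(set(self.labels)) != 2:
            raise ValueError("labels must contain exactly two classes")

    @property
    def classes(self) -> list[str]:
        """The two class names, sorted; the second is the positive class."""
        return sorted(set(self.labels))

    def edge_labels(self) -> list[str]:
        """Human-readable edge names: 'a->b' for directed, 'a--b' otherwise."""
        sep = "->" if self.feature_kind == "atm" else "--"
        names = self.roi_labels or [str(i) for i in range(
            max(max(i, j) for i, j in self.edge_index) + 1
        )]
        return [f"{names[i]}{sep}{names[j]}" for i, j in self.edge_index]


@dataclass
class ClassifierConfig:
    """SVM and cross-validation settings (all randomness from ``seed``)."""

    kernel_grid: tuple[str, ...] = ("linear", "rbf")
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    inner_folds: int = 5
    n_splits: int = 50
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if not self.kernel_grid or not self.c_grid:
            raise ValueError("kernel and C grids must be non-empty")
        if any(c <= 0 for c in self.c_grid):
            raise ValueError("C values must be positive")


@dataclass
class SplitResult:
    """Metrics and fitted-model summaries for one shuffle split."""

    metrics: dict[str, float]
    kernel: str
    C: float
    inner_cv_accuracy: float
    confusion: np.ndarray  # rows true, cols predicted, class order = classes
    roc_points: np.ndarray  # (n_points, 2) of (fpr, tpr)
    coef: np.ndarray | None  # |linear coefficients| unavailable for rbf
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class ClassificationReport:
    """Per-split records plus their mean +/- SD summary."""

    per_split: list[SplitResult]
    summary: dict[str, tuple[float, float]]
    classes: list[str]
    feature_kind: str
    seed: int

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([s.metrics[name] for s in self.per_split])

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "feature_kind": self.feature_kind,
            "seed": self.seed,
            "summary": {k: {"mean": m, "sd": s} for k, (m, s) in self.summary.items()},
            "per_split": [
                {
                    "metrics": s.metrics,
                    "kernel": s.kernel,
                    "C": s.C,
                    "inner_cv_accuracy": s.inner_cv_accuracy,
                    "confusion": s.confusion.tolist(),
                    "roc_points": s.roc_points.tolist(),
                }
                for s in self.per_split
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class ImportanceMap:
    """Median-|coefficient| edge importance and its node aggregation."""

    edge_importance: np.ndarray
    node_importance: np.ndarray
    edge_index: list[tuple[int, int]]
    feature_kind: str
    n_splits_used: int
    roi_labels: list[str] | None = None


def vectorize(
    matrices: Sequence[TransitionMatrix | ConnectivityMatrix],
    labels: Sequence[str],
) -> FeatureSet:
    """Flatten per-subject matrices into an edge-feature design matrix.

    ATMs contribute all ``n*(n-1)`` ordered off-diagonal entries in
    row-major order; symmetric connectivity matrices the ``n*(n-1)/2``
    upper-triangle entries (row-major over i < j). All subjects must share
    ROI labels and matrix size.
    """
    if not matrices:
        raise ValueError("no matrices to vectorize")
    if len(matrices) != len(labels):
        raise ValueError("one label per matrix is required")
    first = matrices[0]
    directed = isinstance(first, TransitionMatrix)
    kind = "atm" if directed else "imcoh"
    ref_labels = first.roi_labels
    mats = []
    for m in matrices:
        arr = m.probs if isinstance(m, TransitionMatrix) else m.values
        if isinstance(m, TransitionMatrix) != directed:
            raise ValueError("cannot mix directed and symmetric matrices")
        if arr.shape != (first.probs if directed else first.values).shape:
            raise ValueError("matrix size differs across subjects")
        if (m.roi_labels is None) != (ref_labels is None) or (
            ref_labels is not None and list(m.roi_labels) != list(ref_labels)
        ):
            raise ValueError("ROI labels differ across subjects")
        mats.append(arr)
    n = mats[0].shape[0]
    if directed:
        edge_index = [(i, j) for i in range(n) for j in range(n) if i != j]
    else:
        edge_index = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rows = np.array([[m[i, j] for i, j in edge_index] for m in mats])
    return FeatureSet(
        matrix=rows,
        edge_index=edge_index,
        labels=list(labels),
        feature_kind=kind,
        roi_labels=list(ref_labels) if ref_labels is not None else None,
    )


def _make_grid(cfg: ClassifierConfig) -> list[dict]:
    grid = []
    for kernel in cfg.kernel_grid:
        grid.append({"svc__kernel": [kernel], "svc__C": list(cfg.c_grid)})
    return grid


def fit_predict_splits(features: FeatureSet, cfg: ClassifierConfig) -> ClassificationReport:
    """Run the repeated shuffle-split SVM evaluation.

    For each stratified 80/20 split: standardize with training statistics,
    select kernel and C by ``inner_folds``-fold grid search on the training
    partition (scored by accuracy), then score the held-out subjects.
    Constant feature columns are retained (their zero scale is replaced by
    1). The whole procedure is deterministic given ``cfg.seed``.
    """
    classes = features.classes
    y = np.array([classes.index(l) for l in features.labels])
    X = features.matrix
    if np.bincount(y, minlength=2).min() < 4:
        raise ValueError("need >= 4 subjects per class")
    splitter = StratifiedShuffleSplit(
        n_splits=cfg.n_splits, test_size=cfg.test_fraction, random_state=cfg.seed
    )
    results: list[SplitResult] = []
    for split_i, (tr, te) in enumerate(splitter.split(X, y)):
        # Inner folds cannot exceed the training count of the rarer class.
        folds = int(min(cfg.inner_folds, np.bincount(y[tr], minlength=2).min()))
        if folds < 2:
            raise ValueError("training partition too small for inner cross-validation")
        inner = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=cfg.seed + split_i
        )
        pipe = Pipeline(
            [("scale", StandardScaler()), ("svc", SVC())]
        )
        search = GridSearchCV(
            pipe, _make_grid(cfg), cv=inner, scoring="accuracy", n_jobs=None
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X[tr], y[tr])
        best = search.best_estimator_
        y_pred = best.predict(X[te])
        scores = best.decision_function(X[te])
        cm = confusion_matrix(y[te], y_pred, labels=[0, 1])
        fpr, tpr, _ = roc_curve(y[te], scores)
        metrics = {
            "accuracy": accuracy_score(y[te], y_pred),
            "roc_auc": roc_auc_score(y[te], scores),
            "f1": f1_score(y[te], y_pred, zero_division=0),
            "precision": precision_score(y[te], y_pred, zero_division=0),
            "sensitivity": recall_score(y[te], y_pred, zero_division=0),
            "specificity": recall_score(y[te], y_pred, pos_label=0, zero_division=0),
        }
        svc: SVC = best.named_steps["svc"]
        coef = np.abs(svc.coef_.ravel()) if svc.kernel == "linear" else None
        results.append(
            SplitResult(
                metrics={k: float(v) for k, v in metrics.items()},
                kernel=svc.kernel,
                C=float(svc.C),
                inner_cv_accuracy=float(search.best_score_),
                confusion=cm,
                roc_points=np.column_stack([fpr, tpr]),
                coef=coef,
                train_idx=tr,
                test_idx=te,
            )
        )
    summary = {}
    for name in METRICS:
        vals = np.array([r.metrics[name] for r in results])
        summary[name] = (float(vals.mean()), float(vals.std()))
    return ClassificationReport(
        per_split=results,
        summary=summary,
        classes=classes,
        feature_kind=features.feature_kind,
        seed=cfg.seed,
    )


def importance(
    features: FeatureSet,
    cfg: ClassifierConfig,
    report: ClassificationReport | None = None,
) -> ImportanceMap:
    """Edge and node feature importance from linear-kernel coefficients.

    Edge importance is the per-edge median over splits of |coefficient|;
    splits in which the grid search picked the RBF kernel have no per-
    feature coefficients and are excluded (logged). Node importance is the
    arithmetic mean of the importances of the edges incident to the node
    (both directions for directed features).

    Raises
    ------
    ValueError
        If no split used the linear kernel; restrict ``kernel_grid`` to
        ``("linear",)`` in that case.
    """
    if report is None:
        report = fit_predict_splits(features, cfg)
    coefs = [s.coef for s in report.per_split if s.coef is not None]
    n_rbf = len(report.per_split) - len(coefs)
    if n_rbf:
        logger.info("importance: excluding %d RBF-kernel splits", n_rbf)
    if not coefs:
        raise ValueError(
            "no split selected the linear kernel; rerun with kernel_grid=('linear',)"
        )
    edge_imp = np.median(np.vstack(coefs), axis=0)
    n_rois = (
        len(features.roi_labels)
        if features.roi_labels is not None
        else max(max(i, j) for i, j in features.edge_index) + 1
    )
    node_sum = np.zeros(n_rois)
    node_cnt = np.zeros(n_rois)
    for e, (i, j) in enumerate(features.edge_index):
        node_sum[i] += edge_imp[e]
        node_cnt[i] += 1
        node_sum[j] += edge_imp[e]
        node_cnt[j] += 1
    node_imp = np.divide(node_sum, node_cnt, out=np.zeros(n_rois), where=node_cnt > 0)
    return ImportanceMap(
        edge_importance=edge_imp,
        node_importance=node_imp,
        edge_index=features.edge_index,
        feature_kind=features.feature_kind,
        n_splits_used=len(coefs),
        roi_labels=features.roi_labels,
    )


def atm_features(
    subjects: Sequence[RoiTimeSeries],
    labels: Sequence[str],
    *,
    threshold_z: float,
    min_duration_bins: int,
    delta_bins: int = 1,
) -> FeatureSet:
    """Binarize, detect avalanches, and vectorize per-subject ATMs.

    Convenience wrapper over the avalanche pipeline at bin size 1; raises
    if a subject yields no avalanche long enough for the lag.
    """
    mats = []
    for ts in subjects:
        raster = binarize(ts, threshold_z)
        avs = [
            a
            for a in detect_avalanches(raster, min_duration_bins)
            if a.n_bins >= delta_bins + 1
        ]
        if not avs:
            raise ValueError(
                f"subject '{ts.subject_id}': no avalanche of >= "
                f"{delta_bins + 1} bins at threshold {threshold_z}"
            )
        mats.append(
            compute_atm(avs, ts.n_rois, delta_bins, roi_labels=ts.roi_labels)
        )
    return vectorize(mats, labels)


def optimize_avalanche_params(
    subjects: Sequence[RoiTimeSeries],
    labels: Sequence[str],
    cfg: ClassifierConfig,
    *,
    threshold_grid: Sequence[float] = (1.2, 1.5, 1.8, 2.1, 2.4, 2.7, 3.0),
    min_duration_grid: Sequence[int] = (2, 3, 4, 5, 6, 7, 8),
    delta_bins: int = 1,
    selection: str = "nested",
) -> tuple[float, int, ClassificationReport, list[dict]]:
    """Grid-search the binarization threshold and minimal avalanche duration.

    Runs the full ATM + classification pipeline for every (threshold,
    min_duration) pair and returns the pair with the best mean accuracy,
    ties broken toward the higher threshold, then the shorter duration.
    With ``selection="nested"`` (default) pairs are ranked by the mean
    inner-CV accuracy of the grid search, which never touches test
    subjects; ``selection="test"`` ranks by held-out accuracy, matching
    the common but optimistic practice of selecting directly on the
    reported score. All pairs' scores are returned for audit.
    """
    if selection not in ("nested", "test"):
        raise ValueError(f"unknown selection mode {selection!r}")
    if not threshold_grid or not min_duration_grid:
        raise ValueError("parameter grids must be non-empty")
    audit: list[dict] = []
    best_key: tuple | None = None
    best: tuple[float, int, ClassificationReport] | None = None
    for thr in threshold_grid:
        for dur in min_duration_grid:
            try:
                features = atm_features(
                    subjects,
                    labels,
                    threshold_z=thr,
                    min_duration_bins=dur,
                    delta_bins=delta_bins,
                )
            except ValueError as exc:
                logger.warning(
                    "skipping threshold=%g min_duration=%d: %s", thr, dur, exc
                )
                continue
            report = fit_predict_splits(features, cfg)
            if selection == "nested":
                score = float(
                    np.mean([s.inner_cv_accuracy for s in report.per_split])
                )
            else:
                score = report.summary["accuracy"][0]
            audit.append(
                {
                    "threshold_z": float(thr),
                    "min_duration_bins": int(dur),
                    "score": score,
                    "test_accuracy_mean": report.summary["accuracy"][0],
                }
            )
            key = (score, thr, -dur)
            if best_key is None or key > best_key:
                best_key = key
                best = (float(thr), int(dur), report)
    if best is None:
        raise ValueError("every (threshold, duration) pair failed to yield avalanches")
    return best[0], best[1], best[2], audit
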