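"""Emotion classification under narrative-grouped nested cross-validation.

Four feature families are supported for classifying the four emotional
states (harmony, satisfaction, depression, anxiety):

- ``words``: the response's unit-norm semantic vector (k dimensions);
- ``rs_totals``: the four rating-scale totals (PHQ-9, GAD-7, SWLS, HILS);
- ``rs_items``: the 26 individual items of those scales;
- ``words_plus_rs``: semantic dimensions concatenated with the 4 totals.

The estimator is L2-penalised multinomial logistic regression. Evaluation
uses 10-fold cross-validation grouped by narrative: every response tied to
one narrative (the narrator's own and all its evaluations) sits in a single
fold, so a model is never scored on a narrative it saw in training. Inside
each training fold a nested (inner, also grouped) cross-validation selects
the number of leading semantic dimensions from a geometric grid; ties go to
the smaller dimension count. Training pools responses from both phases;
accuracy is scored on Phase-2 responses only.

`EmotionClassifier` is the model object; its `fit()` returns an
`EmotionClassificationResults` carrying out-of-fold predictions, the
selected dimension counts, the confusion matrix, the metric panel and a
text `summary()`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import scales as _scales
from .evaluation import (
    CLASS_ORDER,
    ConfusionMatrix,
    MetricsReport,
    confusion,
    format_metric,
    metrics_from_confusion,
    overall_accuracy,
)
from .representation import embed_table
from .semantic import SemanticSpace

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "CVPlan",
    "TrainedClassifier",
    "ConvergenceError",
    "DEFAULT_GRID",
    "DEFAULT_RIDGE",
    "make_feature_set",
    "make_grouped_folds",
    "fit_multinomial",
    "select_dimensions",
    "cross_validated_predictions",
    "predict",
    "EmotionClassifier",
    "EmotionClassificationResults",
]

#: Geometric grid of candidate semantic dimension counts.
DEFAULT_GRID: tuple[int, ...] = (2, 3, 5, 8, 12, 18, 27, 40, 60, 90, 135, 200, 300)

#: Default L2 penalty strength (lambda); plain maximum likelihood diverges
#: on separable data.
DEFAULT_RIDGE = 1e-4

_RS_TOTAL_SCALES = ("PHQ9", "GAD7", "SWLS", "HILS")


class ConvergenceError(RuntimeError):
    """Optimiser failed to converge; carries iteration diagnostics."""


@dataclass
class FeatureSet:
    """Aligned features, labels, narrative groups and phase tags."""

    kind: str  # words | rs_totals | rs_items | words_plus_rs
    X: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    phase: np.ndarray
    n_semantic: int  # leading columns that are semantic dimensions
    row_index: np.ndarray = field(default=None)  # original record index

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.labels) == len(self.groups) == len(self.phase) == n):
            raise ValueError("feature-set fields are not row-aligned")
        if self.row_index is None:
            self.row_index = np.arange(n)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def make_feature_set(
    records: pd.DataFrame,
    kind: str,
    space: SemanticSpace | None = None,
) -> FeatureSet:
    """Build a feature matrix from a response-record table.

    ``records`` must carry ``condition``, ``narrative_id``, ``phase``,
    ``words`` (list or semicolon-joined string) and the scale item columns.
    Rows whose words are entirely out of vocabulary (for word-based kinds)
    or whose scale items are incomplete (for scale-based kinds) are dropped
    with a logged warning.
    """
    if kind not in ("words", "rs_totals", "rs_items", "words_plus_rs"):
        raise ValueError(f"unknown feature kind {kind!r}")

    def word_list(v):
        return v.split(";") if isinstance(v, str) else list(v)

    keep = records.index.to_numpy()
    n_semantic = 0
    totals_frame: pd.DataFrame | None = None

    if kind in ("rs_totals", "words_plus_rs"):
        totals_frame = _scales.score_records(records, _RS_TOTAL_SCALES)
        keep = totals_frame.index.to_numpy()
    elif kind == "rs_items":
        cols = [c for s in _RS_TOTAL_SCALES for c in _scales.scale_columns(s)]
        frame = records[cols]
        ok = frame.notna().all(axis=1)
        for s in _RS_TOTAL_SCALES:
            d = _scales.SCALES[s]
            sub = frame[_scales.scale_columns(s)]
            ok &= ((sub >= d.item_min) & (sub <= d.item_max)).all(axis=1)
        if (~ok).any():
            logger.warning(
                "dropped %d records with missing or out-of-range scale items",
                int((~ok).sum()),
            )
        keep = frame.index[ok].to_numpy()

    if kind in ("words", "words_plus_rs"):
        if space is None:
            raise ValueError(f"feature kind {kind!r} requires a semantic space")
        matrix, kept_pos, excluded = embed_table(
            [word_list(records.loc[i, "words"]) for i in keep], space
        )
        if excluded:
            logger.warning(
                "dropped %d responses with no in-vocabulary word", len(excluded)
            )
        keep = keep[kept_pos]
        n_semantic = space.k

    blocks: list[np.ndarray] = []
    if kind in ("words", "words_plus_rs"):
        blocks.append(matrix)
    if kind in ("rs_totals", "words_plus_rs"):
        blocks.append(
            totals_frame.loc[keep, [f"{s}_total" for s in _RS_TOTAL_SCALES]].to_numpy(float)
        )
    if kind == "rs_items":
        cols = [c for s in _RS_TOTAL_SCALES for c in _scales.scale_columns(s)]
        blocks.append(records.loc[keep, cols].to_numpy(float))

    X = np.hstack(blocks)
    sub = records.loc[keep]
    return FeatureSet(
        kind=kind,
        X=X,
        labels=sub["condition"].to_numpy(),
        groups=sub["narrative_id"].to_numpy(),
        phase=sub["phase"].to_numpy(),
        n_semantic=n_semantic,
        row_index=keep,
    )


@dataclass
class CVPlan:
    """Assignment of narrative groups to cross-validation folds."""

    n_folds: int
    fold_of: dict  # group id -> fold number

    def test_groups(self, fold: int) -> set:
        return {g for g, f in self.fold_of.items() if f == fold}

    def fold_for_rows(self, groups: Sequence) -> np.ndarray:
        return np.array([self.fold_of[g] for g in groups])


def make_grouped_folds(groups: Sequence, n_folds: int = 10, seed: int = 1) -> CVPlan:
    """Shuffle the distinct groups by seed and deal them round-robin.

    Fold sizes differ by at most one group; every group lands in exactly
    one fold, so no narrative is ever split across train and test.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    unique = sorted(set(groups))
    if len(unique) < n_folds:
        raise ValueError(f"need at least {n_folds} distinct groups, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    fold_of = {unique[idx]: pos % n_folds for pos, idx in enumerate(order)}
    return CVPlan(n_folds=n_folds, fold_of=fold_of)


@dataclass
class TrainedClassifier:
    """Fitted multinomial model plus the feature layout it expects."""

    class_order: tuple[str, ...]
    estimator: LogisticRegression
    d_selected: int
    ridge: float
    n_semantic: int
    scale_mean: np.ndarray  # z-scoring stats for the trailing scale columns
    scale_std: np.ndarray

    @property
    def coefficients(self) -> np.ndarray:
        return self.estimator.coef_

    @property
    def intercepts(self) -> np.ndarray:
        return self.estimator.intercept_

    def design(self, X: np.ndarray) -> np.ndarray:
        """Slice to the selected semantic dimensions and z-score the scales."""
        X = np.asarray(X, dtype=float)
        sem = X[:, : self.d_selected] if self.n_semantic else X[:, :0]
        rs = X[:, self.n_semantic :]
        if rs.shape[1]:
            rs = (rs - self.scale_mean) / self.scale_std
        return np.hstack([sem, rs])


def _expected_width(clf: TrainedClassifier) -> int:
    return clf.n_semantic + len(clf.scale_mean)


def fit_multinomial(
    features: np.ndarray,
    labels: Sequence[str],
    ridge: float = DEFAULT_RIDGE,
    d: int | None = None,
    n_semantic: int | None = None,
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> TrainedClassifier:
    """L2-penalised multinomial logistic regression.

    The first ``d`` of the ``n_semantic`` leading (semantic) columns enter
    the model raw; any trailing scale columns are z-scored with the
    training statistics. ``n_semantic`` defaults to the full width
    (pure semantic features).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    present = [c for c in class_order if c in set(y)]
    extra = set(y) - set(class_order)
    if extra:
        raise ValueError(f"labels outside class order: {sorted(extra)}")
    if len(present) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    if n_semantic is None:
        n_semantic = X.shape[1]
    if d is None:
        d = n_semantic
    if n_semantic and not 1 <= d <= n_semantic:
        raise ValueError(f"d={d} outside [1, {n_semantic}]")

    rs = X[:, n_semantic:]
    scale_mean = rs.mean(axis=0) if rs.shape[1] else np.zeros(0)
    scale_std = rs.std(axis=0) if rs.shape[1] else np.zeros(0)
    scale_std = np.where(scale_std == 0, 1.0, scale_std)

    clf = TrainedClassifier(
        class_order=class_order,
        estimator=LogisticRegression(
            C=1.0 / ridge,
            solver="lbfgs",
            max_iter=2000,
            tol=1e-6,
        ),
        d_selected=max(d, 0) if n_semantic else 0,
        ridge=ridge,
        n_semantic=n_semantic,
        scale_mean=scale_mean,
        scale_std=scale_std,
    )
    design = clf.design(X)
    clf.estimator.fit(design, y)
    n_iter = int(np.max(clf.estimator.n_iter_))
    if n_iter >= clf.estimator.max_iter:
        raise ConvergenceError(
            f"lbfgs hit the iteration cap ({n_iter} iterations, ridge={ridge})"
        )
    return clf


def predict(
    clf: TrainedClassifier, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and class probabilities (columns in ``clf.class_order``).

    The label is the argmax probability; exact ties break toward the
    earlier class in ``class_order``. Classes absent from training get
    probability zero.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != _expected_width(clf):
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else X.shape} does not "
            f"match the training layout ({_expected_width(clf)})"
        )
    raw = clf.estimator.predict_proba(clf.design(X))
    probs = np.zeros((X.shape[0], len(clf.class_order)))
    col = {c: j for j, c in enumerate(clf.class_order)}
    for j, c in enumerate(clf.estimator.classes_):
        probs[:, col[c]] = raw[:, j]
    labels = np.array([clf.class_order[i] for i in np.argmax(probs, axis=1)])
    return labels, probs


def _clip_grid(grid: Sequence[int], n_semantic: int) -> list[int]:
    out = sorted({min(int(d), n_semantic) for d in grid if d >= 1})
    return out or [n_semantic]


def select_dimensions(
    X: np.ndarray,
    y: Sequence[str],
    groups: Sequence,
    grid: Sequence[int],
    inner_folds: int = 5,
    seed: int = 1,
    ridge: float = DEFAULT_RIDGE,
    n_semantic: int | None = None,
) -> int:
    """Choose the semantic dimension count by inner grouped CV accuracy.

    Ties break toward the smallest dimension count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_semantic is None:
        n_semantic = X.shape[1]
    candidates = _clip_grid(grid, n_semantic)
    if len(candidates) == 1:
        return candidates[0]
    n_groups = len(set(groups))
    folds = min(inner_folds, n_groups)
    plan = make_grouped_folds(groups, folds, seed)
    row_fold = plan.fold_for_rows(groups)
    correct = {d: 0 for d in candidates}
    total = 0
    for fold in range(folds):
        test = row_fold == fold
        train = ~test
        if len(set(y[train])) < 2 or not test.any():
            continue
        total += int(test.sum())
        for d in candidates:
            clf = fit_multinomial(
                X[train], y[train], ridge=ridge, d=d, n_semantic=n_semantic
            )
            pred, _ = predict(clf, X[test])
            correct[d] += int((pred == y[test]).sum())
    if total == 0:
        return candidates[0]
    best = max(candidates, key=lambda d: (correct[d] / total, -d))
    return best


def cross_validated_predictions(
    featureset: FeatureSet,
    plan: CVPlan,
    grid: Sequence[int] = DEFAULT_GRID,
    ridge: float = DEFAULT_RIDGE,
    seed: int = 1,
    inner_folds: int = 5,
) -> tuple[pd.DataFrame, list[int]]:
    """Out-of-fold predictions for every row, plus per-fold selected d.

    Each row is predicted exactly once, by a model whose training pool
    excluded that row's narrative group. Dimension selection runs in an
    inner grouped CV inside each training fold (skipped for feature kinds
    with no semantic columns).
    """
    fs = featureset
    missing = set(fs.groups) - set(plan.fold_of)
    if missing:
        raise ValueError(f"plan does not cover groups: {sorted(missing)[:5]}")
    row_fold = plan.fold_for_rows(fs.groups)
    pred = np.empty(fs.n_rows, dtype=object)
    probs = np.full((fs.n_rows, len(CLASS_ORDER)), np.nan)
    d_per_fold: list[int] = []
    for fold in range(plan.n_folds):
        test = row_fold == fold
        train = ~test
        if not test.any():
            d_per_fold.append(0)
            continue
        y_train = fs.labels[train]
        if len(set(y_train)) < len(CLASS_ORDER):
            logger.warning(
                "fold %d training pool is missing %d class(es); fitting on the rest",
                fold,
                len(CLASS_ORDER) - len(set(y_train)),
            )
        if fs.n_semantic:
            d = select_dimensions(
                fs.X[train],
                y_train,
                fs.groups[train],
                grid,
                inner_folds=inner_folds,
                seed=seed + fold,
                ridge=ridge,
                n_semantic=fs.n_semantic,
            )
        else:
            d = 0
        d_per_fold.append(d)
        clf = fit_multinomial(
            fs.X[train],
            y_train,
            ridge=ridge,
            d=d if fs.n_semantic else None,
            n_semantic=fs.n_semantic,
        )
        labels, p = predict(clf, fs.X[test])
        pred[test] = labels
        probs[test] = p
    frame = pd.DataFrame(
        {
            "true": fs.labels,
            "pred": pred.astype(str),
            "fold": row_fold,
            "phase": fs.phase,
            "narrative_id": fs.groups,
        },
        index=pd.Index(fs.row_index, name="row"),
    )
    for j, c in enumerate(CLASS_ORDER):
        frame[f"p_{c}"] = probs[:, j]
    return frame, d_per_fold


class EmotionClassifier:
    """Multinomial emotion classifier evaluated by grouped nested CV.

    Parameters
    ----------
    features : FeatureSet
        Built directly or via :meth:`from_dataframe`.
    n_folds, inner_folds : int
        Outer and inner grouped cross-validation folds.
    grid : sequence of int
        Candidate semantic dimension counts (clipped to the space width).
    ridge : float
        L2 penalty strength.
    eval_phase : int or None
        Phase whose rows are scored (None scores every row).
    seed : int
        Controls the fold shuffles.
    """

    def __init__(
        self,
        features: FeatureSet,
        n_folds: int = 10,
        grid: Sequence[int] = DEFAULT_GRID,
        ridge: float = DEFAULT_RIDGE,
        inner_folds: int = 5,
        eval_phase: int | None = 2,
        seed: int = 1,
    ) -> None:
        self.features = features
        self.n_folds = n_folds
        self.grid = tuple(grid)
        self.ridge = ridge
        self.inner_folds = inner_folds
        self.eval_phase = eval_phase
        self.seed = seed

    @classmethod
    def from_dataframe(
        cls,
        records: pd.DataFrame,
        kind: str = "words",
        space: SemanticSpace | None = None,
        **kwargs,
    ) -> "EmotionClassifier":
        return cls(make_feature_set(records, kind, space), **kwargs)

    def fit(self) -> "EmotionClassificationResults":
        plan = make_grouped_folds(self.features.groups, self.n_folds, self.seed)
        preds, d_per_fold = cross_validated_predictions(
            self.features,
            plan,
            grid=self.grid,
            ridge=self.ridge,
            seed=self.seed,
            inner_folds=self.inner_folds,
        )
        return EmotionClassificationResults(self, plan, preds, d_per_fold)

    def fit_full(self, d: int | None = None) -> TrainedClassifier:
        """Fit one model on every row (used for word-cloud scoring)."""
        fs = self.features
        if fs.n_semantic and d is None:
            d = select_dimensions(
                fs.X,
                fs.labels,
                fs.groups,
                self.grid,
                inner_folds=self.inner_folds,
                seed=self.seed,
                ridge=self.ridge,
                n_semantic=fs.n_semantic,
            )
        return fit_multinomial(
            fs.X,
            fs.labels,
            ridge=self.ridge,
            d=d if fs.n_semantic else None,
            n_semantic=fs.n_semantic,
        )


class EmotionClassificationResults:
    """Out-of-fold predictions and the evaluation built on them."""

    def __init__(
        self,
        model: EmotionClassifier,
        plan: CVPlan,
        predictions: pd.DataFrame,
        d_per_fold: list[int],
    ) -> None:
        self.model = model
        self.plan = plan
        self.predictions = predictions
        self.d_per_fold = d_per_fold
        if model.eval_phase is None:
            self.eval_mask = np.ones(len(predictions), dtype=bool)
        else:
            self.eval_mask = (predictions["phase"] == model.eval_phase).to_numpy()

    @property
    def eval_predictions(self) -> pd.DataFrame:
        return self.predictions[self.eval_mask]

    @property
    def confusion(self) -> ConfusionMatrix:
        ep = self.eval_predictions
        return confusion(ep["true"], ep["pred"])

    @property
    def metrics(self) -> MetricsReport:
        return metrics_from_confusion(self.confusion)

    @property
    def accuracy(self) -> float:
        return overall_accuracy(self.confusion)

    @property
    def mean_dimensions(self) -> float:
        used = [d for d in self.d_per_fold if d > 0]
        return float(np.mean(used)) if used else float("nan")

    def correct_flags(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Per-evaluated-row 0/1 correctness, optionally under an extra mask."""
        sel = self.eval_mask if mask is None else (self.eval_mask & np.asarray(mask))
        sub = self.predictions[sel]
        return (sub["true"] == sub["pred"]).to_numpy().astype(int)

    def accuracy_for(self, mask: np.ndarray) -> float:
        flags = self.correct_flags(mask)
        return float(flags.mean()) if flags.size else float("nan")

    def summary(self) -> str:
        cm = self.confusion
        met = self.metrics
        lines = [
            "Emotion classification (grouped nested CV)",
            "=" * 52,
            f"features: {self.model.features.kind}    "
            f"folds: {self.plan.n_folds}    ridge: {self.model.ridge:g}",
            f"rows scored: {cm.total}    overall accuracy: {self.accuracy:.3f}",
        ]
        if self.model.features.n_semantic:
            ds = [d for d in self.d_per_fold if d > 0]
            lines.append(
                f"selected dimensions per fold: {ds} "
                f"(mean {self.mean_dimensions:.1f})"
            )
        lines.append("")
        lines.append("Confusion (rows predicted, columns true):")
        lines.append(cm.to_frame().to_string())
        lines.append("")
        panel = met.per_class.map(format_metric)
        lines.append("Per-class metrics:")
        lines.append(panel.to_string())
        return "\n".join(lines)
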