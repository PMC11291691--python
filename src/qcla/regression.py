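"""Language-based estimation of rating-scale totals.

Multiple linear regression from the response embedding onto an empirical
scale total (PHQ-9, GAD-7, SWLS or HILS), with the number of leading
semantic dimensions selected by nested grouped cross-validation exactly as
in the classifier: an inner grouped CV inside each outer training fold
picks the dimension count that maximises the out-of-fold Pearson r between
predicted and empirical totals. Every row receives an out-of-fold
prediction from a model never trained on its narrative.

Predicted totals are raw linear outputs — not clipped to the scale range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classification import CVPlan, make_grouped_folds, _clip_grid
from .evaluation import (
    UNDEFINED,
    bonferroni,
    pearson,
    two_sample_t,
    variance_f_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScalePredictor",
    "fit_scale_predictor",
    "estimate_scores",
    "subgroup_score_summary",
    "ScaleRegression",
    "ScaleRegressionResults",
]


@dataclass
class ScalePredictor:
    """OLS weights on the leading semantic dimensions plus an intercept."""

    scale: str
    coefficients: np.ndarray  # (d_selected,)
    intercept: float
    d_selected: int


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept; tiny ridge fallback if rank deficient."""
    design = np.hstack([X, np.ones((X.shape[0], 1))])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient design (%d < %d); using ridge fallback",
            rank,
            design.shape[1],
        )
        lam = 1e-8
        gram = design.T @ design + lam * np.eye(design.shape[1])
        beta = np.linalg.solve(gram, design.T @ y)
    return beta[:-1], float(beta[-1])


def _fit_d(X: np.ndarray, y: np.ndarray, d: int, scale: str) -> ScalePredictor:
    coef, intercept = _ols(X[:, :d], y)
    return ScalePredictor(scale=scale, coefficients=coef, intercept=intercept, d_selected=d)


def estimate_scores(predictor: ScalePredictor, embeddings: np.ndarray) -> np.ndarray:
    """Linear evaluation of the predictor on (possibly wider) embeddings."""
    X = np.asarray(embeddings, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] < predictor.d_selected:
        raise ValueError(
            f"embedding width {X.shape[1]} < d_selected {predictor.d_selected}"
        )
    return X[:, : predictor.d_selected] @ predictor.coefficients + predictor.intercept


def _select_d_by_r(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    grid: Sequence[int],
    inner_folds: int,
    seed: int,
    scale: str,
) -> int:
    candidates = _clip_grid(grid, X.shape[1])
    if len(candidates) == 1:
        return candidates[0]
    folds = min(inner_folds, len(set(groups)))
    plan = make_grouped_folds(groups, folds, seed)
    row_fold = plan.fold_for_rows(groups)
    best_d, best_r = candidates[0], -np.inf
    for d in candidates:
        oof = np.full(len(y), np.nan)
        for fold in range(folds):
            test = row_fold == fold
            train = ~test
            if not test.any() or train.sum() <= d + 1:
                continue
            pred = _fit_d(X[train], y[train], d, scale)
            oof[test] = estimate_scores(pred, X[test])
        ok = ~np.isnan(oof)
        if ok.sum() < 3 or np.var(y[ok]) == 0 or np.var(oof[ok]) == 0:
            continue
        r, _ = pearson(y[ok], oof[ok])
        if r > best_r:  # strict: ties keep the smaller d (candidates ascend)
            best_d, best_r = d, r
    return best_d


def fit_scale_predictor(
    embeddings: np.ndarray,
    totals: Sequence[float],
    plan: CVPlan,
    groups: Sequence,
    grid: Sequence[int] = (2, 3, 5, 8, 12, 18, 27, 40, 60, 90, 135, 200, 300),
    inner_folds: int = 5,
    seed: int = 1,
    scale: str = "",
) -> tuple[ScalePredictor, np.ndarray, list[int]]:
    """Nested-CV scale regression.

    Returns the predictor refit on all rows (at the modal selected d,
    smaller d on ties), the per-row out-of-fold predictions, and the
    selected d of each outer fold.
    """
    X = np.asarray(embeddings, dtype=float)
    y = np.asarray(totals, dtype=float)
    groups = np.asarray(groups)
    row_fold = plan.fold_for_rows(groups)
    oof = np.full(len(y), np.nan)
    d_per_fold: list[int] = []
    for fold in range(plan.n_folds):
        test = row_fold == fold
        train = ~test
        if not test.any():
            continue
        d = _select_d_by_r(
            X[train], y[train], groups[train], grid, inner_folds, seed + fold, scale
        )
        d_per_fold.append(d)
        pred = _fit_d(X[train], y[train], d, scale)
        oof[test] = estimate_scores(pred, X[test])
    values, counts = np.unique(d_per_fold, return_counts=True)
    modal_d = int(values[np.argmax(counts)])  # np.unique ascends: ties -> smaller d
    final = _fit_d(X, y, modal_d, scale)
    return final, oof, d_per_fold


def subgroup_score_summary(
    totals: pd.DataFrame,
    estimates: pd.DataFrame,
    paq_groups: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Means/SDs of empirical and word-estimated totals by PAQ group.

    For each scale, two-tailed pooled t-tests compare the low/high group
    means and two-tailed variance-ratio F-tests compare their SDs, for the
    empirical totals and the word-based estimates alike. Bonferroni flags
    are added across each test family.
    """
    groups = np.asarray(paq_groups)
    rows = []
    for scale in totals.columns:
        row: dict[str, float | str] = {"scale": scale}
        for label, frame in (("rs", totals), ("words", estimates)):
            if scale not in frame.columns:
                continue
            x = frame[scale].to_numpy(float)
            lo, hi = x[groups == "low"], x[groups == "high"]
            row[f"{label}_mean_low"] = lo.mean() if lo.size else UNDEFINED
            row[f"{label}_mean_high"] = hi.mean() if hi.size else UNDEFINED
            row[f"{label}_sd_low"] = lo.std(ddof=1) if lo.size > 1 else UNDEFINED
            row[f"{label}_sd_high"] = hi.std(ddof=1) if hi.size > 1 else UNDEFINED
            if lo.size >= 2 and hi.size >= 2:
                row[f"{label}_p_mean"] = two_sample_t(lo, hi).p_value
                row[f"{label}_p_sd"] = variance_f_test(lo, hi).p_value
            else:
                row[f"{label}_p_mean"] = UNDEFINED
                row[f"{label}_p_sd"] = UNDEFINED
        rows.append(row)
    out = pd.DataFrame(rows).set_index("scale")
    for col in [c for c in out.columns if c.startswith(("rs_p", "words_p"))]:
        p = out[col].to_numpy(float)
        ok = ~np.isnan(p)
        flags = np.zeros(len(p), dtype=bool)
        if ok.any():
            flags[ok] = bonferroni(p[ok], alpha)
        out[col + "_bonferroni"] = flags
    return out


class ScaleRegression:
    """Model object: predict one scale's totals from response embeddings."""

    def __init__(
        self,
        embeddings: np.ndarray,
        totals: Sequence[float],
        groups: Sequence,
        scale: str = "",
        n_folds: int = 10,
        grid: Sequence[int] = (2, 3, 5, 8, 12, 18, 27, 40, 60, 90, 135, 200, 300),
        inner_folds: int = 5,
        seed: int = 1,
    ) -> None:
        self.embeddings = np.asarray(embeddings, dtype=float)
        self.totals = np.asarray(totals, dtype=float)
        self.groups = np.asarray(groups)
        self.scale = scale
        self.n_folds = n_folds
        self.grid = tuple(grid)
        self.inner_folds = inner_folds
        self.seed = seed

    def fit(self) -> "ScaleRegressionResults":
        plan = make_grouped_folds(self.groups, self.n_folds, self.seed)
        predictor, oof, d_per_fold = fit_scale_predictor(
            self.embeddings,
            self.totals,
            plan,
            self.groups,
            grid=self.grid,
            inner_folds=self.inner_folds,
            seed=self.seed,
            scale=self.scale,
        )
        return ScaleRegressionResults(self, plan, predictor, oof, d_per_fold)


class ScaleRegressionResults:
    def __init__(
        self,
        model: ScaleRegression,
        plan: CVPlan,
        predictor: ScalePredictor,
        oof_predictions: np.ndarray,
        d_per_fold: list[int],
    ) -> None:
        self.model = model
        self.plan = plan
        self.predictor = predictor
        self.oof_predictions = oof_predictions
        self.d_per_fold = d_per_fold

    @property
    def r_oof(self) -> float:
        """Out-of-fold predicted-vs-empirical Pearson correlation."""
        y = self.model.totals
        ok = ~np.isnan(self.oof_predictions)
        if ok.sum() < 3 or np.var(y[ok]) == 0 or np.var(self.oof_predictions[ok]) == 0:
            return UNDEFINED
        r, _ = pearson(y[ok], self.oof_predictions[ok])
        return r

    @property
    def p_oof(self) -> float:
        y = self.model.totals
        ok = ~np.isnan(self.oof_predictions)
        if ok.sum() < 3 or np.var(y[ok]) == 0 or np.var(self.oof_predictions[ok]) == 0:
            return UNDEFINED
        _, p = pearson(y[ok], self.oof_predictions[ok])
        return p

    def estimate(self, embeddings: np.ndarray) -> np.ndarray:
        return estimate_scores(self.predictor, embeddings)

    def summary(self) -> str:
        return "\n".join(
            [
                f"Scale regression: {self.model.scale or '(unnamed)'}",
                "=" * 40,
                f"rows: {len(self.model.totals)}    folds: {self.plan.n_folds}",
                f"selected d per fold: {self.d_per_fold} (final {self.predictor.d_selected})",
                f"out-of-fold Pearson r: {self.r_oof:.3f} (p = {self.p_oof:.4g})",
            ]
        )
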