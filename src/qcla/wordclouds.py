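"""Ranked word tables ("word clouds").

Every vocabulary word, embedded as its own unit vector, is scored by a
trained model: a multinomial classifier yields one score per emotion class
(the class logit), a scale predictor yields the word's estimated scale
value. The top-k words per target (25 by default), with corpus frequency
attached, form the cloud; output is tabular, not graphical.

Significance of a word's score is assessed against a label-permutation
null: the model is refit under permuted targets, the word rescored, and a
one-sided permutation p-value computed, Bonferroni-corrected across the
vocabulary.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import scales as _scales
from .classification import TrainedClassifier, fit_multinomial, predict
from .evaluation import bonferroni
from .regression import ScalePredictor, estimate_scores
from .semantic import SemanticSpace

logger = logging.getLogger(__name__)

__all__ = [
    "word_coefficients",
    "top_k",
    "significance_screen",
    "scale_word_significance",
    "paq_phq_cells",
]

DEFAULT_TOP_K = 25


def _word_feature_matrix(space: SemanticSpace, clf: TrainedClassifier) -> np.ndarray:
    """Vocabulary vectors padded with neutral scale columns if the model has them."""
    X = space.vectors
    n_rs = len(clf.scale_mean)
    if n_rs:
        X = np.hstack([X, np.tile(clf.scale_mean, (X.shape[0], 1))])
    return X


def word_coefficients(
    space: SemanticSpace,
    model: TrainedClassifier | ScalePredictor,
) -> pd.DataFrame:
    """Score every vocabulary word with a trained model.

    Returns a frame indexed by word with one column per target (emotion
    classes for a classifier, the scale name for a predictor) plus a
    ``frequency`` column with the word's corpus occurrence count.
    """
    if isinstance(model, TrainedClassifier):
        X = _word_feature_matrix(space, model)
        design = model.design(X)
        logits = model.estimator.decision_function(design)
        if logits.ndim == 1:  # two-class edge: decision for classes_[1]
            logits = np.column_stack([-logits, logits])
        frame = pd.DataFrame(0.0, index=space.vocabulary, columns=list(model.class_order))
        for j, cls in enumerate(model.estimator.classes_):
            frame[cls] = logits[:, j]
    elif isinstance(model, ScalePredictor):
        values = estimate_scores(model, space.vectors)
        frame = pd.DataFrame({model.scale or "score": values}, index=space.vocabulary)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    frame["frequency"] = [space.word_frequency.get(w, 1) for w in space.vocabulary]
    frame.index.name = "word"
    return frame


def top_k(
    entries: pd.DataFrame,
    k: int = DEFAULT_TOP_K,
    target: str | None = None,
) -> pd.DataFrame:
    """The k highest-scoring words for one target column.

    Ties break by higher corpus frequency, then lexicographically.
    Returns columns ``rank, word, coefficient, frequency``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if target is None:
        candidates = [c for c in entries.columns if c != "frequency"]
        if len(candidates) != 1:
            raise ValueError("target must be named when several score columns exist")
        target = candidates[0]
    frame = entries.reset_index()
    word_col = frame.columns[0]
    frame = frame.rename(columns={word_col: "word", target: "coefficient"})
    frame = frame.sort_values(
        by=["coefficient", "frequency", "word"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    if k > len(frame):
        logger.warning("k=%d exceeds vocabulary size %d; returning all", k, len(frame))
        k = len(frame)
    out = frame.head(k)[["word", "coefficient", "frequency"]].reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def significance_screen(
    observed: Sequence[float],
    permuted_scores: Callable[[np.random.Generator], np.ndarray],
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values for per-word scores with Bonferroni flags.

    ``permuted_scores(rng)`` must return the per-word score vector under
    one permutation of the target labels. The one-sided p-value for word i
    is ``(1 + #{permutations with score_i >= observed_i}) / (B + 1)``.
    """
    observed = np.asarray(observed, dtype=float)
    if n_permutations < 100:
        raise ValueError("at least 100 permutations are required")
    m = observed.size
    floor = 1.0 / (n_permutations + 1)
    if m and floor > alpha / m:
        logger.warning(
            "permutation floor %.2g exceeds Bonferroni threshold %.2g; "
            "no word can reach significance at this permutation count",
            floor,
            alpha / m,
        )
    rng = np.random.default_rng(seed)
    exceed = np.zeros(m, dtype=int)
    for _ in range(n_permutations):
        exceed += permuted_scores(rng) >= observed
    p = (1 + exceed) / (n_permutations + 1)
    return p, bonferroni(p, alpha)


def scale_word_significance(
    embeddings: np.ndarray,
    totals: Sequence[float],
    space: SemanticSpace,
    d: int,
    scale: str = "",
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 1,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Screen per-word scale estimates against a shuffled-totals null.

    Fits the d-dimension OLS scale predictor on the observed totals, then
    repeatedly on permuted totals, scoring the vocabulary each time.
    Returns the observed word-score frame, the raw p-values and the
    Bonferroni flags (aligned with ``space.vocabulary``).
    """
    from .regression import _fit_d  # local import to avoid cycle at import time

    X = np.asarray(embeddings, dtype=float)
    y = np.asarray(totals, dtype=float)
    predictor = _fit_d(X, y, d, scale)
    frame = word_coefficients(space, predictor)
    observed = frame[scale or "score"].to_numpy()

    def permuted(rng: np.random.Generator) -> np.ndarray:
        perm = _fit_d(X, rng.permutation(y), d, scale)
        return estimate_scores(perm, space.vectors)

    p, flags = significance_screen(
        observed, permuted, n_permutations=n_permutations, alpha=alpha, seed=seed
    )
    frame["p_raw"] = p
    frame["significant_bonferroni"] = flags
    return frame, p, flags


def paq_phq_cells(
    records: pd.DataFrame,
    space: SemanticSpace,
    paq_threshold: int = _scales.PAQ_SPLIT_DEFAULT,
    d: int | None = None,
    k_words: int = DEFAULT_TOP_K,
    ridge: float = 1e-2,
) -> dict[str, pd.DataFrame]:
    """Word clouds for the four low/high PAQ x low/high PHQ-9 cells.

    Records are split at the PAQ threshold (68 by default) and at the
    sample median of the PHQ-9 total (ties low). A multinomial model over
    the four cell labels scores the vocabulary; each cell's cloud is the
    top-k words for its logit. Empty cells yield empty clouds with a
    warning.
    """
    from .representation import embed_table

    totals = _scales.score_records(records, ("PHQ9", "PAQ"))
    kept = totals.index
    words = [
        records.loc[i, "words"].split(";")
        if isinstance(records.loc[i, "words"], str)
        else list(records.loc[i, "words"])
        for i in kept
    ]
    X, kept_pos, _ = embed_table(words, space)
    kept = kept[kept_pos]
    paq = totals.loc[kept, "PAQ_total"].to_numpy()
    phq = totals.loc[kept, "PHQ9_total"].to_numpy()
    paq_lab = _scales.paq_split(paq, paq_threshold)
    phq_lab = np.where(phq <= _scales.median_threshold(phq), "low", "high")
    cells = np.array([f"paq_{a}_phq_{b}" for a, b in zip(paq_lab, phq_lab)])
    order = tuple(
        f"paq_{a}_phq_{b}" for a in ("low", "high") for b in ("low", "high")
    )
    clouds: dict[str, pd.DataFrame] = {}
    present = tuple(c for c in order if (cells == c).any())
    for cell in order:
        if cell not in present:
            logger.warning("cell %s is empty; emitting an empty cloud", cell)
            clouds[cell] = pd.DataFrame(
                columns=["rank", "word", "coefficient", "frequency"]
            )
    if len(present) < 2:
        logger.warning("fewer than two populated cells; no model can be fitted")
        for cell in present:
            clouds[cell] = pd.DataFrame(
                columns=["rank", "word", "coefficient", "frequency"]
            )
        return clouds
    if d is None:
        d = min(space.k, 40)
    clf = fit_multinomial(X, cells, ridge=ridge, d=d, class_order=present)
    scores = word_coefficients(space, clf)
    for cell in present:
        clouds[cell] = top_k(scores[[cell, "frequency"]], k=k_words, target=cell)
    return {cell: clouds[cell] for cell in order}
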