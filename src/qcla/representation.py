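"""Embedding five-word responses in the semantic space.

A response's representation is the normalised sum of its words' vectors.
Out-of-vocabulary words are skipped (the in-vocabulary subset is embedded)
and counted; a response with no known word has no representation and is
excluded downstream.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .semantic import SemanticSpace

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseVector",
    "MissingRepresentationError",
    "normalize_token",
    "embed_response",
    "embed_table",
]

_STRIP = string.punctuation + string.whitespace


class MissingRepresentationError(ValueError):
    """No word of a response exists in the semantic space."""


@dataclass
class ResponseVector:
    vector: np.ndarray
    n_known: int
    source_words: list[str]


def normalize_token(word: str) -> str:
    """Lowercase and strip surrounding punctuation; no spelling correction."""
    return word.lower().strip(_STRIP)


def embed_response(words: Sequence[str], space: SemanticSpace) -> ResponseVector:
    """Sum the word vectors of the in-vocabulary words and renormalise.

    Word count is not enforced (the elicitation asks for five words, but
    the operation accepts any positive number; a warning is logged when
    the count differs from five).
    """
    tokens = [normalize_token(w) for w in words if normalize_token(w)]
    if not tokens:
        raise ValueError("embed_response requires at least one word")
    if len(tokens) != 5:
        logger.warning("response has %d words, expected 5", len(tokens))
    known = [t for t in tokens if t in space]
    if not known:
        raise MissingRepresentationError(
            f"no in-vocabulary word among {tokens!r}"
        )
    total = np.sum([space.vector(t) for t in known], axis=0)
    norm = np.linalg.norm(total)
    if norm == 0:
        # antipodal word vectors cancelling exactly; treat as unembeddable
        raise MissingRepresentationError(
            f"word vectors of {known!r} cancel to the zero vector"
        )
    return ResponseVector(vector=total / norm, n_known=len(known), source_words=list(words))


def embed_table(
    word_lists: Iterable[Sequence[str]], space: SemanticSpace
) -> tuple[np.ndarray, list[int], list[int]]:
    """Embed many responses.

    Returns
    -------
    matrix : ndarray, shape (n_kept, k)
        One unit-norm row per embeddable response, in input order.
    kept : list of int
        Positional indices of the embedded responses.
    excluded : list of int
        Positional indices of responses with no in-vocabulary word.
    """
    rows, kept, excluded = [], [], []
    for i, words in enumerate(word_lists):
        try:
            rows.append(embed_response(words, space).vector)
            kept.append(i)
        except (MissingRepresentationError, ValueError) as exc:
            logger.warning("excluding response %d: %s", i, exc)
            excluded.append(i)
    matrix = np.asarray(rows) if rows else np.empty((0, space.k))
    return matrix, kept, excluded
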