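"""Latent-semantic-analysis word space.

A corpus of short word responses (each response = one context) is turned
into word vectors in three steps:

1. a symmetric word-by-word co-occurrence table, where cell (i, j) counts
   the contexts containing both words and the diagonal counts the contexts
   containing the word at all (context-level counting: duplicates within a
   response count once);
2. an elementwise log(1 + count) transform, which keeps the table sparse
   (zeros stay zero);
3. a truncated singular value decomposition. Word i is represented by row i
   of U·S restricted to the k leading dimensions (k = 300 by default) and
   renormalised to unit Euclidean length.

Sign indeterminacy of the SVD is resolved by forcing the largest-magnitude
entry of every left singular vector to be positive, which makes the space
bit-reproducible for a fixed input.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

logger = logging.getLogger(__name__)

__all__ = [
    "Corpus",
    "CooccurrenceMatrix",
    "SemanticSpace",
    "build_cooccurrence",
    "log_transform",
    "build_space",
    "build_space_from_corpus",
    "cosine",
]

DEFAULT_K = 300


@dataclass
class Corpus:
    """Word responses, one list of tokens per response context."""

    responses: list[list[str]]
    vocabulary: list[str] = field(init=False)
    word_frequency: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        freq: dict[str, int] = {}
        for resp in self.responses:
            for w in resp:
                freq[w] = freq.get(w, 0) + 1
        self.vocabulary = sorted(freq)
        self.word_frequency = freq

    @classmethod
    def from_text(cls, path: str | Path) -> "Corpus":
        """Read one whitespace-tokenised response per line."""
        responses = []
        for line in Path(path).read_text().splitlines():
            tokens = line.split()
            if tokens:
                responses.append(tokens)
        return cls(responses)

    def to_text(self, path: str | Path) -> None:
        Path(path).write_text(
            "\n".join(" ".join(r) for r in self.responses) + "\n"
        )

    @property
    def n_tokens(self) -> int:
        return sum(self.word_frequency.values())

    def __len__(self) -> int:
        return len(self.responses)


@dataclass
class CooccurrenceMatrix:
    """Symmetric context-level co-occurrence counts over a vocabulary."""

    vocabulary: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.vocabulary)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match vocabulary size")

    def toarray(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


def build_cooccurrence(corpus: Corpus) -> CooccurrenceMatrix:
    """Count, for every word pair, the contexts containing both words.

    Implemented as X.T @ X with X the binary response-by-word incidence
    matrix, so the diagonal holds per-word context counts.
    """
    if len(corpus) == 0:
        raise ValueError("cannot build a co-occurrence table from an empty corpus")
    index = {w: i for i, w in enumerate(corpus.vocabulary)}
    rows, cols = [], []
    for r, resp in enumerate(corpus.responses):
        for w in set(resp):
            rows.append(r)
            cols.append(index[w])
    incidence = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(corpus), len(corpus.vocabulary)),
    )
    counts = (incidence.T @ incidence).tocsr()
    return CooccurrenceMatrix(corpus.vocabulary, counts)


def log_transform(matrix: CooccurrenceMatrix | sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Elementwise natural log(1 + count); zeros map to zeros."""
    counts = matrix.counts if isinstance(matrix, CooccurrenceMatrix) else matrix
    counts = sp.csr_matrix(counts, dtype=np.float64)
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("co-occurrence counts must be nonnegative")
    return counts.log1p()


@dataclass
class SemanticSpace:
    """Unit-norm word vectors in the truncated SVD space."""

    vocabulary: list[str]
    vectors: np.ndarray  # (n_words, k), rows unit-norm
    singular_values: np.ndarray  # (k,), nonincreasing
    k: int
    word_frequency: dict[str, int] = field(default_factory=dict)
    weighting: str = "us"

    def __post_init__(self) -> None:
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __len__(self) -> int:
        return len(self.vocabulary)

    def vector(self, word: str) -> np.ndarray:
        """The unit-norm vector of a vocabulary word."""
        return self.vectors[self._index[word]]

    def save(self, vectors_path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write the space as TSV (word + components) with a JSON sidecar."""
        vectors_path = Path(vectors_path)
        if meta_path is None:
            meta_path = vectors_path.with_suffix(".json")
        with vectors_path.open("w") as fh:
            for word, vec in zip(self.vocabulary, self.vectors):
                fh.write(word + "\t" + "\t".join(f"{v:.10g}" for v in vec) + "\n")
        checksum = hashlib.sha256(vectors_path.read_bytes()).hexdigest()
        Path(meta_path).write_text(
            json.dumps(
                {
                    "k": self.k,
                    "weighting": self.weighting,
                    "singular_values": self.singular_values.tolist(),
                    "word_frequency": self.word_frequency,
                    "vectors_sha256": checksum,
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, vectors_path: str | Path, meta_path: str | Path | None = None) -> "SemanticSpace":
        vectors_path = Path(vectors_path)
        if meta_path is None:
            meta_path = vectors_path.with_suffix(".json")
        meta = json.loads(Path(meta_path).read_text())
        words, rows = [], []
        for line in vectors_path.read_text().splitlines():
            parts = line.split("\t")
            words.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(
            vocabulary=words,
            vectors=np.asarray(rows),
            singular_values=np.asarray(meta["singular_values"]),
            k=meta["k"],
            word_frequency={k: int(v) for k, v in meta.get("word_frequency", {}).items()},
            weighting=meta.get("weighting", "us"),
        )


def _canonical_signs(u: np.ndarray) -> np.ndarray:
    """Flip singular-vector signs so each column's largest-|entry| is positive."""
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    return u * flip


def build_space(
    log_matrix: sp.spmatrix | np.ndarray,
    vocabulary: Sequence[str],
    k: int = DEFAULT_K,
    weighting: str = "us",
    word_frequency: dict[str, int] | None = None,
) -> SemanticSpace:
    """Truncated SVD of the log co-occurrence table into unit word vectors.

    Parameters
    ----------
    weighting : {"us", "u"}
        ``"us"`` (default) takes word vectors as rows of U·S, so
        dimensions carry their accounted variance before normalisation;
        ``"u"`` uses raw left singular vectors.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if weighting not in ("us", "u"):
        raise ValueError("weighting must be 'us' or 'u'")
    mat = sp.csr_matrix(log_matrix, dtype=np.float64)
    n = mat.shape[0]
    if mat.shape[0] != mat.shape[1] or n != len(vocabulary):
        raise ValueError("matrix must be square and match the vocabulary")
    k = min(k, n)

    if k >= n - 1 or n <= 200:
        # dense path: small tables, or k too close to n for iterative svds
        u, s, _ = np.linalg.svd(mat.toarray(), full_matrices=False)
    else:
        u, s, _ = svds(mat, k=k, v0=np.full(n, 1.0 / np.sqrt(n)))
        order = np.argsort(s)[::-1]
        u, s = u[:, order], s[order]

    tol = s[0] * max(mat.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank == 0:
        raise ValueError("matrix has rank zero; no semantic space can be built")
    if k > rank:
        logger.warning("requested k=%d exceeds rank %d; clamping", k, rank)
        k = rank
    u, s = _canonical_signs(u[:, :k]), s[:k]

    vecs = u * s if weighting == "us" else u.copy()
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    vecs = vecs / norms
    return SemanticSpace(
        vocabulary=list(vocabulary),
        vectors=vecs,
        singular_values=s,
        k=k,
        word_frequency=dict(word_frequency or {}),
        weighting=weighting,
    )


def build_space_from_corpus(
    corpus: Corpus, k: int = DEFAULT_K, weighting: str = "us"
) -> SemanticSpace:
    """Convenience: co-occurrence + log transform + SVD in one call."""
    cooc = build_cooccurrence(corpus)
    return build_space(
        log_transform(cooc),
        cooc.vocabulary,
        k=k,
        weighting=weighting,
        word_frequency=corpus.word_frequency,
    )


def cosine(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine similarity of two vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal length")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine is undefined for a zero vector")
    return float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
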