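"""Synthetic two-phase study generator.

Emulates the data-collection design the analysis assumes, so the full
pipeline is testable without the archived study data:

- four emotion conditions (harmony, satisfaction, depression, anxiety)
  with per-condition vocabularies; harmony and satisfaction share a larger
  fraction of their vocabularies than other pairs, mirroring the semantic
  closeness of the two positive states;
- five-word responses drawn from a noise mixture: with probability
  (1 - noise) from the condition's vocabulary, otherwise from another
  condition's, Zipf-weighted within each vocabulary;
- item-level rating scales whose condition-congruent scale (depression ->
  PHQ-9, anxiety -> GAD-7, satisfaction -> SWLS, harmony -> HILS) is
  mean-shifted upward;
- a PAQ (alexithymia) total per narrator; narrators above the split
  threshold produce noisier word choices, and their narratives inherit
  that noise in Phase 2 — the direction of the narrator-alexithymia
  effect;
- Phase-2 evaluators each read one Phase-1 narrative and respond with
  words and scales regenerated from the narrative's condition, keyed by
  the narrative id for grouped cross-validation. The evaluator's own PAQ
  does not influence the noise (the evaluator-side null).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import scales as _scales
from .evaluation import CLASS_ORDER
from .semantic import Corpus

__all__ = [
    "SyntheticConfig",
    "CONGRUENT_SCALE",
    "build_vocabularies",
    "generate_corpus",
    "generate_phase1",
    "generate_phase2",
    "generate_study",
    "records_to_frame",
]

#: Which rating scale each condition elevates.
CONGRUENT_SCALE = {
    "depression": "PHQ9",
    "anxiety": "GAD7",
    "satisfaction": "SWLS",
    "harmony": "HILS",
}


@dataclass
class SyntheticConfig:
    """All generator parameters.

    Defaults reflect the emulated study: 116 Phase-1 narrators, 232
    Phase-2 evaluators, a 7088-response training corpus, five words per
    response, and a PAQ distribution centred on the published split
    threshold of 68.
    """

    n_phase1: int = 116
    n_phase2: int = 232
    n_corpus_responses: int = 7088
    vocab_per_emotion: int = 150
    overlap_harmony_satisfaction: float = 0.30
    overlap_other: float = 0.05
    word_noise_low: float = 0.20
    word_noise_high: float = 0.40
    corpus_noise: float = 0.20
    words_per_response: int = 5
    scale_effect: float = 0.35  # item-level mean shift of the congruent scale
    scale_noise: float = 1.25  # item-level SD
    scale_base_quantile: float = 0.25  # baseline item mean within the range
    paq_mean: float = 68.0
    paq_sd: float = 20.0
    paq_threshold: int = _scales.PAQ_SPLIT_DEFAULT
    zipf_exponent: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "overlap_harmony_satisfaction",
            "overlap_other",
            "word_noise_low",
            "word_noise_high",
            "corpus_noise",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.word_noise_high < self.word_noise_low:
            raise ValueError("word_noise_high must be >= word_noise_low")
        if self.vocab_per_emotion < 1:
            raise ValueError("vocab_per_emotion must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def build_vocabularies(config: SyntheticConfig) -> dict[str, list[str]]:
    """Per-emotion vocabularies with pairwise shared word pools.

    Each emotion gets ``vocab_per_emotion`` words: a private core plus,
    for every other emotion, a shared pool whose size is the configured
    overlap fraction of the vocabulary (larger for harmony-satisfaction).
    """
    vocabs: dict[str, list[str]] = {e: [] for e in CLASS_ORDER}
    pair_sizes: dict[tuple[str, str], int] = {}
    for i, a in enumerate(CLASS_ORDER):
        for b in CLASS_ORDER[i + 1 :]:
            frac = (
                config.overlap_harmony_satisfaction
                if {a, b} == {"harmony", "satisfaction"}
                else config.overlap_other
            )
            pair_sizes[(a, b)] = int(round(frac * config.vocab_per_emotion))
    for (a, b), size in pair_sizes.items():
        shared = [f"{a[:3]}{b[:3]}_s{i:03d}" for i in range(size)]
        vocabs[a].extend(shared)
        vocabs[b].extend(shared)
    for e in CLASS_ORDER:
        private = config.vocab_per_emotion - len(vocabs[e])
        if private < 0:
            raise ValueError("overlap fractions exceed the vocabulary size")
        vocabs[e].extend(f"{e[:3]}_w{i:03d}" for i in range(private))
    return vocabs


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def _draw_words(
    condition: str,
    noise: float,
    vocabs: dict[str, list[str]],
    rng: np.random.Generator,
    config: SyntheticConfig,
) -> list[str]:
    others = [e for e in CLASS_ORDER if e != condition]
    words = []
    for _ in range(config.words_per_response):
        source = condition if rng.random() >= noise else others[rng.integers(len(others))]
        vocab = vocabs[source]
        words.append(vocab[rng.choice(len(vocab), p=_zipf_weights(len(vocab), config.zipf_exponent))])
    return words


def _draw_scale_items(
    condition: str, rng: np.random.Generator, config: SyntheticConfig
) -> dict[str, int]:
    items: dict[str, int] = {}
    for name in ("PHQ9", "GAD7", "SWLS", "HILS"):
        d = _scales.SCALES[name]
        base = d.item_min + config.scale_base_quantile * (d.item_max - d.item_min)
        shift = config.scale_effect if CONGRUENT_SCALE[condition] == name else 0.0
        raw = rng.normal(base + shift, config.scale_noise, size=d.n_items)
        vals = np.clip(np.rint(raw), d.item_min, d.item_max).astype(int)
        for i, v in enumerate(vals, start=1):
            items[f"{d.column_prefix}_{i}"] = int(v)
    return items


def _draw_paq_items(rng: np.random.Generator, config: SyntheticConfig) -> dict[str, int]:
    d = _scales.SCALES["PAQ"]
    target = float(
        np.clip(rng.normal(config.paq_mean, config.paq_sd), d.total_min, d.total_max)
    )
    raw = rng.normal(target / d.n_items, 0.8, size=d.n_items)
    vals = np.clip(np.rint(raw), d.item_min, d.item_max).astype(int)
    return {f"{d.column_prefix}_{i}": int(v) for i, v in enumerate(vals, start=1)}


def generate_corpus(config: SyntheticConfig, rng: np.random.Generator | None = None) -> Corpus:
    """Training corpus of word responses, balanced over conditions."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vocabs = build_vocabularies(config)
    if any(not v for v in vocabs.values()):
        raise ValueError("every emotion needs a nonempty vocabulary")
    responses = [
        _draw_words(CLASS_ORDER[i % 4], config.corpus_noise, vocabs, rng, config)
        for i in range(config.n_corpus_responses)
    ]
    return Corpus(responses)


def _record(
    respondent_id: str,
    narrative_id: str,
    phase: int,
    condition: str,
    words: list[str],
    scale_items: dict[str, int],
    paq_items: dict[str, int],
    narrator_paq: int,
) -> dict:
    rec = {
        "respondent_id": respondent_id,
        "narrative_id": narrative_id,
        "phase": phase,
        "condition": condition,
        "words": ";".join(words),
        "narrator_paq": narrator_paq,
    }
    rec.update(scale_items)
    rec.update(paq_items)
    return rec


def generate_phase1(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Narrator records: one narrative per narrator, conditions balanced."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vocabs = build_vocabularies(config)
    rows = []
    for i in range(config.n_phase1):
        condition = CLASS_ORDER[i % 4]
        paq_items = _draw_paq_items(rng, config)
        paq_total = sum(paq_items.values())
        noise = (
            config.word_noise_high
            if paq_total > config.paq_threshold
            else config.word_noise_low
        )
        words = _draw_words(condition, noise, vocabs, rng, config)
        rows.append(
            _record(
                f"p1_{i:04d}",
                f"n{i:04d}",
                1,
                condition,
                words,
                _draw_scale_items(condition, rng, config),
                paq_items,
                paq_total,
            )
        )
    return pd.DataFrame(rows)


def generate_phase2(
    phase1: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Evaluator records tied to Phase-1 narratives.

    Word-choice noise follows the *narrator's* PAQ group (high-alexithymia
    narratives are harder to summarise); the evaluator's own PAQ is drawn
    independently and has no effect on difficulty.
    """
    if len(phase1) == 0:
        raise ValueError("phase1 records are required")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    vocabs = build_vocabularies(config)
    narratives = phase1[["narrative_id", "condition", "narrator_paq"]].to_numpy()
    rows = []
    for j in range(config.n_phase2):
        narrative_id, condition, narrator_paq = narratives[j % len(narratives)]
        noise = (
            config.word_noise_high
            if narrator_paq > config.paq_threshold
            else config.word_noise_low
        )
        words = _draw_words(condition, noise, vocabs, rng, config)
        rows.append(
            _record(
                f"p2_{j:04d}",
                narrative_id,
                2,
                condition,
                words,
                _draw_scale_items(condition, rng, config),
                _draw_paq_items(rng, config),
                int(narrator_paq),
            )
        )
    return pd.DataFrame(rows)


def generate_study(
    config: SyntheticConfig,
) -> tuple[Corpus, pd.DataFrame, pd.DataFrame]:
    """Corpus plus both phases from one seed; deterministic per config."""
    rng = np.random.default_rng(config.seed)
    corpus = generate_corpus(config, rng)
    phase1 = generate_phase1(config, rng)
    phase2 = generate_phase2(phase1, config, rng)
    return corpus, phase1, phase2


def records_to_frame(phase1: pd.DataFrame, phase2: pd.DataFrame) -> pd.DataFrame:
    """Stack the two phases into one record table with a fresh index."""
    return pd.concat([phase1, phase2], ignore_index=True)
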