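"""Rating-scale scoring and alexithymia stratification.

Five self-report instruments are supported:

========  =======  ==========  ===========
scale     items    item range  total range
========  =======  ==========  ===========
PHQ-9     9        0-3         0-27
GAD-7     7        0-3         0-21
SWLS      5        1-7         5-35
HILS      5        1-7         5-35
PAQ       24       1-7         24-168
========  =======  ==========  ===========

Totals are plain sums of the item values as supplied; no reverse keying is
applied (callers pre-orient items if their instrument requires it).
Participants are stratified into low/high alexithymia by a median split on
the PAQ total, with ties assigned to the low group (PAQ <= threshold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleDefinition",
    "ScaleScores",
    "SCALES",
    "SCALE_NAMES",
    "PAQ_SPLIT_DEFAULT",
    "scale_columns",
    "score_scale",
    "score_records",
    "paq_split",
    "median_threshold",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """Static description of one rating scale."""

    name: str
    n_items: int
    item_min: int
    item_max: int

    @property
    def total_min(self) -> int:
        return self.n_items * self.item_min

    @property
    def total_max(self) -> int:
        return self.n_items * self.item_max

    @property
    def column_prefix(self) -> str:
        return self.name.lower().replace("-", "")


SCALES: dict[str, ScaleDefinition] = {
    "PHQ9": ScaleDefinition("PHQ9", 9, 0, 3),
    "GAD7": ScaleDefinition("GAD7", 7, 0, 3),
    "SWLS": ScaleDefinition("SWLS", 5, 1, 7),
    "HILS": ScaleDefinition("HILS", 5, 1, 7),
    "PAQ": ScaleDefinition("PAQ", 24, 1, 7),
}

#: Scale order used throughout (the four emotion scales, then PAQ).
SCALE_NAMES: tuple[str, ...] = ("PHQ9", "GAD7", "SWLS", "HILS", "PAQ")

#: Published PAQ median-split threshold.
PAQ_SPLIT_DEFAULT = 68


def scale_columns(name: str) -> list[str]:
    """Item column names for one scale, e.g. ``phq9_1`` .. ``phq9_9``."""
    d = SCALES[name]
    return [f"{d.column_prefix}_{i}" for i in range(1, d.n_items + 1)]


@dataclass
class ScaleScores:
    """Totals and item answers for one respondent across all scales."""

    totals: dict[str, int]
    items: dict[str, list[int]]

    def __post_init__(self) -> None:
        for name, values in self.items.items():
            if name in self.totals and self.totals[name] != sum(values):
                raise ValueError(f"{name}: total does not equal the item sum")


def score_scale(items: Sequence[int], definition: ScaleDefinition) -> int:
    """Sum item answers into a scale total.

    Raises
    ------
    ValueError
        If the item count does not match the scale, or an item falls
        outside the scale's response range (the message names the index).
    """
    items = list(items)
    if len(items) != definition.n_items:
        raise ValueError(
            f"{definition.name} expects {definition.n_items} items, "
            f"got {len(items)}"
        )
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"{definition.name} item {i + 1} is missing")
        if not definition.item_min <= v <= definition.item_max:
            raise ValueError(
                f"{definition.name} item {i + 1} value {v} outside "
                f"[{definition.item_min}, {definition.item_max}]"
            )
    return int(sum(items))


def score_records(
    frame: pd.DataFrame, scales: Iterable[str] = SCALE_NAMES
) -> pd.DataFrame:
    """Score every requested scale for each row of a response table.

    Rows with missing or out-of-range items are dropped (not imputed),
    with a logged warning, mirroring the exclusion of incomplete surveys.
    Returns a frame of ``<scale>_total`` columns indexed like the kept rows.
    """
    scales = list(scales)
    totals: dict[int, dict[str, int]] = {}
    dropped: list[int] = []
    for idx, row in frame.iterrows():
        scored: dict[str, int] = {}
        try:
            for name in scales:
                cols = scale_columns(name)
                scored[f"{name}_total"] = score_scale(
                    [row[c] for c in cols], SCALES[name]
                )
        except (ValueError, KeyError) as exc:
            logger.warning("excluding row %r: %s", idx, exc)
            dropped.append(idx)
            continue
        totals[idx] = scored
    if dropped:
        logger.warning(
            "excluded %d of %d records with incomplete or invalid scale items",
            len(dropped),
            len(frame),
        )
    return pd.DataFrame.from_dict(totals, orient="index").astype(int)


def paq_split(
    paq_totals: Sequence[int] | np.ndarray,
    threshold: int = PAQ_SPLIT_DEFAULT,
) -> np.ndarray:
    """Label each PAQ total ``low`` (total <= threshold) or ``high``.

    The tie rule follows the published split: scores exactly at the
    threshold belong to the low-alexithymia group.
    """
    totals = np.asarray(paq_totals)
    if totals.size == 0:
        raise ValueError("paq_split requires at least one total")
    paq = SCALES["PAQ"]
    if totals.min() < paq.total_min or totals.max() > paq.total_max:
        raise ValueError(
            f"PAQ totals must lie in [{paq.total_min}, {paq.total_max}]"
        )
    return np.where(totals <= threshold, "low", "high")


def median_threshold(paq_totals: Sequence[int] | np.ndarray) -> int:
    """Sample median of PAQ totals, floored to an integer for even n.

    Flooring keeps the threshold an attainable integer score, matching the
    style of the published cut-off (68).
    """
    totals = np.asarray(paq_totals)
    if totals.size == 0:
        raise ValueError("median_threshold requires at least one total")
    return int(math.floor(float(np.median(totals))))
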