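"""Reading and writing response-record tables.

The on-disk format is a headed CSV with columns::

    respondent_id, narrative_id, phase, condition, words,
    phq9_1..phq9_9, gad7_1..gad7_7, swls_1..swls_5, hils_1..hils_5,
    paq_1..paq_24 [, narrator_paq]

``words`` is a semicolon-separated word list.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import scales as _scales

__all__ = ["RECORD_COLUMNS", "read_records", "write_records"]

RECORD_COLUMNS: list[str] = (
    ["respondent_id", "narrative_id", "phase", "condition", "words"]
    + [c for s in _scales.SCALE_NAMES for c in _scales.scale_columns(s)]
)


def read_records(path: str | Path) -> pd.DataFrame:
    """Load a response-record CSV, checking the required columns exist."""
    frame = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"record file {path} is missing columns: {missing[:6]}")
    frame["phase"] = frame["phase"].astype(int)
    return frame


def write_records(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
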