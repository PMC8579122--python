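"""Headered-CSV readers and writers for the pipeline's file formats.

All formats are plain CSV with fixed column sets:

* events:  ``panellist,sample,onset_ri,descriptor,intensity``
* peaks:   ``peak_id,sample,replicate,rt_min,area,is_internal_standard``
* ladder:  ``carbon_n,rt_min``
* scores:  ``assessor,sample,packaging,weeks,replicate,attribute,value``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .gco import EVENT_COLUMNS
from .ri import AlkaneLadder
from .sensory import SCORE_COLUMNS

PEAK_COLUMNS = ["peak_id", "sample", "replicate", "rt_min", "area", "is_internal_standard"]
LADDER_COLUMNS = ["carbon_n", "rt_min"]


def _read_checked(path, required, name):
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} file {path} missing columns {missing}")
    return df


def read_events(path) -> pd.DataFrame:
    return _read_checked(path, EVENT_COLUMNS, "events")


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    events[EVENT_COLUMNS].to_csv(path, index=False)
    return path


def read_peaks(path) -> pd.DataFrame:
    return _read_checked(path, PEAK_COLUMNS, "peaks")


def write_peaks(peaks: pd.DataFrame, path) -> Path:
    path = Path(path)
    peaks[PEAK_COLUMNS].to_csv(path, index=False)
    return path


def read_ladder(path) -> AlkaneLadder:
    return AlkaneLadder.from_dataframe(_read_checked(path, LADDER_COLUMNS, "ladder"))


def write_ladder(ladder: AlkaneLadder, path) -> Path:
    path = Path(path)
    ladder.to_dataframe().to_csv(path, index=False)
    return path


def read_scores(path) -> pd.DataFrame:
    return _read_checked(path, SCORE_COLUMNS, "scores")


def write_scores(scores: pd.DataFrame, path) -> Path:
    path = Path(path)
    scores[SCORE_COLUMNS].to_csv(path, index=False)
    return path
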