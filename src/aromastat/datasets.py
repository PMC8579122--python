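"""Bundled reference tables from the sterilised-chickpea GC-O panel study.

Two small CSV fixtures ship with the package:

* the full odour-active compound table (40 elution regions, four samples:
  week 0 and week 52 of storage in aluminium and plastic pouches, labelled
  ``A0, A52, P0, P52``) with per-sample nasal impact frequency (NIF, %),
  intensity score (IS, %), odour importance (OI, %) and peak areas relative
  to the internal standard, and
* the ranked shortlist of high-impact odorants derived from it.

They serve as ground truth for the scoring arithmetic and as a realistic
scenario for the synthetic generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Sample codes used throughout: packaging (Aluminium/Plastic) + storage weeks.
SAMPLES = ("A0", "A52", "P0", "P52")


def _read(name: str) -> pd.DataFrame:
    with resources.files("aromastat.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_gco_table() -> pd.DataFrame:
    """Full odour-active region table (one row per compound/region)."""
    return _read("chickpea_gco_table4.csv")


def load_important_compounds() -> pd.DataFrame:
    """Ranked high-impact odorant shortlist (one row per compound)."""
    return _read("chickpea_gco_table5.csv")


def gco_long(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tidy long view of the region table: one row per compound x sample.

    Columns: ``compound, sample, nif, intensity_score, odour_importance``.
    """
    if table is None:
        table = load_gco_table()
    frames = []
    for s in SAMPLES:
        frames.append(
            pd.DataFrame(
                {
                    "compound": table["compound"],
                    "sample": s,
                    "nif": table[f"nif_{s}"],
                    "intensity_score": table[f"is_{s}"],
                    "odour_importance": table[f"oi_{s}"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
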