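"""Retention-index calibration against an n-alkane ladder.

A homologous series of n-alkanes (typically C6-C22) is run under the same
temperature-programmed GC method as the samples; the retention index (RI) of
any retention time is then obtained by linear interpolation between the two
bracketing alkanes (van den Dool & Kratz), so that alkane C_n maps to exactly
100*n.  Retention times falling outside the ladder are linearly extrapolated
from the nearest segment and flagged, because sniff onsets may precede the
first alkane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlkaneLadder",
    "RiValue",
    "retention_index",
    "retention_indices",
    "match_region_to_peak",
]


@dataclass(frozen=True)
class AlkaneLadder:
    """Monotone carbon-number -> retention-time calibration.

    Parameters
    ----------
    carbon_numbers : sequence of int
        Strictly increasing alkane carbon numbers.
    retention_times : sequence of float
        Strictly increasing retention times (minutes), one per alkane.
    """

    carbon_numbers: tuple = field()
    retention_times: tuple = field()

    def __init__(self, carbon_numbers: Sequence[int], retention_times: Sequence[float]):
        c = tuple(int(x) for x in carbon_numbers)
        rt = tuple(float(x) for x in retention_times)
        if len(c) != len(rt):
            raise ValueError("carbon_numbers and retention_times differ in length")
        if len(c) < 2:
            raise ValueError("an alkane ladder needs at least 2 entries")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rt, rt[1:])):
            raise ValueError("retention times must be strictly increasing (degenerate ladder)")
        object.__setattr__(self, "carbon_numbers", c)
        object.__setattr__(self, "retention_times", rt)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AlkaneLadder":
        df = df.sort_values("carbon_n")
        return cls(df["carbon_n"].to_numpy(), df["rt_min"].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"carbon_n": self.carbon_numbers, "rt_min": self.retention_times}
        )

    @property
    def ri_range(self) -> tuple:
        return 100.0 * self.carbon_numbers[0], 100.0 * self.carbon_numbers[-1]


@dataclass(frozen=True)
class RiValue:
    """A retention index with provenance and extrapolation status."""

    value: float
    source: str = "gc_peak"  # or "sniff_onset"
    extrapolated: bool = False


def retention_indices(rts, ladder: AlkaneLadder):
    """Vectorised linear (temperature-programmed) RI interpolation.

    Returns ``(values, extrapolated)`` arrays.  Inside the ladder the value is
    ``100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n) * (n_{+1} - n))`` for the
    bracketing alkanes; outside, the nearest segment is extended.
    """
    rts = np.asarray(rts, dtype=float)
    c = np.asarray(ladder.carbon_numbers, dtype=float)
    rt = np.asarray(ladder.retention_times, dtype=float)
    # segment index for each rt: clip so edge points reuse the nearest segment
    seg = np.searchsorted(rt, rts, side="right") - 1
    seg = np.clip(seg, 0, len(rt) - 2)
    frac = (rts - rt[seg]) / (rt[seg + 1] - rt[seg])
    values = 100.0 * (c[seg] + frac * (c[seg + 1] - c[seg]))
    extrapolated = (rts < rt[0]) | (rts > rt[-1])
    return values, extrapolated


def retention_index(rt: float, ladder: AlkaneLadder, source: str = "gc_peak") -> RiValue:
    """RI of a single retention time (minutes) against the ladder."""
    values, extrapolated = retention_indices([rt], ladder)
    return RiValue(float(values[0]), source=source, extrapolated=bool(extrapolated[0]))


def match_region_to_peak(region_ri, peak_ris, tolerance: float = 10.0):
    """Pair a sniff region with the nearest chromatographic peak by RI.

    Parameters
    ----------
    region_ri : float or RiValue
        Consensus RI of the odorant region (from sniff onsets).
    peak_ris : mapping or sequence of (peak_id, ri)
        Candidate peak RIs.
    tolerance : float
        Maximal |RI difference| for a match.  Regions without a qualifying
        peak return ``None`` -- the odour-without-visible-peak case, reported
        as "ND" for such compounds.

    Ties on the RI difference are broken toward the smaller peak RI, with a
    warning (the choice is then ambiguous).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if isinstance(region_ri, RiValue):
        region_ri = region_ri.value
    items = list(peak_ris.items()) if hasattr(peak_ris, "items") else list(peak_ris)
    candidates = []  # (diff, ri, peak_id)
    for peak_id, ri in items:
        ri = ri.value if isinstance(ri, RiValue) else float(ri)
        diff = abs(ri - region_ri)
        if diff <= tolerance:
            candidates.append((diff, ri, peak_id))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (t[0], t[1]))
    best = candidates[0]
    tied = [pid for d, _, pid in candidates if d == best[0]]
    if len(tied) > 1:
        warnings.warn(
            f"region RI {region_ri:.1f} equidistant from peaks {tied}; "
            f"selecting lower-RI peak {best[2]}",
            stacklevel=2,
        )
    return best[2]
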