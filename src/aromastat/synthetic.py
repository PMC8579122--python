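"""Synthetic GC-O panels and descriptive-sensory score tables with known truth.

The generator emulates the study design that the scoring pipeline was built
for: a 9-judge GC-olfactometry panel sniffing four samples (week 0 and week
52 of storage in aluminium and plastic pouches), and a 10-assessor
descriptive panel scoring 17 attributes on a 0-15 line scale, four replicate
sessions, over up to seven storage times per packaging.  Every stochastic
quantity is driven by per-compound detection probabilities, intensity
distributions on the discrete 1-5 scale (0 is reserved for non-detection,
which simply produces no event), and additive assessor / replicate / sample
effects, so downstream estimates can be checked against the planted truth.

One global seed feeds independent substreams (events, peaks, scores,
ladder), so a stage can be regenerated without re-running the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import SAMPLES, load_gco_table
from .ri import AlkaneLadder

__all__ = [
    "CompoundTruth",
    "PanelDesign",
    "SensoryDesign",
    "ATTRIBUTES",
    "generate_sniff_events",
    "generate_peak_table",
    "generate_sensory_scores",
    "generate_alkane_ladder",
    "truth_from_reference_table",
    "demo_sensory_design",
]

#: The 17 descriptive attributes: orthonasal aroma (A), basic taste (BT), flavour (F).
ATTRIBUTES = (
    "A_Overall Intensity",
    "A_Sulphury",
    "A_Green",
    "A_White Asparagus",
    "A_Boiled Potato",
    "A_Hay",
    "A_Meat Broth",
    "BT_Sweet",
    "BT_Bitter",
    "BT_Umami",
    "F_Watery",
    "F_Corn",
    "F_White Asparagus",
    "F_Hay",
    "F_Oxidised",
    "F_Boiled Potato",
    "F_Meat Broth",
)

#: Storage times (weeks); the aluminium series has no 8-week point, mirroring
#: the excluded-outlier sample of the study design being emulated.
DEFAULT_SENSORY_SAMPLES = tuple(
    [("aluminium", w) for w in (0, 1, 4, 16, 32, 52)]
    + [("plastic", w) for w in (0, 1, 4, 8, 16, 32, 52)]
)

_STREAMS = {"events": 1, "peaks": 2, "scores": 3, "ladder": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, reproducible substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[stream],)))


def _as_sample_map(value, sample_ids, name):
    if isinstance(value, Mapping):
        missing = [s for s in sample_ids if s not in value]
        if missing:
            raise ValueError(f"{name} missing samples {missing}")
        return {s: float(value[s]) for s in sample_ids}
    return {s: float(value) for s in sample_ids}


@dataclass
class CompoundTruth:
    """Ground truth for one odorant: where it elutes and how it is perceived.

    ``detect_prob`` and ``intensity_mean`` may be a single number or a
    per-sample mapping; probabilities live in [0, 1] and mean intensities on
    the 0-5 odour scale.
    """

    compound_id: str
    true_ri: float
    detect_prob: Mapping[str, float] | float
    intensity_mean: Mapping[str, float] | float = 3.0
    intensity_sd: float = 0.8
    peak_area_mean: Mapping[str, float] | float = 1.0
    is_internal_standard: bool = False

    def validate(self, sample_ids: Sequence[str]):
        p = _as_sample_map(self.detect_prob, sample_ids, "detect_prob")
        m = _as_sample_map(self.intensity_mean, sample_ids, "intensity_mean")
        a = _as_sample_map(self.peak_area_mean, sample_ids, "peak_area_mean")
        if any(not 0 <= v <= 1 for v in p.values()):
            raise ValueError(f"{self.compound_id}: detect_prob outside [0, 1]")
        if any(not 0 <= v <= 5 for v in m.values()):
            raise ValueError(f"{self.compound_id}: intensity_mean outside [0, 5]")
        if self.intensity_sd < 0:
            raise ValueError(f"{self.compound_id}: negative intensity_sd")
        if any(v < 0 for v in a.values()):
            raise ValueError(f"{self.compound_id}: negative peak_area_mean")
        return p, m, a


@dataclass
class PanelDesign:
    """GC-O panel layout: 9 judges, four samples, RI onset jitter."""

    n_panellists: int = 9
    sample_ids: Sequence[str] = SAMPLES
    ri_jitter_sd: float = 3.0
    seed: int = 0

    def validate(self):
        if self.n_panellists < 1:
            raise ValueError("n_panellists must be >= 1")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.ri_jitter_sd < 0:
            raise ValueError("ri_jitter_sd must be >= 0")


@dataclass
class SensoryDesign:
    """Descriptive-panel layout and variance components (0-15 line scale).

    ``sample_effect`` maps attribute -> {sample label -> shift} (absent keys
    mean zero).  Scores are ``clip(grand_mean + sample + assessor + replicate
    + assessor x sample + noise, 0, 15)`` in a balanced complete design.
    Defaults: 10 assessors, 4 replicate sessions, 17 attributes, 13
    packaging x storage-time samples; assessor sd 1.0 (panellists are a major
    variance source on line scales), replicate sd 0.3, interaction sd 0.5,
    residual sd 1.0 scale units.
    """

    n_assessors: int = 10
    samples: Sequence[tuple] = DEFAULT_SENSORY_SAMPLES
    n_replicates: int = 4
    attributes: Sequence[str] = ATTRIBUTES
    grand_mean: float = 6.0
    sample_effect: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    assessor_sd: float = 1.0
    replicate_sd: float = 0.3
    interaction_sd: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self):
        if min(self.n_assessors, self.n_replicates) < 1 or not self.samples:
            raise ValueError("counts must be positive and samples non-empty")
        for name in ("assessor_sd", "replicate_sd", "interaction_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @staticmethod
    def sample_label(packaging: str, weeks: int) -> str:
        return f"{packaging[0].upper()}{int(weeks)}"


def generate_sniff_events(
    truth: Sequence[CompoundTruth], design: PanelDesign
) -> pd.DataFrame:
    """Draw a sniff-event log: one row per detected odour.

    For each panellist x sample x compound a detection is drawn with the
    compound's per-sample probability.  Detected events get an onset RI of
    ``true_ri + N(0, ri_jitter_sd)`` and an intensity drawn from a rounded
    Normal truncated to the discrete {1..5} scale; non-detections produce no
    row.  The log is sorted by sample then onset.
    """
    design.validate()
    if not truth:
        warnings.warn("empty compound truth; returning empty event log", stacklevel=2)
        return pd.DataFrame(columns=["panellist", "sample", "onset_ri", "descriptor", "intensity"])
    rng = _rng(design.seed, "events")
    rows = []
    panellists = [f"J{i + 1:02d}" for i in range(design.n_panellists)]
    for compound in truth:
        p, m, _ = compound.validate(design.sample_ids)
        if compound.is_internal_standard:
            continue  # spiked reference, not an odour target of the panel
        for sample in design.sample_ids:
            detected = rng.random(design.n_panellists) < p[sample]
            onsets = compound.true_ri + rng.normal(0.0, design.ri_jitter_sd, design.n_panellists)
            raw = rng.normal(m[sample], compound.intensity_sd, design.n_panellists)
            intensities = np.clip(np.rint(raw), 1, 5).astype(int)
            for j, hit in enumerate(detected):
                if hit:
                    rows.append(
                        {
                            "panellist": panellists[j],
                            "sample": sample,
                            "onset_ri": float(onsets[j]),
                            "descriptor": compound.compound_id,
                            "intensity": int(intensities[j]),
                        }
                    )
    events = pd.DataFrame(rows, columns=["panellist", "sample", "onset_ri", "descriptor", "intensity"])
    return events.sort_values(["sample", "onset_ri"], kind="mergesort").reset_index(drop=True)


def generate_peak_table(
    truth: Sequence[CompoundTruth],
    design: PanelDesign,
    ladder: AlkaneLadder,
    n_extraction_replicates: int = 3,
    area_cv: float = 0.15,
    rt_jitter_sd: float = 0.02,
) -> pd.DataFrame:
    """Integrated chromatographic peak table for the same scenario.

    Retention times are placed so the ladder maps them back to the compound's
    true RI (plus small run-to-run jitter, minutes); areas are lognormal
    around the per-sample mean with coefficient of variation ``area_cv``
    across extraction replicates.  Exactly one compound must be flagged as
    the internal standard; it appears in every sample x replicate run.
    """
    design.validate()
    n_is = sum(c.is_internal_standard for c in truth)
    if n_is != 1:
        raise ValueError(f"scenario must flag exactly one internal standard, got {n_is}")
    rng = _rng(design.seed, "peaks")
    c = np.asarray(ladder.carbon_numbers, dtype=float)
    rt = np.asarray(ladder.retention_times, dtype=float)
    sigma = np.sqrt(np.log(1.0 + area_cv**2))
    rows = []
    for compound in truth:
        _, _, areas = compound.validate(design.sample_ids)
        # invert the ladder: rt whose interpolated RI equals true_ri
        base_rt = float(np.interp(compound.true_ri / 100.0, c, rt))
        for sample in design.sample_ids:
            for rep in range(1, n_extraction_replicates + 1):
                mean_area = areas[sample]
                area = (
                    float(mean_area * rng.lognormal(-0.5 * sigma**2, sigma))
                    if mean_area > 0
                    else 0.0
                )
                rows.append(
                    {
                        "peak_id": compound.compound_id,
                        "sample": sample,
                        "replicate": rep,
                        "rt_min": base_rt + float(rng.normal(0.0, rt_jitter_sd)),
                        "area": area,
                        "is_internal_standard": bool(compound.is_internal_standard),
                    }
                )
    return pd.DataFrame(rows)


def generate_sensory_scores(design: SensoryDesign) -> pd.DataFrame:
    """Balanced complete descriptive-sensory score table (long format).

    Effects are drawn once per attribute: assessor and replicate main
    effects, an assessor x sample interaction, and i.i.d. residual noise;
    scores are clipped (not resampled) at the 0-15 scale bounds, mirroring a
    bounded line scale.  Reproducible for a fixed seed.
    """
    design.validate()
    rng = _rng(design.seed, "scores")
    assessors = [f"A{i + 1:02d}" for i in range(design.n_assessors)]
    labels = [design.sample_label(p, w) for p, w in design.samples]
    rows = []
    for attribute in design.attributes:
        eff = design.sample_effect.get(attribute, {})
        a_eff = rng.normal(0.0, design.assessor_sd, design.n_assessors)
        r_eff = rng.normal(0.0, design.replicate_sd, design.n_replicates)
        i_eff = rng.normal(0.0, design.interaction_sd, (design.n_assessors, len(labels)))
        for si, ((packaging, weeks), label) in enumerate(zip(design.samples, labels)):
            shift = float(eff.get(label, 0.0))
            for ai, assessor in enumerate(assessors):
                noise = rng.normal(0.0, design.noise_sd, design.n_replicates)
                for ri in range(design.n_replicates):
                    value = (
                        design.grand_mean
                        + shift
                        + a_eff[ai]
                        + r_eff[ri]
                        + i_eff[ai, si]
                        + noise[ri]
                    )
                    rows.append(
                        {
                            "assessor": assessor,
                            "sample": label,
                            "packaging": packaging,
                            "weeks": int(weeks),
                            "replicate": ri + 1,
                            "attribute": attribute,
                            "value": float(np.clip(value, 0.0, 15.0)),
                        }
                    )
    return pd.DataFrame(rows)


def generate_alkane_ladder(
    c_min: int = 6, c_max: int = 22, rt_start: float = 2.0, rt_step: float = 1.5
) -> AlkaneLadder:
    """Evenly spaced n-alkane ladder C_{c_min}..C_{c_max} (strictly increasing)."""
    if c_min >= c_max:
        raise ValueError("c_min must be < c_max")
    if rt_step <= 0:
        raise ValueError("rt_step must be positive")
    carbons = list(range(c_min, c_max + 1))
    rts = [rt_start + rt_step * (n - c_min) for n in carbons]
    return AlkaneLadder(carbons, rts)


# ---------------------------------------------------------------------------
# scenario helpers tied to the bundled reference tables


def truth_from_reference_table(table: pd.DataFrame | None = None) -> list:
    """Build a compound-truth scenario from the bundled GC-O region table.

    Detection probabilities are the printed NIF values / 100; the mean raw
    intensity of detectors is approximated as ``5 * IS / NIF`` (the
    all-panellist intensity score divided by the detection fraction), clipped
    to the 1-5 scale.  Peak areas use the printed relative means.  The
    internal standard (4-methyl-1-pentanol) is appended as a non-odour peak.
    """
    if table is None:
        table = load_gco_table()
    truth = []
    for _, row in table.iterrows():
        p, m, a = {}, {}, {}
        for s in SAMPLES:
            nif = float(row[f"nif_{s}"])
            is_ = float(row[f"is_{s}"])
            p[s] = nif / 100.0
            m[s] = float(np.clip(5.0 * is_ / nif, 1.0, 5.0)) if nif > 0 else 0.0
            rpa = row.get(f"rpa_{s}", np.nan)
            a[s] = float(rpa) if np.isfinite(rpa) else 0.0
        truth.append(
            CompoundTruth(
                compound_id=str(row["compound"]),
                true_ri=float(row["ri_snif"]),
                detect_prob=p,
                intensity_mean=m,
                intensity_sd=0.8,
                peak_area_mean=a,
            )
        )
    truth.append(
        CompoundTruth(
            compound_id="4-Methyl-1-pentanol (IS)",
            true_ri=1315.0,
            detect_prob=0.0,
            intensity_mean=0.0,
            intensity_sd=0.0,
            peak_area_mean=1.0,
            is_internal_standard=True,
        )
    )
    return truth


#: Attributes that stay flat in the demo scenario (the remaining 14 drift).
STABLE_ATTRIBUTES = ("BT_Bitter", "F_Corn", "F_Boiled Potato")


def demo_sensory_design(seed: int = 0, effect_size: float = 3.0) -> SensoryDesign:
    """Default sensory scenario: storage trends planted in 14 of 17 attributes.

    Each drifting attribute moves linearly with storage time by
    ``effect_size`` scale units over the full 52 weeks (alternating sign so
    some attributes rise while others fade); the three stable attributes get
    no sample effect.
    """
    design = SensoryDesign(seed=seed)
    effects: dict = {}
    drift_sign = 1.0
    for attribute in design.attributes:
        if attribute in STABLE_ATTRIBUTES:
            continue
        eff = {}
        for packaging, weeks in design.samples:
            label = design.sample_label(packaging, weeks)
            eff[label] = drift_sign * effect_size * (weeks / 52.0 - 0.5)
        effects[attribute] = eff
        drift_sign = -drift_sign
    design.sample_effect = effects
    return design
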