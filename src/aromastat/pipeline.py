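"""End-to-end orchestration: simulate -> calibrate -> score -> ANOVA -> PCA.

A single :class:`RunConfig` (loadable from YAML) drives the whole pipeline
and a :class:`RunManifest` records everything needed to re-derive the
outputs: the config echo, software version, seeds, per-stage row counts and
warnings.  With a fixed seed the run is byte-identical across invocations
(the manifest deliberately carries no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, gco, io, pca, sensory, synthetic
from .ri import match_region_to_peak, retention_indices

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_inputs"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All thresholds and paths for one pipeline run.

    Thresholds default to the study's values: 9-judge panel, odour-active at
    more than three detections, shortlist at OI > 65%, alpha 0.05, 5 RI units
    clustering and 10 RI units region-to-peak matching tolerance.  Either a
    synthetic scenario (``simulate = True``) or explicit input CSV paths must
    be provided.
    """

    outdir: str = "aromastat_run"
    seed: int = 0
    simulate: bool = True
    events: str | None = None
    peaks: str | None = None
    ladder: str | None = None
    scores: str | None = None
    panel_size: int = 9
    cluster_tolerance: float = 5.0
    match_tolerance: float = 10.0
    min_detections: int = 4
    oi_threshold: float = 65.0
    alpha: float = 0.05
    is_mode: str = "all_panellists"
    splits: tuple = ("aluminium", "plastic", "combined")
    max_components: int = 6
    exclude_samples: tuple = ()
    sensory_effect_size: float = 3.0

    def __post_init__(self):
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.cluster_tolerance <= 0 or self.match_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.simulate:
            for name in ("events", "peaks", "ladder", "scores"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"input file for {name!r} missing: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("splits", "exclude_samples"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunManifest:
    """Reproducibility record: rerunning from the manifest recreates the run."""

    config: dict
    version: str
    stages: list = field(default_factory=list)

    def add_stage(self, name: str, rows_in: int, rows_out: int, outputs, warnings_seen):
        self.stages.append(
            {
                "name": name,
                "rows_in": int(rows_in),
                "rows_out": int(rows_out),
                "outputs": [str(p) for p in outputs],
                "warnings": list(warnings_seen),
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "version": self.version, "stages": self.stages},
            indent=2,
            sort_keys=True,
        )

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json() + "\n")
        return path


def _catch(stage):
    class _Ctx:
        def __init__(self):
            self.records = None

        def __enter__(self):
            self._cm = warnings.catch_warnings(record=True)
            self.records = self._cm.__enter__()
            warnings.simplefilter("always")
            return self

        def __exit__(self, exc_type, exc, tb):
            self._cm.__exit__(None, None, None)
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(stage, exc) from exc
            return False

        @property
        def messages(self):
            return [str(w.message) for w in self.records]

    return _Ctx()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order, writing CSV outputs and a JSON manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__)
    # make tuples JSON-friendly
    for key in ("splits", "exclude_samples"):
        manifest.config[key] = list(manifest.config[key])

    # -- stage: simulate -----------------------------------------------------
    with _catch("simulate") as ctx:
        if config.simulate:
            truth = synthetic.truth_from_reference_table()
            panel = synthetic.PanelDesign(n_panellists=config.panel_size, seed=config.seed)
            ladder = synthetic.generate_alkane_ladder()
            events = synthetic.generate_sniff_events(truth, panel)
            peaks = synthetic.generate_peak_table(truth, panel, ladder)
            # odour-without-visible-peak case: drop zero-area peaks
            peaks = peaks[
                (peaks["area"] > 0) | peaks["is_internal_standard"]
            ].reset_index(drop=True)
            sdesign = synthetic.demo_sensory_design(
                seed=config.seed, effect_size=config.sensory_effect_size
            )
            scores = synthetic.generate_sensory_scores(sdesign)
            paths = [
                io.write_events(events, outdir / "events.csv"),
                io.write_peaks(peaks, outdir / "peaks.csv"),
                io.write_ladder(ladder, outdir / "ladder.csv"),
                io.write_scores(scores, outdir / "scores.csv"),
            ]
            manifest.add_stage("simulate", 0, len(events) + len(peaks) + len(scores), paths, ctx.messages)
        else:
            events = io.read_events(config.events)
            peaks = io.read_peaks(config.peaks)
            ladder = io.read_ladder(config.ladder)
            scores = io.read_scores(config.scores)
            manifest.add_stage(
                "load", 0, len(events) + len(peaks) + len(scores), [], ctx.messages
            )

    if config.exclude_samples:
        scores = scores[~scores["sample"].isin(config.exclude_samples)].reset_index(drop=True)

    # -- stage: calibrate-ri -------------------------------------------------
    with _catch("calibrate-ri") as ctx:
        values, extrapolated = retention_indices(peaks["rt_min"].to_numpy(), ladder)
        peaks = peaks.assign(ri=values, ri_extrapolated=extrapolated)
        p = outdir / "peaks_ri.csv"
        peaks.to_csv(p, index=False)
        manifest.add_stage("calibrate-ri", len(peaks), len(peaks), [p], ctx.messages)

    # -- stage: score-gco ----------------------------------------------------
    with _catch("score-gco") as ctx:
        sample_ids = sorted(events["sample"].unique())
        centred = gco.block_centre(events)
        clustered = gco.cluster_events(centred, tolerance=config.cluster_tolerance)
        regions = gco.score_regions(
            clustered, panel_size=config.panel_size, sample_ids=sample_ids, mode=config.is_mode
        )
        active = gco.filter_odour_active(regions, min_detections=config.min_detections)
        # pair regions with MS peaks via RI
        peak_ri = peaks.groupby("peak_id")["ri"].mean()
        rpa = gco.relative_peak_areas(peaks)
        matched = []
        for _, region in active.iterrows():
            pid = match_region_to_peak(
                region["consensus_ri"], peak_ri, tolerance=config.match_tolerance
            )
            matched.append(pid if pid is not None else "ND")
        active = active.assign(peak_id=matched)
        wide_rpa = (
            rpa.pivot(index="peak_id", columns="sample", values="rpa_mean")
            if len(rpa)
            else pd.DataFrame()
        )
        for s in sample_ids:
            col = []
            for pid in active["peak_id"]:
                if pid != "ND" and s in getattr(wide_rpa, "columns", []):
                    v = wide_rpa.at[pid, s] if pid in wide_rpa.index else np.nan
                else:
                    v = np.nan
                col.append(v)
            active[f"rpa_{s}"] = col
        shortlist = gco.select_important(active, oi_threshold=config.oi_threshold)
        p1 = outdir / "gco_regions.csv"
        p2 = outdir / "gco_important.csv"
        active.to_csv(p1, index=False)
        shortlist.to_csv(p2, index=False)
        manifest.add_stage("score-gco", len(events), len(active), [p1, p2], ctx.messages)

    # -- stage: sensory-anova ------------------------------------------------
    with _catch("sensory-anova") as ctx:
        splits = {
            k: v for k, v in sensory.split_scores(scores).items() if k in config.splits
        }
        significant = sensory.attribute_screen(splits, alpha=config.alpha)
        outputs = []
        for split, table in splits.items():
            anova_rows, summary_frames = [], []
            for attribute in pd.unique(table["attribute"]):
                res = sensory.mixed_anova(table, attribute, alpha=config.alpha)
                anova_rows.append(
                    {
                        "attribute": attribute,
                        "f_sample": res.f_sample,
                        "p_sample": res.p_sample,
                        "df_num": res.df_num,
                        "df_den": res.df_den,
                        "ms_error": res.ms_error,
                        "significant": res.significant,
                    }
                )
                summ = sensory.summarize_attribute(table, attribute)
                letters = sensory.tukey_letters(res, table, alpha=config.alpha)
                summ = summ.join(letters["letters"])
                summ.insert(0, "attribute", attribute)
                summary_frames.append(summ.reset_index())
            pa = outdir / f"anova_{split}.csv"
            ps = outdir / f"summary_{split}.csv"
            pd.DataFrame(anova_rows).to_csv(pa, index=False)
            pd.concat(summary_frames, ignore_index=True).to_csv(ps, index=False)
            outputs.extend([pa, ps])
        manifest.add_stage("sensory-anova", len(scores), sum(map(len, splits.values())), outputs, ctx.messages)

    # -- stage: pca ----------------------------------------------------------
    with _catch("pca") as ctx:
        outputs = []
        n_rows_out = 0
        for split, table in splits.items():
            attrs = significant.get(split, [])
            if len(attrs) < 2:
                warnings.warn(f"split {split!r}: fewer than 2 significant attributes; PCA skipped")
                continue
            mat = pca.per_repetition_means(table, attrs)
            scaled, means, sds = pca.autoscale(mat)
            model = pca.fit_pca(scaled)
            max_k = min(config.max_components, min(mat.shape) - 1)
            errors, selected = pca.rmsecv(mat, max_k)
            var = pd.DataFrame(
                {
                    "component": [f"PC{a + 1}" for a in range(model.n_components)],
                    "explained_pct": model.explained,
                    "cumulative_pct": model.cumulative,
                }
            )
            var["rmsecv"] = [
                errors.get(a + 1, np.nan) for a in range(model.n_components)
            ]
            var["selected_k"] = selected
            bscores, bload = pca.biplot_coords(model, (1, 2))
            pv = outdir / f"pca_variance_{split}.csv"
            psc = outdir / f"pca_scores_{split}.csv"
            pl = outdir / f"pca_loadings_{split}.csv"
            var.to_csv(pv, index=False)
            bscores.to_csv(psc)
            bload.to_csv(pl)
            outputs.extend([pv, psc, pl])
            n_rows_out += len(mat)
        manifest.add_stage("pca", len(scores), n_rows_out, outputs, ctx.messages)

    manifest.write(outdir / "manifest.json")
    return manifest


def validate_inputs(
    events=None, peaks=None, ladder=None, scores=None
) -> pd.DataFrame:
    """Schema, range and balance checks; returns a report of violations.

    Report columns: ``file, row, check, detail``.  An empty report means the
    inputs are clean.  This is report-only: nothing is rejected here.
    """
    problems = []

    def add(file, row, check, detail):
        problems.append({"file": file, "row": row, "check": check, "detail": detail})

    if events is not None:
        try:
            ev = io.read_events(events)
        except ValueError as e:
            add("events", None, "schema", str(e))
        else:
            bad = ev.index[~ev["intensity"].isin([1, 2, 3, 4, 5])]
            for i in bad:
                add("events", int(i), "intensity-range",
                    f"intensity {ev.at[i, 'intensity']} outside 1-5")
    if ladder is not None:
        try:
            io.read_ladder(ladder)
        except ValueError as e:
            add("ladder", None, "monotonicity", str(e))
    if peaks is not None:
        try:
            pk = io.read_peaks(peaks)
        except ValueError as e:
            add("peaks", None, "schema", str(e))
        else:
            for i in pk.index[pk["area"] < 0]:
                add("peaks", int(i), "area-range", "negative peak area")
            n_is = pk[pk["is_internal_standard"].astype(bool)].groupby(["sample", "replicate"]).size()
            for run in pk.groupby(["sample", "replicate"]).size().index:
                if n_is.get(run, 0) != 1:
                    add("peaks", None, "internal-standard",
                        f"run {run} has {n_is.get(run, 0)} internal-standard peaks")
    if scores is not None:
        try:
            sc = io.read_scores(scores)
        except ValueError as e:
            add("scores", None, "schema", str(e))
        else:
            lo, hi = sensory.SCALE_RANGE
            for i in sc.index[(sc["value"] < lo) | (sc["value"] > hi)]:
                add("scores", int(i), "value-range", f"value {sc.at[i, 'value']} outside 0-15")
            for attribute in pd.unique(sc["attribute"]):
                sub = sc[sc["attribute"] == attribute]
                try:
                    sensory._check_balance(sub, attribute)
                except ValueError as e:
                    add("scores", None, "balance", str(e))
    return pd.DataFrame(problems, columns=["file", "row", "check", "detail"])
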