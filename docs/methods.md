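# Methods

## GC-olfactometry scoring model

The unit of observation is a *sniff event*: one panellist perceiving one
odour in one sample's GC run, recorded with onset position (retention index),
a free-text descriptor and an intensity on a discrete 6-point scale (0 = not
detected, 1 = just noticeable … 5 = very intense). Intensity 0 is synonymous
with "no event": event logs contain only detections, and the generator never
emits zero-intensity rows.

**Block centring.** Assessors use the intensity scale with different personal
offsets. The correction subtracts each assessor's mean intensity over *all*
their events across the whole evaluation set (all samples pooled — the
assessor's "block") and adds back the grand mean. This conserves the grand
mean exactly and leaves a homogeneous panel unchanged; centred values may
leave the 0–5 range, which is expected and handled downstream.

**Region formation.** Events are pooled across panellists and samples and
clustered on onset RI by single linkage: the sorted onsets are chained until
a gap exceeds the tolerance (default 5 RI units, configurable). Dense chains
can drift, so clusters whose span exceeds 3× the tolerance are split
recursively at their largest internal gap. Within a region, each panellist
contributes at most one event per sample (highest intensity kept; earliest
onset on ties), and the consensus RI is the median onset of the retained
events. The defaults assume the panel was instructed to mark discrete odour
starts, so genuine regions are well separated relative to onset jitter.

**Scores.** Per region and sample:

* NIF = 100 · detections / panel size (%), reported rounded to integers
  (half away from zero, as printed tables round). With 9 judges the
  attainable values are {0, 11, 22, 33, 44, 56, 67, 78, 89, 100}.
* IS = 100 · mean centred intensity / 5 (%). Default mode counts
  non-detectors as zero intensity (the scale defines 0 as "not detected");
  a `detectors_only` mode averages over detectors only, since either
  convention is defensible. A negative centred mean (possible after block
  centring) is floored at zero with a warning, because the geometric mean
  below is undefined for negatives.
* OI = √(NIF · IS) (%), rounded. OI is computed from the *rounded* NIF and
  IS so that recomputation from a printed table is self-consistent; all
  printed-table comparisons use a ±1 tolerance because the original rounding
  provenance (raw vs pre-rounded inputs) is unknowable from a printed table.

**Selection rules.** A region is odour-active when strictly more than three
panellists detect it in at least one sample (≥4 of 9); kept regions report
all samples, including sub-threshold ones. The high-impact shortlist keeps
regions with OI strictly above the threshold (default 65 %) in at least one
sample and ranks them by descending mean OI across samples.

*Data note.* Applying the strict shortlist rule to the bundled reference
table selects **eleven** compounds, while the bundled ranked shortlist lists
ten: 2-butanone reaches OI = round(√(89·55)) = 70 in sample A0 yet is absent
from the printed shortlist (it would rank last by mean OI, 42.75). The
package implements the stated rule and reports the honest count rather than
adding an unstated filter; the test asserting ten-compound membership is
left failing deliberately as a record of the discrepancy.

**Retention indices.** Van den Dool & Kratz linear interpolation against a
C6–C22 alkane ladder, appropriate for temperature-programmed GC (the
logarithmic Kovats form applies to isothermal runs). Alkane anchors map to
exactly 100·n. Times outside the ladder are extrapolated from the nearest
segment and flagged rather than rejected, because sniff onsets can precede
the first alkane. Region-to-peak matching takes the nearest peak RI within a
tolerance (default 10 RI units, chosen because observed sniff-vs-GC RI
discrepancies are of order ≤8 units); exact ties go to the lower RI with a
warning, and no qualifying peak yields "ND" (odour perceived without a
visible peak).

**Relative peak areas** are total-ion areas divided by the
internal-standard area of the same sample × extraction-replicate run
(exactly one internal-standard peak per run is enforced), summarised as
mean ± sd over replicates (ddof = 1).

## Sensory statistics

Scores are 0–15 line-scale values in a balanced complete design
(assessor × sample × replicate session, per attribute). Three splits are
analysed: plastic-pouch samples, aluminium-pouch samples, and all samples
combined.

**Mixed ANOVA.** Factors: sample (fixed), assessor (random), replicate
(random), plus the sample × assessor interaction; the replicate × sample
interaction is pooled into the residual. Sums of squares come from a
sequential (type I) fit of
`value ~ sample + assessor + replicate + sample:assessor`, which is
orthogonal — hence order-free — on a balanced design. By the
expected-mean-squares rules for this mixed model the correct denominator for
the fixed sample effect is the interaction mean square:
F = MS_sample / MS_sample×assessor on (a−1, (a−1)(b−1)) df. Degenerate
inputs (zero interaction MS, e.g. constant data) are flagged as "no
variation" instead of forming 0/0. The SS partition identity is asserted to
1e-8 relative in tests. No multiple-testing correction is applied across
attributes; each attribute is tested at α = 0.05, matching per-attribute
screening practice.

**Tukey HSD and letters.** All pairwise sample-mean differences are compared
with q(α, k, df)·√(MS_error/n) using the same interaction error term and df
as the F test, n being observations per sample. The compact letter display
uses insert-and-absorb: start with one group holding all samples, split
every group containing a significantly different pair, absorb subset groups.
Two samples then share a letter iff they were never declared different, a
property tested against the raw pairwise matrix on randomised instances.
Letters are produced even when the omnibus test is not significant.

**Attribute summaries.** The reported sample mean is the mean of the
replicate-session panel means (mean over assessors per replicate), and the
sd is taken over exactly those replicate means (n = 4 by default). Missing
cells are rejected with an explicit list; a config switch in the pipeline
excludes listed samples to mirror panel-outlier removal (the emulated design
drops the 8-week aluminium sample).

## PCA

Input: the matrix of per-repetition panel means (rows = sample × replicate
session, columns = the attributes found significant in the split). Columns
are autoscaled to mean 0, sd 1 (ddof = 1); a zero-variance attribute is
rejected by name. The model is a singular-value decomposition; the explained
variance share of component a is s_a²/Σs² · 100, and signs are fixed by
making the largest-magnitude loading of each component positive, so output
is deterministic and row-order invariant.

**RMSECV.** Leave-one-row-out: for each held-out row the scaling and PCA are
refit on the remaining rows. Each entry of the held-out row is then
predicted from the *other* entries of that row, by least-squares regression
of the reduced row onto the rank-k loadings with that entry's row removed.
Predicting an entry from a projection that includes the entry itself makes
the error non-increasing in k and hides overfitting, so a naive row
projection always selects the maximal k; the element-wise scheme is the
standard remedy and produces the usual U-shaped curve. RMSECV(0) is the RMS
of the scaled held-out rows (prediction = training column mean). The
selected k is the global minimum with ties (1e-9 relative) resolved toward
smaller k. With the default scenario sizes (≤ 52 rows, ≤ 17 attributes,
k ≤ 6) the full cross-validation runs in well under a second.

**Biplot coordinates** are the component scores plus correlation loadings —
the Pearson correlation between each autoscaled attribute and each score
vector, loading·s_a/√(n−1) — bounded in [−1, 1]. Only coordinates are
exported; rendering is out of scope.

## Synthetic data generator

The generator emulates the study design the pipeline targets: 9 GC-O judges
× 4 samples, with per-compound, per-sample detection probabilities and
intensity distributions, and a 10-assessor descriptive panel, 4 replicate
sessions, 17 attributes, 6 aluminium + 7 plastic storage-time samples on a
0–15 scale. Defaults for the variance components are typical line-scale
magnitudes: assessor sd 1.0 (assessors are a dominant variance source),
replicate sd 0.3, assessor × sample interaction sd 0.5, residual sd 1.0
scale units, grand mean 6.0. The demo scenario plants linear storage trends
of 3 scale units (over the full 0–52-week range, alternating sign across
attributes) in 14 of the 17 attributes, leaving bitter taste and the corn
and boiled-potato flavours flat — the pattern of stable attributes in the
emulated study.

Detections are Bernoulli draws per panellist × sample × compound; detected
events get onset RI = true RI + N(0, jitter sd, default 3 RI units) and an
intensity from a Normal (per-sample mean, sd 0.8) rounded and clipped to the
discrete 1–5 scale. Sensory scores are the additive effect sum clipped (not
resampled) at the 0–15 bounds, mirroring a bounded line scale. One global
seed feeds fixed substreams (events, peaks, scores, ladder), so stages can
be regenerated independently and a fixed seed gives byte-identical CSV
output. The GC-O demo scenario derives compound truths from the bundled
reference table (detection probability = NIF/100; detector mean intensity
approximated by 5·IS/NIF, clipped to [1, 5]) plus a spiked internal-standard
peak.

What the generator does *not* emulate: raw chromatograms, mass spectra,
co-elution, panellist fatigue or carry-over, scale-use drift over sessions,
non-Gaussian score distributions, or correlated attributes beyond the
planted means. Passing tests therefore demonstrate correctness of the
scoring and inference arithmetic under idealised panel behaviour, not
robustness to real-panel pathologies.

## Pipeline and reproducibility

`run-all` executes simulate → RI calibration → GC-O scoring → per-split
ANOVA/Tukey → PCA, each stage consuming the previous stage's CSVs; a failure
aborts with the stage name. The JSON manifest records the config echo,
package version, per-stage row counts, output files and captured warnings —
and deliberately no timestamps, so identical config + seed reproduces every
output byte for byte. Validation (`validate`) reports schema, range and
balance violations with row numbers without rejecting anything.

## Known limitations

* The published sensory mean tables and PCA variance percentages of the
  emulated study are not reproducible here: they require the original raw
  panel data and unstated settings of the original SPSS/SOLO analyses
  (model interactions, CV scheme). The statistical arm is instead validated
  against brute-force oracles, simulation calibration (type-I error,
  power), and planted-truth recovery.
* Descriptor text is carried as annotations only; no odour-vocabulary
  ontology or spectral identification is attempted (identification evidence
  codes m/r/a/s are pass-through metadata).
* Single-column RI only; no second-column confirmation of co-elutions.
* The odour-active membership of a *specific* sample (counts of compounds
  detected per sample) depends on a per-sample threshold convention that the
  emulated study leaves unstated; the package reports per-sample detection
  counts and leaves that interpretation to the user.
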