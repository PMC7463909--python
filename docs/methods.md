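# Methods

`calcinet` reimplements, as a tested pipeline, the analysis chain used to
quantify how acute hypoxia (and a candidate neuroprotective drug) degrades
the functional connectivity of dissociated neuron–glial cultures observed
by calcium imaging: per-cell transient detection → activity statistics →
thresholded pairwise-correlation networks → group statistics, plus the
multi-reference ΔΔCt estimator used for the accompanying qPCR panel.
Because no raw recordings are publicly deposited for this kind of study,
the package ships a synthetic culture simulator with known ground truth;
the analysis modules are written against the generic recording contract
(traces + geometry) and apply unchanged to real per-cell traces.

## The culture simulator

**Geometry.** `n_cells` somata (default 60) are scattered uniformly on a
`field_width × field_height` µm field (default 400 × 400) by rejection
sampling under a hard minimum centroid separation (15 µm). Radii are
normal (mean 10 µm, sd 2, truncated at 1 µm); a seeded choice marks
`astrocyte_fraction` (default 0.3) of the cells as astrocytes. The
imaged-field cell count is not a published quantity; 60 cells keeps all
pairwise computations desk-scale while leaving ≈5–10 soma-contact pairs
per culture.

**Structure.** Each unordered neuron pair is independently an edge with
probability `connect_p0 · exp(−d/connect_lambda)` (λ = 150 µm).
Astrocytes receive no structural edges.

**Activity.** A Poisson network drive (`burst_rate` = 8 min⁻¹) picks a
seed neuron per burst among the non-silent neurons; each structural
neighbour joins with `participation_prob`, with a 0–0.25 s lag.
Recruitment stops one hop from the seed: this keeps the correlation
structure local to the planted graph and analytically predictable, at the
cost of not producing the culture-wide avalanches real networks can show.
A seeded choice of `silent_fraction` of all cells (fixed count, not
Bernoulli, so the active fraction is tight across replicates) receives no
events. Non-silent astrocytes fire independent Poisson transients
(0.4 min⁻¹) with kernel time constants twice the neuronal ones. Every
event is convolved with a difference-of-exponentials kernel
(τ_rise = 0.3 s, τ_decay = 3 s, peak ΔF/F = 1.0 — the transient scale of
a high-affinity green calcium dye), every cell receives one shared
Ornstein–Uhlenbeck background (τ = 10 s, sd `background_amplitude`) and
white noise (sd 0.03 ΔF/F), and traces are rebuilt around a positive
100 a.u. baseline. All randomness for one recording comes from one
`numpy` Generator seeded by `config.seed`, so output is bit-reproducible.

**What the generator does and does not emulate.** It reproduces the
statistical structure the network analysis assumes — distance-decaying
connectivity, burst-driven correlated neuronal transients, independent
slow astrocyte activity, a silent-cell fraction, a weak shared slow
component, measurement noise. It has no photobleaching, motion, focal
drift, cell overlap/segmentation error, inhibition, or drug
pharmacokinetics; treatment arms are regime presets, not mechanisms.
Passing tests therefore demonstrate correctness of the analysis chain and
its calibration on data with this structure, not performance on real
microscopy.

## Regime presets and calibration

The six presets (`intact`, `hypoxia`, and the four drug arms: 1/15 µM,
immediate/post-treatment) differ only in `silent_fraction`,
`participation_prob`, `connect_p0` and `background_amplitude` — the four
parameters an insult plausibly acts on. Their values are package
calibration constants: they were tuned, once, so that the full pipeline
(simulate → ΔF/F → detect → correlate) reproduces the published
group-level readouts for the two anchor groups —

* intact: ≈50% working cells; pooled mean adjacent-pair ρ within the
  normal band 0.21 ± 0.08 (shipped preset lands at ≈0.18–0.23 over
  6-culture cohorts); percent correlated connections ≈27% (published:
  30.93%);
* hypoxia: ≈25% working cells (published median 25.25%); pooled mean
  adjacent-pair ρ ≈ 0.08–0.11 around the published floor value 0.10.

The four drug arms are set to give the published qualitative ordering
(immediate treatment preserves activity and, partially, connectivity;
post-treatment preserves activity at 15 µM but not connectivity) and are
not calibration anchors. Absolute connections-per-cell magnitudes scale
with cell count; the published intact value (97.92) comes from fields
with hundreds of cells and is not reproduced at the 60-cell default —
the calibrated quantities are the intensive ones (percentages, mean
correlations).

## ΔF/F and event detection

F₀ is a running 20th percentile of the raw trace in a centred 60 s
window (clipped at the edges); ΔF/F = (F − F₀)/F₀. The percentile
baseline tracks slow drift (a 100→120 a.u. linear drift over 10 min
leaves |ΔF/F| < 0.05) while sitting below sparse transients.

Detection is two-threshold hysteresis on ΔF/F: an oscillation opens at
the first frame ≥ θ_on = 0.2 and closes at the first frame < θ_off = 0.1
(or at the trace end); events shorter than 1 s are discarded. Duration
is onset-to-offset in seconds; with τ_decay = 3 s and unit amplitude a
single transient spans ≈7 s, so the defaults detect every isolated
default-amplitude event at default noise while producing essentially no
false events on silent cells. A cell with ≥1 event is *working*;
frequency (osc/min) is computed over working cells only, since the
source definition ("average number of oscillations per min") does not
state a denominator; duration statistics pool all events in a culture.
Overlapping transients within a cell merge into one detected event —
recall scoring treats a planted onset falling inside a detected interval
(±2 s) as matched.

## Functional networks

Pairwise Pearson correlation of full-length ΔF/F traces (Spearman
available as a switch; Pearson on the continuous signal is the minimal
reading of "pairwise correlation analysis"). Zero-variance traces get
ρ = 0, flagged, so silent cells remain isolated nodes and stay in all
denominators. The functional graph keeps every cell as a node and joins
pairs with ρ strictly greater than the threshold (default 0.3, justified
by the astrocyte-monoculture null: with no shared drive the 95th
percentile of distant-pair (>100 µm) correlations stays well below 0.3).
Metrics: connections per cell 2E/N; mean ρ over adjacent pairs (somata in
contact: distance ≤ r_i + r_j + 1 µm, boundary inclusive); percent
correlated connections 100·E/(N(N−1)/2). The identity
`connections_per_cell = percent_correlated·(N−1)/100` holds exactly and
is property-tested. Mean adjacent ρ is reported unfloored (the published
hypoxia value "0.10 (0.10–0.10)" suggests a reporting floor in the
original software; this package reports the actual mean, with a flag when
no pair is adjacent).

## Group statistics

Viability is 100·(1 − dead/total) to 2 decimals, summarised mean ± SEM;
activity/network metrics are summarised median (Q1, Q3) with
linear-interpolation quantiles (`numpy.percentile` default). Two-group
tests are Mann–Whitney U: exact enumeration when the combined n ≤ 12
with no ties, tie-corrected normal approximation with continuity
correction otherwise (two identical all-tied samples are returned as
p = 1). Multi-group comparison is one-way ANOVA with Tukey HSD
(studentized range); the source's "two-way ANOVA" names no factors, so
one-way across groups is the default and an explicit hypoxia × treatment
two-factor ANOVA is exposed separately. Fold changes are ratios of group
medians; no multiple-testing correction is applied beyond Tukey.

## ΔΔCt expression

ΔCt_g = mean Ct_control − mean Ct_sample per gene (condition means —
no per-replicate pairing is assumed), and
R = 2^(ΔCt_target − (1/K)·ΣΔCt_ref) over K reference genes (ACTB, GAPDH,
RPLP0, POLR2F; K = 4 gives the ¼ coefficient; K = 1 reduces to classical
2^ΔΔCt). Efficiency is fixed at 2. Significance is a permutation test:
whole replicates (columns, all genes jointly — preserving replicate
linkage) are relabelled control/sample; two-sided
p = (1 + #{|log₂R_perm| ≥ |log₂R_obs|})/(n_perm + 1), so p is bounded in
[1/(n_perm+1), 1]. This randomization scheme stands in for the
resampling test of dedicated relative-expression software.

## Numerical choices and degenerate inputs

* Placement raises after a bounded number of rejection attempts
  (2000 per cell), reporting the count.
* Detector ties: the onset is the *first* frame at/above θ_on, the
  offset the *first* frame below θ_off; events are disjoint by
  construction.
* Fewer than two cells → network metrics error; no adjacent pairs →
  mean adjacent ρ = 0 with a flag; dead > total, zero baseline median,
  all-zero within-group variance → explicit errors.
* Geometry CSVs are read with round-trip float precision so write→read
  is exact; traces are stored at 6 decimals (≈10⁻⁴ relative error at
  the 100 a.u. baseline, far below noise).

## Problem sizes

Defaults (60 cells, 600 s at 2 Hz = 1200 frames, 6 cultures/group) keep a
full six-group experiment around a minute on one CPU and give stable
correlation estimates (≈1200 frames against an ≈6 s signal correlation
time). The calibration checks use 6-culture cohorts of the anchor
presets and a 50-cell astrocyte monoculture on a 600 × 600 µm field.

## Known limitations

One-hop burst propagation caps attainable long-range correlation; the
shared background is global rather than spatially structured, so
adjacent and distant silent pairs share the same residual correlation;
preset constants are calibrated at the 60-cell default and would need
re-calibration at very different densities; the permutation test
requires ≥2 replicates per condition and full replicate linkage across
genes.
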