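# Methods

## Data model

All fragment-level data are anchored to a genome-wide CpG serial index
(1-based, contiguous across chromosomes), the coordinate system of
PAT/BETA-style files. A fragment is a pattern over {C = methylated,
T = unmethylated, . = unobserved} starting at a serial index, with a
multiplicity count. Coverage is defined as mean observed CpG calls per CpG
site — the natural fragment-level analogue of depth, needed because target
coverages (2.5–30×) are specified without an estimator. BED emission of
blocks is 0-based half-open (C of the first CpG through G of the last),
while CpG serial ranges are 1-based inclusive; the two are kept mutually
consistent through the index.

Up-sampling in `resample_to_coverage` draws molecules with replacement and
keeps duplicates as multiplicity counts; down-sampling consumes a random
permutation without replacement. Both stop within one fragment of the call
target and are bit-reproducible given a seed.

## Synthetic data generator

The generator emulates, at desk scale, a multi-tissue methylation atlas and
plasma-like mixtures:

- **Atlas structure.** 10 cell types × 3 replicates over 6,000 blocks of
  3–8 CpGs (intra-block CpG gaps 2–60 bp, so spans stay far below the
  5,000 bp block cap; inter-block gaps 0.5–3 kb across 2 chromosomes).
  Each type owns 500 *private hypomethylated* blocks, pairwise disjoint
  across types. 500 per type (rather than a few dozen) is deliberate: it
  reproduces the 500-marker deconvolution configuration that the spike-in
  experiments identify as optimal, so that configuration is exercised
  rather than vacuously truncated.
- **Methylation levels.** Baseline block means ~N(0.85, 0.04), hypo-block
  means ~N(0.10, 0.03), both clipped to [0,1]; the planted separation is
  ≥ 0.3 (the marker threshold) by construction, with ~0.75 typical.
  Between-replicate jitter s.d. 0.03 per block models individual
  variation; mixtures draw a fresh jitter realization, so markers are never
  derived from the very sample being deconvolved (the analogue of excluding
  spike-in samples from marker derivation to avoid overfitting).
- **Reads.** Fragment CpG counts uniform on {3,…,10} — enough to satisfy
  the ≥3-observed-CpG classification rule while exercising its exclusion
  branch (fragments truncated at chromosome ends can be shorter). Each CpG
  call is Bernoulli in the block beta; bisulfite conversion error (0.5%
  false C) and inappropriate conversion (0.5% false T) act in both
  directions. No read-level noise model is specified by the underlying
  study; 0.5%/0.5% is a typical WGBS conversion-fidelity figure and is
  config-exposed.
- **Mixtures.** Background composition is blood-dominated (four blood
  lineages at 90%: granulocytes 35%, megakaryocytes 25%, monocytes 15%,
  lymphocytes 15%; remainder endothelium/hepatocyte/erythroblast/adipocyte;
  neuronal types at 0), reflecting healthy plasma. A spike fraction f
  rescales the background by 1−f. The truth record stores realized
  per-type fragment fractions.

What the generator does **not** model: base-pair fragment lengths and
nucleosome-positioning fragmentation bias, non-random genomic placement of
cfDNA fragments, unconverted-read filtering, cell types absent from the
reference, and the heavy-tailed coverage of real WGBS. Passing tests
therefore demonstrate the correctness and internal calibration of the
pipeline under its stated assumptions — not the detection limits achievable
on real plasma, which the study itself found substantially worse at low
spike fractions.

## Segmentation

The named segmentation tool used upstream in the field does not publish its
objective, so segmentation here is defined explicitly: partition each
chromosome's CpGs to minimise the sample-averaged within-block SSE of
per-CpG beta values plus λ·(number of blocks), subject to ≥ min_cpg CpGs
per block and ≤ max_bp genomic span, solved exactly by dynamic programming
(window-limited by the span constraint). λ = 0.05 by default: below the
SSE gain of splitting a 0.3 methylation step flanked by ≥ 4 CpGs (~0.18)
and above the expected spurious gain from binomial beta noise at ~10×
depth (~0.02). Uncovered CpGs contribute no cost. Where the constraints
are jointly infeasible, undersized blocks are emitted with a `flagged`
attribute (implemented as a large additive penalty, so the DP uses as few
as possible) and excluded from methylation tables by default. Absolute
block counts of the real genome are out of scope by design.

## Marker discovery

Per block and sample, methylation is the pooled call ratio across the
block's CpGs, NA when mean depth < 5. A block is tested for a target type
when ≤ 1/3 of target and of background entries are NA and both sides have
≥ 2 observed values. The test is Welch's (unequal-variance) two-sided
t-test — group sizes are very unbalanced (3 replicates vs 27 background
samples here; 3 vs ~200 at full scale), where pooling variances is unsafe.
The background is the pool of all non-target samples, not the mean of type
means. Thresholds: |Δmean| ≥ 0.3, p ≤ 0.05 raw — no multiple-testing
correction, deliberately, since the subsequent ranking-and-truncation step
(top-k by the gap quantile(background, 0.025) − quantile(target, 0.75) for
hypomethylated markers; mirrored under beta-flip for hypermethylated ones)
is the operative selection. Quantiles use linear interpolation (type 7);
ranking ties break by smaller p, then genomic order, for deterministic
output. Both directions are computed, but deconvolution uses hypomethylated
markers only.

Clustering QC follows the standard recipe: average linkage on cityblock
distances with optimal leaf ordering, over the top 1% of blocks by variance
among NA-free blocks. At desk scale 1% of a few hundred blocks is too few
to discriminate 10 types, so the fraction is a parameter; the default-scale
suite verifies replicate purity at the 1% setting.

## U/X/M classification and NNLS deconvolution

Thresholds follow the published read-level defaults (U: f ≤ 0.25, M:
f ≥ 0.75, ≥ 3 observed CpGs), config-exposed. A molecule counts toward a
marker only via the CpGs it observes *inside* the marker's serial range —
flanking CpGs never dilute region specificity, and the ≥3-CpG rule applies
to the inside calls. The atlas pools replicates before forming U/(U+X+M);
markers with zero eligible molecules in any cell type are NA rows, dropped
from both the design matrix and the sample vector (count reported in the
result diagnostics). The solver is plain NNLS followed by normalisation to
the simplex — not equality-constrained least squares — matching standard
practice and keeping the estimator simple; an optional √count row weighting
exists (off by default, as the upstream tool's weighting is unstated).
A sample whose usable markers carry no signal at all returns all-NaN
proportions with a `degenerate` flag rather than dividing by zero.

## Spike-in evaluation

"Detection" is an estimated spike-type proportion strictly above a
threshold, default 0 — the loosest defensible reading, exposed as a
parameter. AUC is the Mann–Whitney U statistic over n₁·n₂ with half-weight
ties (no curve interpolation, deterministic). The false-positive model is
OLS of the per-replicate count of strictly-positive cell types on coverage
and marker count. Replicates default to 12 per grid cell, mirroring the 12
plasma samples the optimised configuration was applied to.

**Calibration.** The calibration operation is OLS of estimated on true
fraction with adjusted r² = 1 − (1−r²)(n−1)/(n−2). The headline linearity
check regresses *per-fraction mean* estimates (20 replicates per fraction
at 1/2.5/5/10%, 10×, 500 markers) on the true fractions. The reason is a
counting-noise bound, not convenience: at 10× coverage a 1% spike
contributes only tens of U-molecules to the spike type's markers
(~4,000–5,000 molecules land in those markers per sample at either desk or
full scale), so a single replicate's estimate has ~15–45% relative Poisson
error and replicate-level OLS cannot exceed r² ≈ 0.99 at any atlas size.
Only the replicate-averaged calibration curve can exhibit adjusted
r² > 0.998, and that is the quantity the per-marker-set linearity claim
describes; the per-replicate scatter instead shows up in the poor AUC at
≤ 0.5% spike-ins.

Problem sizes throughout (6,000 blocks, ~33,000 CpGs, 30 reference samples
at 30×, mixtures of ~50,000 fragments at 10×, 8–20 replicates per
condition) were chosen as the desk-scale regime in which every stage — and
in particular the 500-marker configuration — runs end to end in seconds to
a few minutes while keeping Monte-Carlo error well inside the asserted
margins.

## Pharmacokinetic detectability model

Internal units are pg, min, µl; public interfaces accept years/days,
litres and percent and convert explicitly, because the source constants mix
units freely. The model is the steady-state infusion equation
C = d·k₀·t½/(ln 2·Vd), with k₀ = (cells dying) × 6.46 pg / duration —
a constant loss rate over the disease course, consistent with
neurofilament kinetics plateauing during progression. Defaults: d = 0.03
(megakaryocyte/endothelium maximum; erythroblast minimum 3×10⁻⁵ spans the
plausible range), t½ = 114 min (steady-state, not distribution,
half-life), Vd = 3.0 L plasma, 500,000 lower motor neurons, total cfDNA
297 pg/µl. The inverse (death rate required for a target cfDNA fraction)
is the exact algebraic inversion and round-trips with the forward model to
1×10⁻¹² relative. With these constants, one-year total loss of all motor
neurons yields 3.4×10⁻⁶ % of plasma cfDNA; the published headline bound of
1.6×10⁻⁵ % is not exactly derivable from the stated constants under any
obvious duration/d pairing, so it is treated as an upper bound, not an
equality. Two-compartment distribution kinetics are deliberately out of
scope: only the steady-state form enters the published estimate.

## Known limitations

- Synthetic backgrounds are cleaner than real plasma: real cfDNA carries
  unmodelled cell types, batch effects and non-uniform coverage, so the
  AUC and detection probabilities here are upper bounds on real-data
  performance (AUC at 1% spike is near 1.0 synthetically vs 0.69 reported
  on real backgrounds).
- Marker counts and block boundaries of the real genome are not
  reproduced; all counts are properties of the synthetic atlas.
- The segmentation objective is this package's own definition (documented
  above), chosen for exactness and testability rather than fidelity to any
  unpublished implementation.
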