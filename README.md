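# cfmeth

Fragment-level methylation deconvolution of cell-free DNA (cfDNA), built
around the question of whether DNA released by dying motor neurons (MN) can
be detected in blood plasma — the premise of a WGBS-based biomarker for
amyotrophic lateral sclerosis.

Plasma cfDNA is a mixture of DNA from many dying cell populations, dominated
by blood lineages. Because CpG methylation is cell-type specific and is read
out molecule by molecule in whole-genome bisulfite sequencing (WGBS), the
cell types contributing to a cfDNA sample can be estimated from reads
overlapping regions that are *uniquely hypomethylated* in one cell type.
`cfmeth` implements that whole chain on fragment-level (PAT-format) data:

1. **Segmentation** of the genome's CpGs into blocks of co-methylated sites
   (exact dynamic program minimising within-block beta variance plus a
   block-count penalty, under `min_cpg >= 3/4` and `max_bp <= 5000`
   constraints).
2. **Marker discovery**: per block and sample, mean methylation with a
   read-depth floor (NA below 5x); a block is a marker for a target type
   when |mean(target) − mean(background)| ≥ 0.3 and a Welch t-test gives
   p ≤ 0.05; hypomethylated markers are ranked by the gap between the
   background 2.5th centile and the target 75th centile and truncated to
   top-k ∈ {25 … 500}.
3. **U/X/M deconvolution**: each molecule overlapping a marker is classified
   by its methylated-CpG fraction *f* inside the region (U if f ≤ 0.25, M if
   f ≥ 0.75, else X; ≥ 3 observed CpGs required). The reference atlas **A**
   is the markers × cell-types matrix of U-proportions; a sample's
   per-marker U-proportion vector **b** is explained by non-negative least
   squares, `min‖Aw − b‖₂, w ≥ 0`, and `w` is normalised to proportions.
4. **Spike-in experiments**: synthetic mixtures of a blood-dominated
   background with 0–10% spiked motor-neuron reads at 2.5–30× coverage,
   scored by detection probability, Mann–Whitney ROC AUC, linear
   calibration, and a regression of false-positive cell-type counts on
   coverage and marker count.
5. **Pharmacokinetic detectability model**: at steady state the plasma
   concentration of DNA released at rate k₀ is `C = d·k₀·t½ / (ln 2 · Vd)`,
   with d the fraction of released DNA reaching plasma cfDNA, t½ = 114 min
   and Vd = 3.0 L; dividing by the total cfDNA concentration (297 pg/µl)
   gives the maximum share of cfDNA attributable to a dying population of
   known size (~500,000 lower motor neurons, 6.46 pg DNA per diploid
   genome).

A seeded synthetic-data generator (`cfmeth.synthetic`) produces atlases with
planted private hypomethylated blocks, fragment-level reads with
bisulfite-conversion noise, and spiked plasma-like mixtures, so every stage
is testable end to end without downloads.

## Worked example

```python
from cfmeth import (AtlasSpec, SyntheticAtlas, MixtureSpec, deconvolve,
                    CfDNADetectabilityModel, PKParams)
from cfmeth.pipeline import ReferencePipeline

atlas = SyntheticAtlas(AtlasSpec())          # 10 cell types, 6,000 blocks
pipe = ReferencePipeline.build(atlas, coverage=30.0, min_cpgs=(3,), seed=11)
ref = pipe.reference_atlas(min_cpg=3, top_k=500)

mix, truth = atlas.simulate_mixture(
    MixtureSpec(spike_cell_type="MotorNeuron", spike_fraction=0.05,
                coverage=10.0), seed=123)
print(f"true spike fraction: {truth.spike_fraction_realized:.4f}")
print(deconvolve(mix, ref).summary())

pk = CfDNADetectabilityModel(PKParams())
print(f"max MN share of plasma cfDNA over 1 y: "
      f"{pk.max_cfdna_percent(duration_years=1.0):.3e} %")
print(f"MN deaths/day needed to reach 1%:      "
      f"{pk.required_death_rate_per_day(0.01):,.0f}")
```

Output:

```
true spike fraction: 0.0518
UXM deconvolution result
============================================
markers used / dropped : 4603 / 1
residual norm          : 6.07518
cell types detected    : 9
--------------------------------------------
cell type                 proportion
Granulocyte                   0.3295
Megakaryocyte                 0.2356
Lymphocyte                    0.1497
Monocyte                      0.1474
MotorNeuron                   0.0488
Endothelium                   0.0361
Hepatocyte                    0.0289
Erythroblast                  0.0147
Adipocyte                     0.0094
CorticalNeuron                0.0000

max MN share of plasma cfDNA over 1 y: 3.403e-06 %
MN deaths/day needed to reach 1%:      402,538,138
```

The mixture carried a true 5.2% motor-neuron spike and the deconvolution
estimates 4.9%, with the blood background recovered close to its nominal
composition. The PK model says the most optimistic biological scenario
(every lower motor neuron dying within one year, maximal plasma
availability d = 3%) would still leave motor-neuron DNA at ~3×10⁻⁶ % of
plasma cfDNA — about six orders of magnitude below that comfortably
detectable 5% and far below the ~1% practical detection limit seen in the
spike-in experiments; reaching 1% would take ~4×10⁸ motor-neuron deaths per
day, vastly more neurons than exist.

A `cfmeth` command-line tool exposes the same stages
(`cfmeth simulate|segment|markers|deconv|evaluate|pk`, and `cfmeth io
merge|resample|beta`); see `cfmeth --help`.

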