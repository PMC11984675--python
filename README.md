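# geosilence

Analysis of **geographically clustered transcriptional silencing** in
single-cell RNA-seq, together with the multi-isotope imaging mass
spectrometry (MIMS) metrics that reveal its anatomical counterpart —
DNA-dense, transcription-silent nuclear globules. The package is aimed at
researchers studying cellular senescence (or any state suspected of
silencing chromosomal segments rather than individual genes) who have a
count matrix with cluster labels, a gene annotation, and optionally
ion-count images.

## The statistic at the core

For cell *i* in cluster *c* and gene *g* expressed in *c* (cluster mean
μ₍cg₎ > 0), the gene is **silenced** when

```
x_ig ≤ (1 − θ) · μ_cg ,   θ = 0.5 by default
```

— at least a 50% reduction relative to the cluster mean, the signature of
hemi-allelic (one-allele) silencing. Ordering the evaluated genes along
each somatic chromosome, a **geographical silencing event** is a maximal
run of ≥ L consecutive silenced genes (L = 10). Per cell, the number of
events is its **burden**; cells with > 150 events are *high burden* and
cells with < 25 are the opposite extreme. The pipeline summarizes run
frequencies per cluster and chromosome (two-way ANOVA with Sidak-adjusted
contrasts), compares high-burden frequencies between conditions
(chi-square), and tests recurrently silenced genes (prevalence > 20% of
evaluated cells) for gene-set over-representation (hypergeometric + BH),
with a ranked, permutation-tested variant for the high- vs low-burden
contrast.

The imaging side quantifies isotope enrichment per pixel as
`E = (R/R_nat − 1) × 100` (% above natural abundance), segments
nucleus/cytoplasm from the ³¹P and CN⁻ planes, measures nuclear
DNA-labeling heterogeneity as a median absolute deviation (M.A.D.),
runs pixel-level PCA and line profiles, and detects globules as connected
regions that are ¹³C-rich, ³¹P-rich and devoid of ¹⁵N labeling.

A fully seeded synthetic-data module generates cohorts with ground-truth
injected segments and ion images with ground-truth globules, so every
stage is testable without downloads. See `docs/methods.md` for the model,
parameter defaults and their rationale, and known limitations.

## Worked example

```python
import geosilence as gs
from geosilence.burden import per_cell_burden, classify_burden, high_burden_test, class_frequencies

spec = gs.SimulationSpec(seed=3)                # 19 x 1000 genes, 500 cells/arm
dataset, truth = gs.generate_cohort(spec)
annotation = gs.generate_annotation(spec)
config = gs.AnalysisConfig()                    # θ=0.5, L=10, >150 / <25

silence = gs.call_silenced_dataset(dataset, config)
events = gs.detect_runs_dataset(silence, annotation, config.somatic_chromosomes)
records = classify_burden(per_cell_burden(events, dataset.cell_meta, 10))
print(class_frequencies(records).round(3))
test = high_burden_test(records, [("senescent", "control")])[0]
print(f"chi-square {test.statistic:.1f}, p = {test.p_value:.2e}")
```

prints

```
burden_class    low  intermediate   high
condition
control       0.912         0.076  0.012
senescent     0.790         0.146  0.064
chi-square 18.5, p = 1.71e-05
```

Read: ~91% of control cells have fewer than 25 silencing events, while
6.4% of senescent cells exceed 150 events — the extreme-burden tail — and
the condition difference in that tail is highly significant. The scripts
in `examples/` walk through each capability (silencing calls and
recurrent genes, the run-length landscape and ANOVA, burden and
enrichment, MIMS globule quantification) and print annotated output.

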