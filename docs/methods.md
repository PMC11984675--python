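# Methods

## The phenomenon and the analysis model

Senescent cells can silence transcription over contiguous chromosomal
segments rather than gene by gene: condensed, DNA-dense nuclear globules
exclude nascent-RNA labeling, and single-cell RNA-seq shows stretches of
consecutive genes that all drop in expression together. Because a globule
is expected to capture one allele of the genes inside it, the transcript
count of an affected gene should fall by about half — *hemi-allelic
silencing*. This package implements the downstream analysis of that model:

1. **Silencing call.** A gene is silenced in a cell when its (optionally
   depth-scaled) count is at most `(1 − θ)` times the mean of the cells in
   that cell's cluster, with θ = 0.5 by default. The boundary counts as
   silenced (the definition is "at least a θ reduction"). Genes whose
   cluster mean is zero are excluded from evaluation — *not evaluated* is
   distinct from *not silenced*, and the distinction propagates through
   every downstream stage.
2. **Runs.** Within each cluster, the evaluated genes are ordered along
   each somatic chromosome by start coordinate (ties broken by gene id).
   A geographical silencing event is a maximal run of consecutive silenced
   genes of length ≥ L (L = 10 by default). Unexpressed genes are skipped
   rather than treated as run breakers, because they were excluded from
   evaluation entirely; a strict annotation-adjacency mode is available
   for sensitivity analysis.
3. **Burden.** A cell's burden is its number of qualifying events across
   the somatic chromosomes. Cells with more than 150 events are *high
   burden*; cells with fewer than 25 are the *low* extreme; both
   inequalities are strict, so boundary cells are intermediate. Condition
   differences in the high-burden fraction are tested with a Pearson
   chi-square on the 2×2 high/not-high × condition table (no continuity
   correction by default; high-vs-low contrast available).
4. **Enrichment.** Recurrently silenced genes are those silenced in
   strictly more than a fraction π (default 0.2) of the cells in which
   they were evaluated. An unranked list is tested by one-sided
   hypergeometric over-representation with Benjamini–Hochberg adjustment;
   the high- vs low-burden contrast uses a weighted Kolmogorov–Smirnov
   running-sum score over genes ranked by log fold-change (pseudocount 1),
   with significance from seeded gene-label permutations. The universe is
   the set of genes evaluated in the relevant cells, not the whole
   annotation, to avoid expression bias.

Statistical comparisons of run frequencies across chromosomes use a
two-way ANOVA (group × chromosome) on per-cell per-chromosome event
counts, with Welch t contrasts per chromosome adjusted by Sidak
(`1 − (1 − p)^k` over all chromosome × pair contrasts). Cells serve as
replicates; the error structure of the original figure is not specified,
so this is the simplest design with honest degrees of freedom.

## Normalization

The silencing definition speaks of transcript counts, so `raw` is the
default. Sequencing depth, however, confounds a 50%-reduction criterion
directly: a shallow cell looks globally silenced. `depth_scaled`
normalization (cell total scaled to the median total) is provided and
recommended whenever library sizes vary; note that it also removes genuine
global transcriptional shutdown, so deeply silenced cells become invisible
to it — the choice is exposed, not hidden. A leave-one-out cluster mean is
available behind a flag; by default the evaluated cell contributes to its
own cluster mean, the plainest reading of the definition.

## The synthetic cohort generator

`SimulationSpec` emulates a two-arm (control vs. senescent) experiment on
a mouse-like genome of 19 autosomes. Counts are negative binomial with
variance μ + μ²/k; per-gene baseline means are log-normal and per-cell
depth factors log-normal with unit mean. Each cell receives a number of
injected non-overlapping 12-gene segments whose means are multiplied by
(1 − r), r = 0.5 for hemi-allelic silencing; placements are uniform over
all non-overlapping configurations (an exact gap construction, so dense
burdens stay fast). Every injected segment is recorded as ground truth.

Default parameters were chosen once to reproduce, at a realistic
transcriptome size (19 × 1000 genes), the qualitative burden phenomenology
the analysis is built around: most cells carry 0–25 events, the senescent
arm is right-shifted at every run length, and only the senescent arm has
an appreciable tail of > 150-event cells. The defaults are:

| parameter | default | why |
| --- | --- | --- |
| `genes_per_chromosome` | 1000 | ~19k genes ≈ a real transcriptome; the absolute burden thresholds (>150, <25) are only meaningful at this scale |
| `baseline_log_mean`, `baseline_log_sd` | 0.3, 0.3 | a narrow band of low-expressed genes (median ≈ 1.35 counts), the regime where silencing calls are zero-driven; see the note below |
| `dispersion` (k) | 10 | near-Poisson, typical of UMI counts |
| `depth_factor_sd` | 0.45 | realistic library-size spread (CV ≈ 47%) |
| `lambda_control` / `lambda_senescent` | 1 / 60 | sparse background burden vs. a clear senescent load (~4% of the genome hemi-silenced) |
| `tail_fraction`, `lambda_tail` | 0.2, 1500 | a deep-senescent subpopulation whose segments saturate the genome (~full coverage at capacity 1577) |
| `tail_depth_factor` | 0.85 | deep-senescent cells also transcribe less overall, mirroring the reduced nuclear RNA synthesis of senescence |

Two non-obvious couplings motivated the narrow baseline-mean band. First,
the count of *maximal* runs at L = 1 is non-monotone in the per-gene call
probability (it peaks at 0.5): in a background regime near p = 0.5, extra
silencing merges runs and the event count can *fall*. Keeping the
background call probability near 0.3 puts every silencing increment on the
rising side of that curve, so the cumulative run-length curve shifts
rightward at every L. Second, cluster-relative thresholds are themselves
depressed when many cluster cells are silenced at a gene; in the
zero-driven regime (thresholds below one count) this depression has no
effect on the calls, which keeps the arms comparable. With broad
(log-sd ≈ 1) gene means both effects reappear and the L = 1 end of the
curve becomes sign-unstable — a genuine property of maximal-run counting,
not of the implementation.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, cell-cycle structure, gene-length or GC biases, realistic gene
spacing, or allele-level expression (hemi-allelic silencing is modeled as
a mean reduction, since the analysis observes total counts only). Cluster
labels default to the condition labels — real clustering is an upstream,
external step — and a `single`-cluster mode exists for null studies (see
below). Passing tests on this generator therefore demonstrates the
correctness and calibration of the *analysis*, not robustness to every
artifact of real data.

### A note on recovering individual segments

With hemi-allelic (r = 0.5) reduction, the probability that a 50%-reduced
gene is called silenced is the negative-binomial lower-tail mass at half
the cluster mean — about 0.6–0.75 across realistic mean regimes. Ten
consecutive calls therefore occur for only a few percent of individual
12-gene segments, and regimes that push the per-gene call rate up push
the background call rate up in lockstep, flooding the genome with
background runs. Individual hemi-silenced segments are thus close to
undetectable by consecutive-call runs; what the method measures reliably
is the *aggregate* shift in run-length frequencies and burden between
conditions, which is exactly how it is used. Complete silencing (r = 1)
is recovered essentially perfectly. The acceptance suite keeps an
assertion of high per-segment sensitivity at r = 0.5 as a falsifiable
record of this limit.

## Null calibration of the burden test

Type-I error of the high-burden chi-square is measured on 500 small
exchangeable cohorts (4 × 500 genes, 60 cells/arm, equal segment rates,
no tail), with the burden threshold scaled to the cohort (high = at least
one event, ~24% of cells) so the 2×2 tables are well filled. Two design
points matter. The arms must share a single cluster: when clusters
coincide with the arms, each arm's calls are centered on its own cluster
mean, which absorbs arm-level fluctuations and makes the test markedly
conservative (rejection rate ≈ 0) — itself a noteworthy property of
cluster-relative definitions. And the threshold choice is part of the
design, fixed before measurement; the measured rejection rate at α = 0.05
is ~5% (500 seeds).

## MIMS image quantification

Isotope enrichment is `E = (R/R_nat − 1) × 100` per pixel, R the
minor/major count ratio, with natural-abundance defaults 0.0112 (¹³C/¹²C)
and 0.00367 (¹⁵N/¹⁴N), both overridable. Pixels with fewer than 100
major-isotope counts are masked, not zero-filled — a ratio of a handful
of Poisson counts is noise. Segmentation thresholds default to Otsu on
the ³¹P (nucleus) and ¹²C¹⁴N (cell) planes with small components removed.
Nuclear DNA-labeling heterogeneity is the median absolute deviation of
¹³C enrichment within the nucleus. Pixel PCA standardizes each feature
over the masked pixels and decomposes the correlation matrix, with the
sign convention that each component's largest-magnitude loading is
positive. Globules are 8-connected components that jointly satisfy high
¹³C (above nuclear median + 2 × M.A.D.), low ¹⁵N (below nuclear median)
and high ³¹P (above nuclear median + 2 × M.A.D.), with a minimum area of
a 0.2 μm disc; the robust two-channel outlier form keeps the
false-positive rate on null nuclei at the percent level while true
globules (hundreds of percent enrichment) pass by a wide margin. Group
comparisons check Shapiro–Wilk normality at α = 0.05 per sample and fall
back from the two-tailed t-test to the two-sided Mann–Whitney U.
No instrument-level corrections (deadtime, QSA) are applied; inputs are
assumed corrected counts.

The image generator paints background / cytoplasm / nucleus (and
optionally a condensed lamina ring and globules) with region-wise expected
counts and enrichments and samples every plane as Poisson. Globules are
¹³C- and ³¹P-rich with ¹⁵N at natural background; the lamina ring shares
their composition, which is what makes the pixel-PCA overlap between
globules and lamina reproducible.

## Numerical and degenerate-input choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; permutation p-values use add-one smoothing
  `(1 + #exceed)/(1 + n_perm)` and are bitwise reproducible.
- Ties in gene position are broken lexicographically by gene id; sorting
  is stable everywhere, so results are independent of input order.
- A chi-square table with a zero margin (e.g., no high-burden cell in
  either arm) is reported as no evidence (statistic 0, p 1) rather than an
  error; expected counts below 1 set a warning flag recommending an exact
  test.
- Clusters with fewer than two cells, zero-total cells under depth
  scaling, empty gene universes, all-invalid ratio images and uniform
  planes under Otsu all raise typed errors naming the offending object.
- Duplicate annotation records keep the smallest start; chromosome names
  are compared after stripping a `chr` prefix.
- Counts must be integers at load; depth scaling happens downstream only.

## Problem sizes used in the test and acceptance runs

Cohort-level checks run at 19 × 1000 genes with 500 cells per arm
(the calibrated default); the parameter-recovery study at 19 × 300 genes
per the stated recovery conditions; the null calibration on 500 cohorts
of 4 × 500 genes × 120 cells; imaging checks on 128 × 128 px images with
100-seed null batches. These sizes keep the full suite and the
acceptance script at a few minutes on one CPU while leaving every
statistical margin (type-I window, chi-square significance, monotone
shift) comfortably resolved.

## Known limitations

- Cluster-relative silencing is blind to silencing shared by a whole
  cluster (the cluster mean moves with the cells); the `single` cluster
  mode and the normalization switch make this visible but do not remove
  it. This is a property of the published definition itself.
- Per-segment recovery at hemi-allelic reduction is intrinsically weak
  (see above); burden values should be read as aggregate statistics.
- The ANOVA treats cells as independent replicates; within-cell
  correlation across chromosomes is ignored, as the original design is
  not specified further.
- GTF parsing is a minimal Ensembl-dialect reader (gene records with a
  `gene_id` attribute); exotic dialects should be converted to the TSV
  form.
- The imaging module analyzes single 2-D planes; no drift correction,
  3-D stacks, or raw instrument formats.
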