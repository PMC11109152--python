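# Methods

This note documents the models and procedures implemented in `chromclone`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish
about real data.

## Reference peak set

Peak summits (one list per condition) are extended to 801 bp windows
(±400 bp), pooled, ranked by descending summit significance, and kept
greedily iff they overlap no previously kept window; atlas peaks, recentred
to the same width, are appended afterwards under the same non-overlap rule;
kept windows are finally resized to 301 bp (±150 bp around the summit).
Coordinates are 0-based half-open throughout. Score ties are broken by
(chrom, position) so the output is invariant to input order. Disjointness
is enforced at the 801 bp stage only: resized 301 bp peaks are subsets of
disjoint windows, so their disjointness is inherited. Strand is ignored
(ATAC is unstranded). Atlas peaks are strictly appended after data peaks
rather than re-ranked against them; with atlas significance scores on a
different scale, appending is the only order-safe choice.

## Gene activity scores

`score(g,i) = Σ_p exp(-|center(p) - tss(g)| / λ) · c(p,i)` over peaks whose
centre lies within half the window of the TSS, followed by division by the
cell's mean score. λ = 1,000 bp is the e-folding length; the window
full-width is `2·⌈λ·ln(1/tail)⌉ = 9,212 bp` at tail = 1%. A "half-life"
parameterisation is sometimes meant base-2; only the e-folding reading
reproduces the 9,212 bp constant, so that is the default and the base-2
convention is available via `halflife_base2=True`. Distance is measured to
the peak centre; peaks are narrow (301 bp) so the anchor choice is
immaterial at λ = 1 kb. Per-cell normalisation averages over genes that
have at least one in-window peak (configurable): including never-scoreable
genes would only rescale all cells by a common constant.

## Deviation Z-scores

For annotation A and cell i: observed `X = Σ_{p∈A} c(p,i)`, expected
`E = f_A·T_i` where `f_A` is A's share of all reads and `T_i` the cell
total; `raw_dev = (X-E)/E`. Each of `n_background = 100` iterations
replaces every annotation peak with its b-th matched background draw and
recomputes the deviation; `z = (raw_dev - mean_b)/sd_b` (sd with the n-1
denominator) and the bias-corrected deviation `raw_dev - mean_b` are both
exposed. Entries with zero expectation (empty cells, empty annotations) or
zero background sd are masked as NaN and counted in a warning.

Backgrounds are matched on (GC, log1p mean accessibility), standardised to
zero mean and unit variance; each peak's draws are sampled with replacement
from its 50 nearest neighbours in that plane, self excluded. A kNN pool is
the simplest scheme that delivers "matched for GC content and mean
accessibility"; binned Mahalanobis sampling would be an equivalent
alternative. Pool membership is deterministic; draws are reproducible under
the seed.

## Peak-gene links, DORCs, residuals

Candidates are (gene, peak) pairs with the peak centre within 10 kb of the
TSS. Accessibility is depth-normalised (and optionally kNN-smoothed in a
supplied embedding; off by default so tests are exact); expression is
depth-normalised. The default correlation is Spearman — robust to sparse
counts — with Pearson available. The permutation p-value uses the add-one
rule `p = (1 + #{r_bg ≥ r_obs})/(1 + n_perm)` and so never reaches zero;
retained links require `r_obs > 0` and `p ≤ 0.05`. Genes with ≥ 3 retained
links are DORCs. Note the one-sided test's nominal level means ~5% of all
tested candidate pairs are retained under a broken pairing (the
permuted-RNA control); conditioning the denominator on positive-r
candidates roughly doubles that rate, which is a property of the test, not
a miscalibration.

DORC per-cell scores are `Σ_p c(p,i) / T_i · median(T)` over linked peaks,
optionally kNN-smoothed (k includes self; k = 1 is the identity).
Residuals are row-z-scored accessibility minus row-z-scored expression;
positive values flag cells whose chromatin runs ahead of transcription.
TF-vs-cognate-DORC Pearson correlation classifies activators (r > 0) and
repressors (r < 0); the function accepts either per-cell or
clone-aggregated profiles, since clone-level analyses correlate across
clones.

## Co-accessibility modules

Motif dedup: single-linkage components over |Pearson r| ≥ 0.8 between
motif-peak match profiles, keeping each component's most variable motif
(deviation-Z variance where supplied). PWM-level similarity is out of
scope because PWMs are not inputs. Jackstraw: PCA on the motifs×cells Z
matrix; per iteration 10% of motifs are permuted across cells and PCA
refit; the statistic is the max over the first 10 components of squared
loading × component variance, and a motif passes at empirical p ≤ 0.05
against the pooled null. TF-peak association: cells split at the median
Z per TF, Welch two-sample t-test per peak on depth-normalised,
per-cell-mean-centred counts, BH FDR ≤ 1e-06; the Welch form is chosen
over pooled variance for robustness. Modules: Louvain communities
(resolution 1.0, seeded) on the kNN graph (k = 30) of significant peaks'
fold-change profiles across TFs. The kNN digraph is symmetrised by union
(the scanpy/Seurat convention) rather than by intersection: with tied
distances — e.g. blocks of near-identical profiles — deterministic
tie-breaking makes neighbour lists asymmetric and an intersection graph
degenerates into singletons.

## Differential testing

Pseudobulk: exact integer sums per (sample, cell type, genotype); groups
under 10 cells are dropped with a warning. Size factors are
median-of-ratios against per-peak geometric means (peaks containing zeros
excluded), rescaled to geometric mean 1. Each peak gets a
negative-binomial GLM (log link, offsets = log size factors, design =
intercept + genotype + cell-type indicators). Dispersion is a per-peak
maximum-likelihood estimate (floor 1e-8) initialised from a Pearson moment
estimate and profiled in two rounds alternating with coefficient refits —
deliberately without empirical-Bayes shrinkage: at pseudobulk depths with
several replicates per arm the Wald statistic `β/SE` (two-sided normal) is
the operative quantity, and a shrinkage hook can be added behind the same
interface. No outlier refitting or independent filtering is applied.
Significance at BH FDR ≤ 0.01. Non-converged peaks are flagged;
configurably excluded from the FDR denominator.

DORC differential testing is a two-sided Wilcoxon rank-sum per
(DORC, cell type) — exact enumeration when both arms are ≤ 10 cells,
asymptotic otherwise — BH-corrected across all tests, with the effect
reported as the difference in mean normalised score.

Neighbourhood localisation computes exact Euclidean kNN (k = 50, self
excluded, distance ties broken by cell index for determinism) and reports
the fraction of neighbours with the query label. The statistic is
embedding-agnostic; the bundled embedding is PCA on depth-normalised
log1p counts with a deterministic sign convention (largest-|loading|
element positive per component), standing in for heavier topic-model +
batch-integration embeddings, which are out of scope. Cluster-restricted
analyses are expressed by subsetting cells, not by hard-coded cluster ids.

## Clone analytics

FPS: every assay column is z-standardised over all rows — WT and KO pooled,
matching a single scaling pass over the whole table (per-genotype scaling
is available behind a flag) — and the score is the unweighted Euclidean
WT-KO distance per clone. Constant columns are dropped with a warning, so
scores are comparable only within one call; the score is exactly invariant
to affine transforms of any assay column. Feature ranking uses Spearman
correlation of features against the score with BH-adjusted p-values.

Barcodes: reads are scanned for an exact 5' flank, the next 28 bases
taken, an exact 3' flank required, and the library's constant bases
enforced. Error correction visits barcodes in descending count order
(ties lexicographic) and merges each into the most abundant already-kept
barcode within Levenshtein distance ≤ 2 holding ≥ 5× its count — the
abundance-ratio guard prevents genuine co-abundant clones from collapsing —
then removes survivors with count < 10. Distance 2 and ratio 5:1 are the
conventional defaults for 28-mers and are exposed as flags. Merging
conserves total assigned reads; only the final count cut discards. Sister
samples are compared on fractional abundances with an OLS fit of B on A;
positive residuals flag clones expanded in B.

## Synthetic data generator

The generator emulates a bifurcating myeloid differentiation experiment:
pseudotime uniform on [0,1]; a branch label (monocytic/neutrophilic) takes
effect past pseudotime 0.5 with equal probability, before which cells are
"stem". TF activity programs are smooth functions of (pseudotime, branch)
— one stem-decaying, the rest branch-rising — with amplitude 1.5
(natural-log units on peak rates) and per-cell sd 0.1 fluctuations that
also feed the counts. Peak log-rates are
`baseline + Σ_m loading·activity + clone offset + ln2·ko_log_fc·[KO ∧ KO-peak]`,
softmax-normalised per cell and scaled by a lognormal per-cell depth
(mean `depth_mean`, sigma 0.3); counts are Gamma-Poisson with shared size
parameter `nb_dispersion` (∞ = Poisson). Baselines are Normal(0, 1) on the
log scale: real ATAC peak abundances span orders of magnitude, and this
spread is what makes accessibility-matched background pools representative
of the whole peak set rather than of the planted programs. Roughly 10% of
peaks carry a program (planted cis peaks plus ~60 intergenic carriers per
program), comparable to a typical motif's hit rate in a real atlas.

Each DORC gene's planted peaks sit spread across its ±10 kb TSS window
(plus one uncorrelated in-window decoy peak per gene); its expression rate
tracks the mean planted log-accessibility of those peaks evaluated at
pseudotime minus `lead_lag` — "foreshadowing" as a pure lag, not a causal
model. Clone offsets are iid Normal(0, `clone_offset_sd`) per
(clone, peak); the magnitude of real clone-to-clone chromatin
heterogeneity is unknown, so this is a free knob, not an estimate.
Genotype is assigned at the sample level (`frac_ko` of samples are KO) so
pseudobulk designs have replicates per arm. Identical seeds give
bit-identical outputs.

Default study conditions are 2,000 cells, 4,000 peaks, 300 genes, 40 DORC
genes × 6 peaks, 100 KO-responsive peaks at +1 log2, depth 5,000,
dispersion 10, 8 samples (4 per genotype), 8 clones. These sizes keep the
full test suite and the acceptance script to a couple of minutes on one
CPU while leaving every statistic well-powered.

What the generator does **not** model: read-level fragments, doublets,
batch effects beyond clone offsets, chromatin-potential causality, or the
scale of real atlases (hundreds of thousands of peaks, tens of thousands
of cells). Passing recovery tests therefore demonstrates correctness of
the estimators under a faithful miniature of the assumed data-generating
process — not performance on real data, where peak calling, pairing error
and batch structure add failure modes the generator deliberately omits.

Clone functional tables: WT profiles iid Normal(0,1) over 8 assay columns
(surface markers, cytokine, ROS, phagocytosis, proliferation); KO = WT +
perturbation·unit-direction + Normal(0, 0.3) noise. Barcode reads carry
iid substitutions at `error_rate` within the barcode; the default library
fixes 3 of the 28 positions, so at a 1% per-base error rate the expected
read loss to the perfect-constant-base filter is ~3%, within the 5%
recovery envelope of the corrected counts.

## Interfaces

The package is a library (plus `scripts/acceptance.py`); functions and
scripts are the interface, as with most single-cell analysis toolkits —
no shell CLI is shipped. On-disk formats are standard text: MTX triplets
with features/barcodes TSVs, BED6+GC for peaks, TSV tables, FASTQ for
reads.

## Known limitations

- Per-peak NB dispersion without shrinkage is noisier than shrunken
  estimators at very low replicate counts; with < 3 pseudobulk groups per
  arm the Wald test should not be trusted.
- The permutation link test's level is nominal per candidate pair;
  correlated candidates within a gene make the retained count
  overdispersed relative to binomial.
- GC content is consumed, never computed from genome sequence.
- Barcode merging is O(n²) in distinct barcodes and intended for
  library-scale (≤ ~10⁵) barcode sets.
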