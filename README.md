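# chromclone

Clone-resolved single-cell chromatin analytics: tools for asking whether
heritable, clone-of-origin epigenetic states shape how hematopoietic
progenitors respond to a genetic perturbation (e.g. loss of an epigenetic
regulator), using paired single-cell ATAC + RNA data, clone functional
assays, and expressed lineage barcodes.

## Who this is for

Computational biologists analysing paired multiome (scATAC + scRNA)
experiments with clonal structure — lineage-barcoded cultures,
single-clone-derived progenitor lines, or mouse chimeras mixing wild-type
and knockout cells — who need the full chain from peak sets to clone-level
statistics in one tested package.

## What it computes

- **Reference peak set** — per-condition peak summits are extended to
  801 bp windows, greedily deduplicated by summit significance into a
  disjoint set (optionally augmented with non-overlapping atlas peaks), and
  resized to 301 bp.
- **Gene activity scores** — accessibility summed around each gene's TSS
  with exponentially decaying weights, `w(d) = exp(-d/λ)` with λ = 1 kb
  over a 9,212 bp window (the span holding 99% of the weight).
- **Motif / annotation deviation Z-scores** (chromVAR-style) — for an
  annotated peak set A and cell i, the raw deviation is
  `(X - E)/E` with `X = Σ_{p∈A} c_pi` and `E = f_A·T_i`; it is
  bias-corrected and Z-scored against n = 100 background peak sets matched
  on GC content and mean accessibility.
- **Peak-gene cis-regulatory links and DORCs** — Spearman correlation of
  peak accessibility with paired gene expression for peaks within 10 kb of
  a TSS, tested against the peak's matched background draws
  (`p = (1 + #{r_bg ≥ r_obs}) / (1 + n_perm)`); genes with ≥ 3 retained
  positive links are domains of regulatory chromatin (DORCs), scored per
  cell and compared with expression via standardized residuals
  ("chromatin foreshadowing expression").
- **Co-accessibility peak modules** — motif dedup at |r| ≥ 0.8, jackstraw
  PCA selection of variable motifs, Welch t-tests of each peak between
  TF-high and TF-low cell halves (BH FDR ≤ 1e-06), and Louvain communities
  on the kNN graph of peak fold-change profiles (k = 30).
- **Pseudobulk differential accessibility** — counts summed per
  (sample, cell type, genotype), median-of-ratios size factors, per-peak
  negative-binomial GLM with a cell-type covariate, Wald test on the
  genotype coefficient, BH FDR ≤ 0.01.
- **DORC differential testing** — Wilcoxon rank-sum per cell type, BH FDR.
- **Neighbourhood localisation** — per cell, the fraction of its k = 50
  nearest embedding neighbours carrying a query label (e.g. KO genotype).
- **Functional Perturbation Score (FPS)** — each assay column of a paired
  WT/KO clone table is z-standardised; a clone's score is the Euclidean
  distance between its standardised WT and KO profiles. Helpers correlate
  FPS with chromatin features and TF activities across clones.
- **Barcode clonal tracking** — 28-mer lineage barcodes isolated between
  flanking sequences with constant-base filtering, error-corrected by
  bounded-edit-distance merging into abundant centroids, low-count
  (< 10) artifacts removed, and sister samples compared by regression of
  fractional clone sizes.
- **Synthetic paired multiome generator** — every input above with planted
  ground truth (trajectory, TF programs, cis links, KO effects, clone
  offsets, barcode abundances), so the whole pipeline is testable
  end-to-end.

## Worked example

```python
import numpy as np, scipy.stats
from chromclone import *
from chromclone.synthdata import SimConfig, simulate_multiome

cfg = SimConfig(n_cells=800, n_peaks=1500, n_genes=150, dorc_genes=20,
                peaks_per_dorc=5, depth_mean=4000.0, seed=0)
atac, rna, peaks, motifs, tss, truth = simulate_multiome(cfg)

bg = match_backgrounds(peaks, n_background=100, seed=0)
dev = compute_deviations(atac, motifs, bg,
                         annotation_names=list(truth.tf_activity.index))
links = link_peaks_to_genes(atac, rna, peaks, tss, bg, n_perm=100)
dorcs = call_dorcs(links)
print(f"retained peak-gene links: {len(links)}")
print(f"DORC genes (>=3 linked peaks): {len(dorcs)}")

pb = pseudobulk(atac)
res = nb_wald_test(pb)
print(f"differential peaks at FDR<=0.01: up={len(res.up)} down={len(res.down)}")
```

prints

```
retained peak-gene links: 66
DORC genes (>=3 linked peaks): 16
differential peaks at FDR<=0.01: up=99 down=10
```

The 66 retained links are the (gene, in-window peak) pairs whose
accessibility-expression correlation beats the matched-background null at
P ≤ 0.05; 16 of the 20 planted DORC genes reach the ≥ 3-peak threshold at
this reduced scale. The 99 up peaks recover 99% of the 100 planted
KO-responsive peaks (the generator plants a +1 log2 genotype effect);
the 10 down calls are the false-positive cost of the 1% FDR over 1,400
null peaks. On the same data the stem-program motif's deviation Z tracks
its planted activity at Spearman r = 0.96.

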