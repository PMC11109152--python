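"""Co-accessible peak modules from TF motif deviations.

Pipeline: deduplicate redundant motifs (single-linkage on match-profile
correlation), select significantly variable motifs by jackstraw PCA on the
deviation Z matrix, split cells at the median Z per TF and t-test every peak
between the high and low halves, then cluster the significant peaks'
fold-change profiles across TFs into modules with Louvain communities on a
mutual kNN graph.  The resulting binary peak x module annotation matrix is
directly scoreable with ``compute_deviations``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModuleResult",
    "dedup_motifs",
    "jackstraw_variable_motifs",
    "tf_peak_association",
    "cluster_peak_modules",
]


def dedup_motifs(
    motif_profiles: pd.DataFrame,
    cutoff: float = 0.8,
    variability: pd.Series | None = None,
) -> list[str]:
    """Collapse near-identical motifs to one representative each.

    Single-linkage clusters over |pairwise Pearson correlation| >= ``cutoff``
    of the motif columns of ``motif_profiles`` (units x motifs, e.g. the
    peaks x motifs match matrix); within a cluster the motif with the highest
    ``variability`` (e.g. deviation-Z variance; column variance if omitted)
    is kept.  Constant columns have undefined correlation and form their own
    clusters.
    """
    motifs = list(motif_profiles.columns)
    if len(motifs) < 2:
        return motifs
    M = motif_profiles.to_numpy(float)
    sd = M.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.corrcoef(M, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)  # constant columns: no similarity edges
    adj = np.abs(C) >= cutoff
    adj[sd == 0, :] = False
    adj[:, sd == 0] = False
    np.fill_diagonal(adj, True)

    n_comp, labels = sp.csgraph.connected_components(sp.csr_matrix(adj), directed=False)
    if variability is None:
        var = pd.Series(M.var(axis=0), index=motifs)
    else:
        var = variability.reindex(motifs)
    reps = []
    for c in range(n_comp):
        members = [m for m, l in zip(motifs, labels) if l == c]
        reps.append(var.loc[members].idxmax())
    return sorted(reps, key=motifs.index)


def jackstraw_variable_motifs(
    z: pd.DataFrame,
    n_iter: int = 100,
    n_pcs: int = 10,
    p_cut: float = 0.05,
    perm_frac: float = 0.1,
    seed: int = 0,
) -> list[str]:
    """Jackstraw-selected significantly variable motifs.

    PCA is fit on the motifs x cells deviation Z matrix (cells as samples,
    motifs as features).  Per iteration a random ``perm_frac`` of motifs have
    their cell values permuted and PCA is refit; the permuted motifs'
    association statistics — max over the first ``n_pcs`` components of
    squared loading x component variance — are pooled into a null.  A motif
    is selected if its observed statistic has empirical p <= ``p_cut``.
    """
    from sklearn.decomposition import PCA

    X = z.to_numpy(float).T  # cells x motifs
    n_cells, n_motifs = X.shape
    if n_cells < n_pcs:
        raise ValueError("need at least n_pcs cells")
    n_perm = max(int(round(perm_frac * n_motifs)), 1)
    if n_iter * n_perm < 100:
        warnings.warn(
            f"only {n_iter * n_perm} null draws; jackstraw p-values unstable",
            stacklevel=2,
        )

    def stats(mat: np.ndarray) -> np.ndarray:
        pca = PCA(n_components=n_pcs, svd_solver="full" if min(mat.shape) < 500 else "randomized",
                  random_state=0)
        pca.fit(mat)
        # squared loading weighted by component variance, max over components
        load2 = pca.components_**2 * pca.explained_variance_[:, None]
        return load2.max(axis=0)

    obs = stats(X)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter * n_perm)
    for it in range(n_iter):
        sel = rng.choice(n_motifs, size=n_perm, replace=False)
        Xp = X.copy()
        for j in sel:
            Xp[:, j] = Xp[rng.permutation(n_cells), j]
        s = stats(Xp)
        null[it * n_perm : (it + 1) * n_perm] = s[sel]

    null.sort()
    # empirical p with add-one rule
    exceed = len(null) - np.searchsorted(null, obs, side="left")
    pvals = (1.0 + exceed) / (1.0 + len(null))
    return [m for m, p in zip(z.index, pvals) if p <= p_cut]


def tf_peak_association(
    atac_norm: np.ndarray,
    z_tf: np.ndarray,
    fdr_cut: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Peaks associated with one TF's activity.

    Cells are split at the median of ``z_tf`` (high: z > median); each peak's
    values in ``atac_norm`` (peaks x cells, depth-normalised then
    mean-centred per cell) are compared between halves with a two-tailed
    Welch t-test, BH-corrected across peaks.  Returns (significant peak
    indices, per-peak fold-change = mean(high) - mean(low), FDR values).
    """
    z_tf = np.asarray(z_tf, float)
    med = np.median(z_tf)
    high = z_tf > med
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("median split leaves a group with < 2 cells")
    A, B = atac_norm[:, high], atac_norm[:, ~high]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = scipy.stats.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.where(np.isfinite(t.pvalue), t.pvalue, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    fc = A.mean(axis=1) - B.mean(axis=1)
    sig = np.flatnonzero(fdr <= fdr_cut)
    return sig, fc, fdr


@dataclass
class ModuleResult:
    peak_module: pd.Series  # peak index -> module id
    annot_matrix: sp.csr_matrix  # all peaks x modules, binary
    fc_matrix: pd.DataFrame  # significant peaks x TFs
    variable_tfs: list[str]
    singletons: list[int]


def cluster_peak_modules(
    fc_matrix: pd.DataFrame,
    n_total_peaks: int,
    k: int = 30,
    seed: int = 0,
    resolution: float = 1.0,
    variable_tfs: list[str] | None = None,
) -> ModuleResult:
    """Louvain communities on the mutual kNN graph of peak fold-change profiles.

    Rows of ``fc_matrix`` are peaks significant for at least one TF (index =
    peak indices into the full peak set), columns TFs.  The kNN digraph
    (Euclidean) is symmetrised by union, so a tie-broken asymmetric neighbour
    pair still yields an edge; isolated peaks become singleton modules and
    are flagged.
    """
    import igraph
    import random as _random

    peaks = fc_matrix.index.to_numpy()
    n = len(peaks)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} peaks, got {n}")
    from .differential import _knn_indices

    nbr = _knn_indices(fc_matrix.to_numpy(float), k)
    edges = sorted(
        {(min(i, j), max(i, j)) for i in range(n) for j in nbr[i]}
    )
    g = igraph.Graph(n=n, edges=edges)
    igraph.set_random_number_generator(_random.Random(seed))
    part = g.community_multilevel(resolution=resolution)
    labels = np.asarray(part.membership)

    singles = [int(peaks[i]) for i in range(n) if g.degree(i) == 0]
    if singles:
        warnings.warn(
            f"{len(singles)} peaks had no mutual-kNN edge; kept as singleton modules",
            stacklevel=2,
        )
    peak_module = pd.Series(labels, index=peaks, name="module")
    n_mod = int(labels.max()) + 1
    annot = sp.csr_matrix(
        (np.ones(n), (peaks, labels)), shape=(n_total_peaks, n_mod)
    )
    return ModuleResult(
        peak_module=peak_module,
        annot_matrix=annot,
        fc_matrix=fc_matrix,
        variable_tfs=variable_tfs or list(fc_matrix.columns),
        singletons=singles,
    )
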