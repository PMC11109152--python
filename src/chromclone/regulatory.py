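"""Peak-gene cis-regulatory links, DORCs, per-cell DORC scores and residuals.

A gene's candidate regulatory peaks are those whose centre lies within a
fixed window of its TSS (10 kb by default).  Each candidate is scored by the
correlation between peak accessibility and the gene's expression across
paired cells, and tested against an empirical null built from GC- and
accessibility-matched background peaks.  Genes with at least ``min_peaks``
retained links form domains of regulatory chromatin (DORCs), which are then
scored per cell as depth-normalised summed accessibility over the linked
peaks; the accessibility-expression residual quantifies chromatin state
running ahead of (or behind) transcription.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .activity import BackgroundSets, DeviationResult
from .io_peaks import CellCountMatrix, PeakSet

__all__ = [
    "PeakGeneLink",
    "link_peaks_to_genes",
    "call_dorcs",
    "dorc_scores",
    "dorc_residuals",
    "knn_smooth",
    "tf_dorc_regulation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakGeneLink:
    gene: str
    peak: int
    r_obs: float
    p_perm: float
    distance: int


def _rank_standardize(M: np.ndarray) -> np.ndarray:
    """Row-wise ranks standardised to zero mean, unit norm (for fast Spearman)."""
    R = scipy.stats.rankdata(M, axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(R, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(nrm > 0, R / nrm, 0.0)


def _center_standardize(M: np.ndarray) -> np.ndarray:
    C = M - M.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(C, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(nrm > 0, C / nrm, 0.0)


def knn_smooth(values: np.ndarray, embedding: np.ndarray, k: int = 30) -> np.ndarray:
    """Average each cell's column of ``values`` (features x cells) over its k
    nearest cells in ``embedding`` (self included)."""
    from .differential import _knn_indices

    if k <= 1:
        return values.copy()
    nbr = _knn_indices(embedding, k - 1)  # excludes self
    out = np.empty_like(values, dtype=float)
    for i in range(values.shape[1]):
        cols = np.concatenate([[i], nbr[i]])
        out[:, i] = values[:, cols].mean(axis=1)
    return out


def link_peaks_to_genes(
    atac: CellCountMatrix,
    rna: CellCountMatrix,
    peaks: PeakSet,
    tss: pd.DataFrame,
    bg: BackgroundSets,
    window: int = 10_000,
    n_perm: int = 100,
    method: str = "spearman",
    embedding: np.ndarray | None = None,
    smooth_k: int = 30,
    return_candidates: bool = False,
):
    """Correlate in-window peak accessibility with paired gene expression.

    For each (gene, peak-within-``window``-of-TSS) pair the observed
    correlation r_obs across cells is compared with correlations of the
    peak's ``n_perm`` matched background draws against the same gene;
    p_perm = (1 + #{r_bg >= r_obs}) / (1 + n_perm) (add-one rule, never 0).
    Links with r_obs > 0 and p_perm <= 0.05 are retained.  Accessibility is
    depth-normalised and optionally kNN-smoothed in ``embedding`` first.

    With ``return_candidates=True``, also returns a DataFrame of every tested
    (gene, peak) pair with its r_obs, p_perm and retained flag.
    """
    if not atac.cell_ids.equals(rna.cell_ids):
        raise ValueError("atac and rna must share identical cell ids (paired)")
    if method not in {"spearman", "pearson"}:
        raise ValueError("method must be 'spearman' or 'pearson'")

    acc = atac.depth_normalized()
    if embedding is not None:
        acc = knn_smooth(acc, embedding, k=smooth_k)
    expr = rna.depth_normalized()

    standardize = _rank_standardize if method == "spearman" else _center_standardize
    accS = standardize(acc)
    centers = peaks.centers
    chroms = peaks.df["chrom"].to_numpy()

    n_bg = bg.draws.shape[1]
    if n_perm > n_bg:
        raise ValueError(f"n_perm={n_perm} exceeds available background draws {n_bg}")

    links: list[PeakGeneLink] = []
    cand_rows: list[tuple] = []
    gene_index = {g: j for j, g in enumerate(rna.feature_ids)}
    for gene, row in tss.iterrows():
        gj = gene_index.get(gene)
        if gj is None:
            log.info("gene %s absent from rna; skipped", gene)
            continue
        on_chrom = chroms == str(row["chrom"])
        dist = centers - int(row["tss"])
        cand = np.flatnonzero(on_chrom & (np.abs(dist) <= window))
        if cand.size == 0:
            continue
        e = standardize(expr[gj][None, :])[0]
        if not e.any():
            continue  # constant expression: correlation undefined
        r_obs = accS[cand] @ e
        for pk, r in zip(cand, r_obs):
            if not accS[pk].any():
                continue  # constant accessibility
            r_bg = accS[bg.draws[pk, :n_perm]] @ e
            p = (1.0 + float(np.sum(r_bg >= r))) / (1.0 + n_perm)
            retained = r > 0 and p <= 0.05
            cand_rows.append((str(gene), int(pk), float(r), float(p), retained))
            if retained:
                links.append(
                    PeakGeneLink(
                        gene=str(gene),
                        peak=int(pk),
                        r_obs=float(r),
                        p_perm=float(p),
                        distance=int(dist[pk]),
                    )
                )
    if return_candidates:
        cands = pd.DataFrame(
            cand_rows, columns=["gene", "peak", "r_obs", "p_perm", "retained"]
        )
        return links, cands
    return links


def call_dorcs(links: list[PeakGeneLink], min_peaks: int = 3) -> pd.DataFrame:
    """Group retained links by gene; keep genes with >= ``min_peaks`` linked
    peaks (domains of regulatory chromatin), ranked by peak count descending."""
    if not links:
        return pd.DataFrame(columns=["gene", "n_peaks", "peaks"]).set_index("gene")
    df = pd.DataFrame([(l.gene, l.peak) for l in links], columns=["gene", "peak"])
    grouped = df.groupby("gene")["peak"].agg(list)
    table = pd.DataFrame(
        {"n_peaks": grouped.map(len), "peaks": grouped}
    )
    table = table[table["n_peaks"] >= min_peaks]
    return table.sort_values("n_peaks", ascending=False, kind="mergesort")


def dorc_scores(
    atac: CellCountMatrix,
    dorcs: pd.DataFrame,
    embedding: np.ndarray | None = None,
    smooth_k: int = 30,
) -> pd.DataFrame:
    """Per-cell DORC accessibility: summed counts over linked peaks, scaled by
    median total / cell total.  Optional kNN smoothing over ``embedding``
    (``smooth_k`` includes self; k=1 is the identity).  Zero-depth cells are
    masked as NaN."""
    T = atac.cell_totals().astype(float)
    med = float(np.median(T[T > 0])) if (T > 0).any() else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(T > 0, med / T, np.nan)
    rows = []
    for gene, row in dorcs.iterrows():
        idx = np.asarray(row["peaks"], dtype=int)
        raw = np.asarray(atac.values[idx].sum(axis=0)).ravel()
        rows.append(raw * scale)
    scores = np.asarray(rows, dtype=float)
    if embedding is not None and smooth_k > 1:
        scores = knn_smooth(scores, embedding, k=smooth_k)
    return pd.DataFrame(scores, index=dorcs.index, columns=atac.cell_ids)


def dorc_residuals(scores: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Row-z-scored accessibility minus row-z-scored expression per DORC gene.

    Positive residuals mark cells whose chromatin is open ahead of the gene's
    transcription ("priming"); ``expr`` rows are matched to ``scores`` genes.
    """
    common = scores.index.intersection(expr.index)
    s = scores.loc[common].to_numpy(float)
    e = expr.loc[common].to_numpy(float)

    def zrow(M):
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, ddof=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sd > 0, (M - mu) / sd, 0.0)

    return pd.DataFrame(zrow(s) - zrow(e), index=common, columns=scores.columns)


def tf_dorc_regulation(
    motif_z: DeviationResult | pd.DataFrame,
    dorc_scores_df: pd.DataFrame,
    tf_to_gene: dict[str, str],
    min_abs_r: float = 0.1,
) -> pd.DataFrame:
    """Classify TFs as activators or repressors of their cognate DORC.

    For each TF whose cognate gene has a DORC, r is the Pearson correlation
    across units (cells, or clone-aggregated profiles) between the TF's motif
    deviation Z and the cognate DORC score; r > 0 marks an activator,
    r < 0 a repressor.  TFs with |r| < ``min_abs_r`` are flagged as weak.
    """
    z = motif_z.z if isinstance(motif_z, DeviationResult) else motif_z
    if not z.columns.equals(dorc_scores_df.columns):
        common = z.columns.intersection(dorc_scores_df.columns)
        if len(common) == 0:
            raise ValueError("no shared units between motif Z and DORC scores")
        z = z[common]
        dorc_scores_df = dorc_scores_df[common]
    rows = []
    for tf, gene in tf_to_gene.items():
        if tf not in z.index or gene not in dorc_scores_df.index:
            continue
        a = z.loc[tf].to_numpy(float)
        b = dorc_scores_df.loc[gene].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
            warnings.warn(f"correlation undefined for TF {tf}; skipped", stacklevel=2)
            continue
        r = float(np.corrcoef(a[ok], b[ok])[0, 1])
        rows.append(
            {
                "tf": tf,
                "gene": gene,
                "r": r,
                "class": "activator" if r > 0 else "repressor",
                "weak": abs(r) < min_abs_r,
            }
        )
    return pd.DataFrame(rows, columns=["tf", "gene", "r", "class", "weak"])
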