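"""Per-cell gene activity scores and bias-corrected deviation Z-scores.

Gene activity aggregates peak accessibility around each gene's TSS with
exponentially decaying distance weights.  Deviation Z-scores measure, per cell
and per peak annotation (TF motif, differential signature, co-accessibility
module), how the annotation's aggregate accessibility departs from the
expectation given the cell's total accessibility, normalised against GC- and
accessibility-matched background peak sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_peaks import CellCountMatrix, PeakSet

__all__ = [
    "GeneActivityParams",
    "BackgroundSets",
    "DeviationResult",
    "activity_window_fullwidth",
    "gene_activity",
    "match_backgrounds",
    "compute_deviations",
]


def activity_window_fullwidth(decay_bp: float = 1000.0, tail: float = 0.01) -> int:
    """Full width of the TSS aggregation window.

    The half-width is the distance at which the one-sided exponential tail
    (e-folding length ``decay_bp``) holds fraction ``tail`` of the total
    weight: ``ceil(decay_bp * ln(1/tail))``.  Defaults give 9,212 bp.
    """
    return 2 * math.ceil(decay_bp * math.log(1.0 / tail))


@dataclass
class GeneActivityParams:
    """Parameters of the exponential-decay gene activity score.

    ``decay_bp`` is the e-folding length of the distance weight.  With the
    default 1 kb decay and a 1% tail the window is 9,212 bp.  Set
    ``halflife_base2=True`` to interpret ``decay_bp`` as a base-2 half-life
    instead (weight = 2^(-d/decay)).
    """

    tss_table: pd.DataFrame  # index gene, columns chrom, tss[, strand]
    decay_bp: float = 1000.0
    window_fullwidth: int | None = None
    halflife_base2: bool = False
    normalize_over_scored_only: bool = True

    def __post_init__(self) -> None:
        if self.window_fullwidth is None:
            self.window_fullwidth = activity_window_fullwidth(self.decay_bp)


def gene_activity(
    atac: CellCountMatrix, peaks: PeakSet, params: GeneActivityParams
) -> pd.DataFrame:
    """Gene x cell activity scores from peak accessibility.

    score(g, i) = sum over in-window peaks p of w(|center(p) - tss(g)|) * c(p, i)
    with w(d) = exp(-d / decay) and window half-width ``window_fullwidth / 2``;
    each cell's scores are then divided by that cell's mean score over genes
    having at least one in-window peak.  Distances are peak-centre to TSS,
    strand-independent.  Genes without any in-window peak score 0 and are
    flagged in the ``no_peak`` attribute of the result.
    """
    tss = params.tss_table
    half = params.window_fullwidth / 2.0
    centers = peaks.centers
    chroms = peaks.df["chrom"].to_numpy()

    # weight matrix genes x peaks, sparse
    rows, cols, w = [], [], []
    by_chrom: dict[str, np.ndarray] = {}
    order: dict[str, np.ndarray] = {}
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        srt = np.argsort(centers[idx], kind="stable")
        by_chrom[c] = idx[srt]
        order[c] = centers[idx[srt]]
    for gi, (gene, row) in enumerate(tss.iterrows()):
        c = str(row["chrom"])
        if c not in by_chrom:
            continue
        pos = float(row["tss"])
        cent = order[c]
        lo = np.searchsorted(cent, pos - half, side="left")
        hi = np.searchsorted(cent, pos + half, side="right")
        if hi <= lo:
            continue
        pidx = by_chrom[c][lo:hi]
        d = np.abs(cent[lo:hi] - pos)
        if params.halflife_base2:
            wt = np.power(2.0, -d / params.decay_bp)
        else:
            wt = np.exp(-d / params.decay_bp)
        rows.extend([gi] * len(pidx))
        cols.extend(pidx.tolist())
        w.extend(wt.tolist())

    W = sp.csr_matrix(
        (w, (rows, cols)), shape=(len(tss), len(peaks)), dtype=np.float64
    )
    scores = np.asarray((W @ atac.values).todense(), dtype=np.float64)
    scored = np.asarray(W.sum(axis=1)).ravel() > 0

    norm_rows = scored if params.normalize_over_scored_only else np.ones(len(tss), bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        cell_mean = scores[norm_rows].mean(axis=0)
        out = np.where(cell_mean > 0, scores / cell_mean[None, :], 0.0)
    result = pd.DataFrame(out, index=tss.index, columns=atac.cell_ids)
    result.attrs["no_peak"] = tss.index[~scored].tolist()
    result.attrs["raw"] = pd.DataFrame(scores, index=tss.index, columns=atac.cell_ids)
    return result


# ---------------------------------------------------------------------------
# GC / accessibility matched background peaks
# ---------------------------------------------------------------------------

@dataclass
class BackgroundSets:
    """Per-peak background draws matched on (GC, log mean accessibility).

    ``draws`` is an integer array of shape (n_peaks, n_background); a peak never
    draws itself.
    """

    draws: np.ndarray
    pools: np.ndarray = field(repr=False, default=None)  # (n_peaks, k_pool)

    @property
    def n_background(self) -> int:
        return self.draws.shape[1]


def match_backgrounds(
    peaks: PeakSet,
    n_background: int = 100,
    k_pool: int = 50,
    seed: int = 0,
) -> BackgroundSets:
    """Sample matched background peaks for each peak.

    (gc, log1p(mean_access)) are standardised to zero mean / unit variance;
    each peak's ``n_background`` draws are taken with replacement from its
    ``k_pool`` nearest neighbours in that plane (Euclidean, self excluded).
    """
    gc = peaks.df["gc"].to_numpy(float)
    acc = peaks.df["mean_access"].to_numpy(float)
    if np.isnan(gc).any() or np.isnan(acc).any():
        raise ValueError("match_backgrounds requires gc and mean_access populated")
    n = len(peaks)
    if n < k_pool + 1:
        warnings.warn(
            f"only {n} peaks; background pool shrunk to {n - 1}", stacklevel=2
        )
        k_pool = n - 1
    X = np.column_stack([gc, np.log1p(acc)])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k_pool + 1).fit(Xs)
    _, ind = nn.kneighbors(Xs)
    # drop self (which may be displaced by an identical point); keep k_pool
    pools = np.empty((n, k_pool), dtype=np.int64)
    for i in range(n):
        row = ind[i][ind[i] != i]
        pools[i] = row[:k_pool]
    rng = np.random.default_rng(seed)
    choice = rng.integers(0, k_pool, size=(n, n_background))
    draws = pools[np.arange(n)[:, None], choice]
    return BackgroundSets(draws=draws, pools=pools)


# ---------------------------------------------------------------------------
# Deviations
# ---------------------------------------------------------------------------

@dataclass
class DeviationResult:
    """Raw, bias-corrected and Z-scored deviations (annotations x cells)."""

    raw_dev: pd.DataFrame
    corrected_dev: pd.DataFrame
    z: pd.DataFrame
    n_background: int
    masked: pd.DataFrame | None = None  # boolean, True where undefined


def _dev(annot: sp.csr_matrix, counts: sp.csr_matrix, peak_totals, grand, T):
    """Raw deviation matrix for one peak->row mapping. annot: peaks x annots."""
    X = np.asarray((annot.T @ counts).todense(), dtype=float)  # annots x cells
    fA = (annot.T @ peak_totals) / grand  # annots
    E = fA[:, None] * T[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = (X - E) / E
    return dev, E


def compute_deviations(
    atac: CellCountMatrix,
    annot: sp.spmatrix | np.ndarray,
    bg: BackgroundSets,
    annotation_names: list[str] | None = None,
) -> DeviationResult:
    """chromVAR-style deviation Z-scores for arbitrary binary peak annotations.

    For annotation A and cell i the observed aggregate count X is compared to
    the expectation E = f_A * T_i (f_A the annotation's share of all reads,
    T_i the cell total): raw_dev = (X - E) / E.  Each background iteration
    replaces every annotation peak with its matched background draw and the
    deviation is recomputed; z = (raw_dev - mean_b) / sd_b and the
    bias-corrected deviation raw_dev - mean_b are both returned.  Cells or
    annotations with zero expectation are masked.
    """
    A = sp.csr_matrix(annot)
    if A.shape[0] != atac.n_features:
        raise ValueError("annotation rows must align with peaks")
    counts = atac.values.astype(np.float64)
    T = atac.cell_totals().astype(float)
    peak_totals = atac.feature_totals().astype(float)
    grand = float(peak_totals.sum())

    raw, E = _dev(A, counts, peak_totals, grand, T)
    nb = bg.n_background
    bg_devs = np.empty((nb,) + raw.shape, dtype=np.float64)
    n_peaks = A.shape[0]
    for b in range(nb):
        perm = bg.draws[:, b]
        # rows of A scattered to background peaks: B[q, a] = sum_{p: perm[p]=q} A[p, a]
        P = sp.csr_matrix(
            (np.ones(n_peaks), (perm, np.arange(n_peaks))), shape=(n_peaks, n_peaks)
        )
        Ab = P @ A
        bg_devs[b], _ = _dev(Ab, counts, peak_totals, grand, T)

    mean_b = bg_devs.mean(axis=0)
    sd_b = bg_devs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = raw - mean_b
        z = corrected / sd_b

    masked = ~np.isfinite(raw) | ~np.isfinite(z)
    if masked.any():
        warnings.warn(
            f"{int(masked.sum())} deviation entries undefined (zero expectation "
            "or zero background sd); masked as NaN",
            stacklevel=2,
        )
    raw[~np.isfinite(raw)] = np.nan
    z[~np.isfinite(z)] = np.nan
    corrected[~np.isfinite(corrected)] = np.nan

    names = annotation_names or [f"annot_{j}" for j in range(A.shape[1])]
    cols = atac.cell_ids
    return DeviationResult(
        raw_dev=pd.DataFrame(raw, index=names, columns=cols),
        corrected_dev=pd.DataFrame(corrected, index=names, columns=cols),
        z=pd.DataFrame(z, index=names, columns=cols),
        n_background=nb,
        masked=pd.DataFrame(masked, index=names, columns=cols),
    )
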