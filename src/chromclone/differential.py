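"""Pseudobulk differential accessibility, DORC differential testing, and
neighbourhood localisation.

Differential accessibility follows the pseudobulk replicate design: raw
counts are summed per (sample, cell type, genotype) group, size factors are
estimated by median-of-ratios, and each peak is fit with a negative-binomial
GLM (log link, genotype + cell type design) whose genotype coefficient is
Wald-tested against zero.  Per-peak dispersions are maximum-likelihood
estimates with a moment initialisation — no empirical-Bayes shrinkage; at
pseudobulk depths the Wald statistic is the operative quantity and a
shrinkage hook is left in the interface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io_peaks import CellCountMatrix

__all__ = [
    "PseudobulkMatrix",
    "DiffPeakResult",
    "pseudobulk",
    "size_factors_median_of_ratios",
    "nb_wald_test",
    "wilcoxon_dorc_diff",
    "neighborhood_fraction",
    "pca_embedding",
]

log = logging.getLogger(__name__)


@dataclass
class PseudobulkMatrix:
    """Peaks x groups integer sums with group-level metadata and size factors."""

    counts: pd.DataFrame  # peaks x groups, integer
    group_meta: pd.DataFrame  # index groups; columns e.g. sample, celltype, genotype
    size_factors: pd.Series | None = None


def pseudobulk(
    atac: CellCountMatrix,
    groupby: tuple[str, ...] = ("sample", "celltype", "genotype"),
    min_cells: int = 10,
) -> PseudobulkMatrix:
    """Sum raw counts per metadata group; groups smaller than ``min_cells``
    are dropped with a warning."""
    meta = atac.cell_meta
    missing_cols = [c for c in groupby if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"cell_meta lacks columns {missing_cols}")
    bad = meta[list(groupby)].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"missing group metadata for cells: {list(meta.index[bad][:10])}"
        )
    keys = meta[list(groupby)].astype(str).agg("|".join, axis=1)
    cols, metas = {}, []
    for key, idx in keys.groupby(keys).groups.items():
        pos = meta.index.get_indexer(idx)
        if len(pos) < min_cells:
            warnings.warn(
                f"pseudobulk group {key!r} has {len(pos)} < {min_cells} cells; dropped",
                stacklevel=2,
            )
            continue
        cols[key] = np.asarray(atac.values[:, pos].sum(axis=1)).ravel().astype(np.int64)
        metas.append(
            dict(zip(groupby, key.split("|"))) | {"group": key, "n_cells": len(pos)}
        )
    counts = pd.DataFrame(cols, index=atac.feature_ids)
    gm = pd.DataFrame(metas).set_index("group") if metas else pd.DataFrame()
    return PseudobulkMatrix(counts=counts, group_meta=gm)


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the per-peak geometric mean
    (peaks with any zero excluded), rescaled to geometric mean 1."""
    M = counts.to_numpy(float)
    with np.errstate(divide="ignore"):
        logM = np.where(M > 0, np.log(M), np.nan)
    ok = ~np.isnan(logM).any(axis=1)
    if ok.sum() == 0:
        raise ValueError("no peak has all-positive counts; cannot estimate size factors")
    loggeo = logM[ok].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logM[ok] - loggeo, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


@dataclass
class DiffPeakResult:
    table: pd.DataFrame  # per peak: log2fc, se, wald_p, fdr, direction, converged
    fdr_cut: float

    @property
    def up(self) -> pd.Index:
        t = self.table
        return t.index[(t["fdr"] <= self.fdr_cut) & (t["log2fc"] > 0)]

    @property
    def down(self) -> pd.Index:
        t = self.table
        return t.index[(t["fdr"] <= self.fdr_cut) & (t["log2fc"] < 0)]


def _nb_negloglik(log_alpha: float, y: np.ndarray, mu: np.ndarray) -> float:
    a = np.exp(log_alpha)
    r = 1.0 / a
    return -float(
        np.sum(
            scipy.special.gammaln(y + r)
            - scipy.special.gammaln(r)
            - scipy.special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def nb_wald_test(
    pb: PseudobulkMatrix,
    genotype_col: str = "genotype",
    covariates: tuple[str, ...] = ("celltype",),
    reference: str = "WT",
    fdr_cut: float = 0.01,
    dispersion_floor: float = 1e-8,
    drop_nonconverged_from_fdr: bool = False,
) -> DiffPeakResult:
    """Per-peak negative-binomial Wald test of the genotype effect.

    Size factors enter as offsets (log scale); the design is
    [intercept, genotype, covariate indicators].  Dispersion is estimated per
    peak by maximum likelihood (floored at ``dispersion_floor``) starting from
    a Pearson moment estimate; the Wald statistic beta/SE is referred to the
    standard normal two-sided and BH-adjusted across peaks.
    """
    gm = pb.group_meta
    geno = gm[genotype_col].astype(str)
    levels = sorted(geno.unique())
    if len(levels) < 2:
        raise ValueError(f"need two genotype levels, got {levels}")
    if reference not in levels:
        reference = levels[0]
    alt = [l for l in levels if l != reference]
    if geno.value_counts().min() < 2:
        raise ValueError("fewer than 2 pseudobulk groups in a genotype level")

    if pb.size_factors is None:
        pb.size_factors = size_factors_median_of_ratios(pb.counts)
    offset = np.log(pb.size_factors.loc[pb.counts.columns].to_numpy(float))

    X = pd.DataFrame({"intercept": 1.0}, index=gm.index)
    X["genotype"] = (geno != reference).astype(float)
    for cov in covariates:
        dummies = pd.get_dummies(gm[cov].astype(str), prefix=cov, drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    Xm = X.to_numpy(float)
    Y = pb.counts.to_numpy(float)

    rows = []
    for p in range(Y.shape[0]):
        y = Y[p]
        res = {"log2fc": np.nan, "se": np.nan, "wald_p": np.nan, "converged": False}
        try:
            pois = sm.GLM(
                y, Xm, family=sm.families.Poisson(), offset=offset
            ).fit()
            mu = pois.fittedvalues
            df = max(len(y) - Xm.shape[1], 1)
            alpha = max(
                float(np.sum((y - mu) ** 2 - mu) / np.sum(mu**2)) * len(y) / df,
                dispersion_floor,
            )
            # profile MLE of dispersion given Poisson mu, then refit betas
            for _ in range(2):
                opt = scipy.optimize.minimize_scalar(
                    _nb_negloglik,
                    bounds=(np.log(dispersion_floor), np.log(100.0)),
                    args=(y, np.maximum(mu, 1e-8)),
                    method="bounded",
                )
                alpha = max(float(np.exp(opt.x)), dispersion_floor)
                fit = sm.GLM(
                    y,
                    Xm,
                    family=sm.families.NegativeBinomial(alpha=alpha),
                    offset=offset,
                ).fit()
                mu = fit.fittedvalues
            beta = fit.params[1]
            se = fit.bse[1]
            res.update(
                log2fc=beta / np.log(2.0),
                se=se / np.log(2.0),
                wald_p=2.0 * scipy.stats.norm.sf(abs(beta) / se),
                converged=bool(fit.converged) and np.isfinite(se) and se > 0,
            )
        except Exception as exc:  # noqa: BLE001 - flag peak, keep going
            log.debug("peak %d failed: %s", p, exc)
        rows.append(res)

    table = pd.DataFrame(rows, index=pb.counts.index)
    testable = table["converged"] & table["wald_p"].notna()
    table["fdr"] = np.nan
    if drop_nonconverged_from_fdr:
        sel = testable
    else:
        sel = table["wald_p"].notna()
    if sel.any():
        table.loc[sel, "fdr"] = multipletests(
            table.loc[sel, "wald_p"], method="fdr_bh"
        )[1]
    table["direction"] = np.where(
        (table["fdr"] <= fdr_cut) & (table["log2fc"] > 0),
        "Up",
        np.where((table["fdr"] <= fdr_cut) & (table["log2fc"] < 0), "Down", "ns"),
    )
    table.attrs["contrast"] = f"{alt[0]} vs {reference}"
    return DiffPeakResult(table=table, fdr_cut=fdr_cut)


def wilcoxon_dorc_diff(
    dorc_scores_df: pd.DataFrame,
    genotype: pd.Series,
    celltype: pd.Series,
    reference: str = "WT",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per (DORC, cell type) comparing
    genotypes, BH-adjusted across all tests; effect = difference in mean
    normalised score (alt - reference).  Cell types with a single genotype,
    or all-tied scores, are skipped."""
    genotype = genotype.astype(str)
    rows = []
    for ct in sorted(celltype.astype(str).unique()):
        in_ct = (celltype.astype(str) == ct).to_numpy()
        g = genotype.to_numpy()[in_ct]
        if len(np.unique(g)) < 2:
            log.info("celltype %s has one genotype; skipped", ct)
            continue
        is_ref = g == reference
        for gene in dorc_scores_df.index:
            x = dorc_scores_df.loc[gene].to_numpy(float)[in_ct]
            a, b = x[~is_ref], x[is_ref]
            pooled = np.concatenate([a, b])
            if np.all(pooled == pooled[0]):
                continue
            method = "exact" if max(len(a), len(b)) <= 10 else "asymptotic"
            stat = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            rows.append(
                {
                    "dorc": gene,
                    "celltype": ct,
                    "effect": float(a.mean() - b.mean()),
                    "p": float(stat.pvalue),
                }
            )
    out = pd.DataFrame(rows, columns=["dorc", "celltype", "effect", "p"])
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["fdr"] = []
    return out


def _knn_indices(embedding: np.ndarray, k: int, chunk: int = 512) -> np.ndarray:
    """Exact Euclidean kNN (self excluded), distance ties broken by cell index."""
    X = np.asarray(embedding, float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    sq = np.einsum("ij,ij->i", X, X)
    out = np.empty((n, k), dtype=np.int64)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = sq[lo:hi, None] + sq[None, :] - 2.0 * X[lo:hi] @ X.T
        np.maximum(d2, 0.0, out=d2)
        for i in range(lo, hi):
            row = d2[i - lo].copy()
            row[i] = np.inf  # exclude self
            order = np.lexsort((np.arange(n), row))
            out[i] = order[:k]
    return out


def neighborhood_fraction(
    embedding: np.ndarray,
    labels: pd.Series | np.ndarray,
    query_label,
    k: int = 50,
) -> np.ndarray:
    """Per cell, the fraction of its k nearest neighbours (Euclidean,
    self excluded) carrying ``query_label``."""
    labels = np.asarray(labels)
    nbr = _knn_indices(embedding, k)
    is_q = labels == query_label
    return is_q[nbr].mean(axis=1)


def pca_embedding(
    counts: CellCountMatrix | np.ndarray, n_pcs: int = 30
) -> np.ndarray:
    """Cells x n_pcs PCA embedding of depth-normalised log1p counts.

    Component signs follow a deterministic convention: the largest-|loading|
    element of each component is positive.
    """
    from sklearn.decomposition import PCA

    if isinstance(counts, CellCountMatrix):
        M = np.log1p(counts.depth_normalized()).T  # cells x features
    else:
        M = np.asarray(counts, float)
    if n_pcs > min(M.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(data dims)={min(M.shape)}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    Z = pca.fit_transform(M)
    comp = pca.components_
    for j in range(n_pcs):
        i = int(np.argmax(np.abs(comp[j])))
        if comp[j, i] < 0:
            comp[j] *= -1.0
            Z[:, j] *= -1.0
    return Z
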