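"""Core containers, standard-format I/O, QC and reference peak-set construction.

The two workhorse containers are :class:`PeakSet` (a thin wrapper around a
pandas DataFrame of genomic intervals) and :class:`CellCountMatrix` (a sparse
features x cells count matrix with feature/cell annotations).  All genomic
coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "PeakSet",
    "CellCountMatrix",
    "FormatError",
    "read_mtx",
    "write_mtx",
    "qc_filter_rna",
    "build_disjoint_peakset",
    "read_bed",
    "write_bed",
]


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


PEAK_COLUMNS = ["chrom", "start", "end", "summit", "score", "gc", "mean_access"]


@dataclass
class PeakSet:
    """Fixed-width accessibility peaks.

    ``df`` holds one row per peak with columns ``chrom, start, end, summit,
    score, gc, mean_access``.  After :func:`build_disjoint_peakset` all peaks
    are 301 bp wide and pairwise disjoint.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"PeakSet missing columns: {missing}")
        if (self.df["end"] <= self.df["start"]).any():
            raise FormatError("peak intervals must satisfy end > start")
        gc = self.df["gc"].to_numpy(float)
        ok = np.isnan(gc) | ((gc >= 0) & (gc <= 1))
        if not ok.all():
            raise FormatError("gc must lie in [0, 1]")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def centers(self) -> np.ndarray:
        """Integer midpoint of each interval."""
        return ((self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2).astype(
            np.int64
        )

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()


@dataclass
class CellCountMatrix:
    """Sparse nonnegative integer counts, features x cells.

    ``cell_meta`` is indexed by cell id and typically carries ``sample``,
    ``celltype``, ``genotype``, ``clone`` and ``mito_frac`` columns.
    """

    values: sp.csr_matrix
    feature_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.feature_ids = pd.Index(self.feature_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.feature_ids.has_duplicates:
            raise FormatError("duplicate feature ids")
        if self.cell_ids.has_duplicates:
            raise FormatError("duplicate cell ids")
        if self.values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        if len(self.cell_meta) == 0:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        else:
            if not self.cell_meta.index.equals(self.cell_ids):
                self.cell_meta = self.cell_meta.reindex(self.cell_ids)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def feature_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def subset_cells(self, mask_or_ids) -> "CellCountMatrix":
        if isinstance(mask_or_ids, (pd.Index, list)):
            idx = self.cell_ids.get_indexer(mask_or_ids)
            if (idx < 0).any():
                raise KeyError("unknown cell ids in subset")
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        return CellCountMatrix(
            self.values[:, idx],
            self.feature_ids,
            self.cell_ids[idx],
            self.cell_meta.iloc[idx],
        )

    def subset_features(self, mask_or_idx) -> "CellCountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellCountMatrix(
            self.values[idx], self.feature_ids[idx], self.cell_ids, self.cell_meta
        )

    def depth_normalized(self, target: float | None = None) -> np.ndarray:
        """Dense features x cells matrix scaled so each cell sums to ``target``
        (median cell total by default).  Zero-depth cells yield NaN columns."""
        T = self.cell_totals().astype(float)
        if target is None:
            target = float(np.median(T[T > 0])) if (T > 0).any() else 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(T > 0, target / T, np.nan)
        return self.values.toarray() * scale[None, :]


# ---------------------------------------------------------------------------
# MTX triplet I/O
# ---------------------------------------------------------------------------

def write_mtx(ccm: CellCountMatrix, outdir: str | Path, prefix: str = "") -> None:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` (+cell meta)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / f"{prefix}matrix.mtx", ccm.values.astype(np.int64))
    pd.Series(ccm.feature_ids).to_csv(
        outdir / f"{prefix}features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(ccm.cell_ids).to_csv(
        outdir / f"{prefix}barcodes.tsv", sep="\t", index=False, header=False
    )
    if len(ccm.cell_meta.columns):
        ccm.cell_meta.to_csv(outdir / f"{prefix}cells.tsv", sep="\t")


def read_mtx(outdir: str | Path, prefix: str = "") -> CellCountMatrix:
    """Read the triplet written by :func:`write_mtx`; exact round trip."""
    outdir = Path(outdir)
    mat = sp.csr_matrix(scipy.io.mmread(outdir / f"{prefix}matrix.mtx"))
    feats = pd.read_csv(
        outdir / f"{prefix}features.tsv", sep="\t", header=None
    )[0].astype(str)
    cells = pd.read_csv(
        outdir / f"{prefix}barcodes.tsv", sep="\t", header=None
    )[0].astype(str)
    if mat.shape != (len(feats), len(cells)):
        raise FormatError(
            f"MTX header {mat.shape} disagrees with annotations "
            f"({len(feats)} features, {len(cells)} cells)"
        )
    meta_path = outdir / f"{prefix}cells.tsv"
    meta = (
        pd.read_csv(meta_path, sep="\t", index_col=0)
        if meta_path.exists()
        else pd.DataFrame()
    )
    if len(meta):
        meta.index = meta.index.astype(str)
    return CellCountMatrix(mat.astype(np.int64), pd.Index(feats), pd.Index(cells), meta)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """BED6 + GC fraction in column 7 (name=peak index, score, strand='.')."""
    df = peaks.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": [f"peak_{i}" for i in range(len(df))],
            "score": df["score"],
            "strand": ".",
            "gc": df["gc"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> PeakSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "gc"],
    )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "summit": ((df["start"] + df["end"]) // 2).astype(np.int64),
            "score": df["score"].astype(float),
            "gc": df["gc"].astype(float),
            "mean_access": np.nan,
        }
    )
    return PeakSet(out[PEAK_COLUMNS])


# ---------------------------------------------------------------------------
# RNA cell/gene QC
# ---------------------------------------------------------------------------

def qc_filter_rna(
    rna: CellCountMatrix,
    min_features: int = 200,
    min_umi: int = 5000,
    max_mito: float = 0.05,
) -> CellCountMatrix:
    """Standard droplet QC: keep cells with detected features >= ``min_features``,
    total UMIs >= ``min_umi`` and mitochondrial fraction strictly below
    ``max_mito``; then drop genes with zero total UMIs.  Order preserved.
    """
    if "mito_frac" not in rna.cell_meta.columns:
        raise FormatError("qc_filter_rna requires mito_frac in cell_meta")
    n_feat = np.asarray((rna.values > 0).sum(axis=0)).ravel()
    totals = rna.cell_totals()
    mito = rna.cell_meta["mito_frac"].to_numpy(float)
    keep = (n_feat >= min_features) & (totals >= min_umi) & (mito < max_mito)
    if not keep.any():
        warnings.warn("qc_filter_rna removed every cell", stacklevel=2)
    out = rna.subset_cells(keep)
    gene_tot = out.feature_totals()
    return out.subset_features(gene_tot > 0)


# ---------------------------------------------------------------------------
# Disjoint reference peak set from summit calls
# ---------------------------------------------------------------------------

def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    # half-open intervals
    return a_start < b_end and b_start < a_end


def build_disjoint_peakset(
    summits: Sequence[Iterable[tuple]],
    atlas: PeakSet | None = None,
    extend: int = 400,
    final_halfwidth: int = 150,
) -> PeakSet:
    """Build a disjoint fixed-width reference peak set from per-condition summits.

    Each summit ``(chrom, pos, score)`` is extended to a ``2*extend + 1`` bp
    window; pooled windows are ranked by descending significance score and kept
    greedily iff they overlap no previously kept window; atlas peaks (re-centred
    to the same window width) are then appended iff non-overlapping; finally
    every kept window is resized to ``2*final_halfwidth + 1`` bp around its
    summit.  Score ties break on (chrom, pos) so the result is invariant to
    input order.
    """
    rows = []
    for cond in summits:
        for chrom, pos, score in cond:
            if pos < extend:
                raise ValueError(f"summit {chrom}:{pos} closer than {extend} bp to origin")
            rows.append((str(chrom), int(pos), float(score)))
    pool = pd.DataFrame(rows, columns=["chrom", "pos", "score"])
    # descending score; ties by (chrom, pos) ascending for order invariance
    pool = pool.sort_values(
        ["score", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    )

    kept: dict[str, list[tuple[int, int]]] = {}
    kept_rows: list[tuple[str, int, float]] = []

    def try_keep(chrom: str, pos: int, score: float) -> None:
        start, end = pos - extend, pos + extend + 1
        for s, e in kept.get(chrom, ()):
            if _overlaps(start, end, s, e):
                return
        kept.setdefault(chrom, []).append((start, end))
        kept_rows.append((chrom, pos, score))

    for chrom, pos, score in pool.itertuples(index=False):
        try_keep(chrom, pos, score)

    if atlas is not None and len(atlas):
        adf = atlas.df.sort_values(
            ["score", "chrom", "summit"], ascending=[False, True, True], kind="mergesort"
        )
        for row in adf.itertuples(index=False):
            try_keep(str(row.chrom), int(row.summit), float(row.score))

    out = pd.DataFrame(kept_rows, columns=["chrom", "summit", "score"])
    out["start"] = out["summit"] - final_halfwidth
    out["end"] = out["summit"] + final_halfwidth + 1
    if (out["start"] < 0).any():
        raise ValueError("negative coordinate after resizing")
    out["chrom"] = out["chrom"].astype(str)
    out["gc"] = np.nan
    out["mean_access"] = np.nan
    out = out.sort_values(["chrom", "start"], kind="mergesort")
    return PeakSet(out[PEAK_COLUMNS])
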