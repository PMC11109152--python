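"""Clone-level analytics: Functional Perturbation Score, clone-resolved
correlations, and the expressed-barcode clonal abundance pipeline.

The Functional Perturbation Score (FPS) summarises how strongly a clone's
functional phenotype shifts when the mutation is introduced: each assay
column of a paired WT/KO clone table is z-standardised across all rows, and
the score is the Euclidean distance between a clone's standardised WT and KO
profiles.  Barcode counting isolates 28-mer lineage barcodes between known
flanking sequences, enforces the library's constant bases, collapses
sequencing-error variants into abundant centroids by bounded edit distance,
and drops low-frequency artifacts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CloneFunctionTable",
    "PerturbationScores",
    "BarcodeCounts",
    "functional_perturbation_score",
    "correlate_function_with_tf",
    "correlate_score_with_features",
    "extract_barcodes",
    "correct_and_filter",
    "paired_clone_sizes",
]

log = logging.getLogger(__name__)


@dataclass
class CloneFunctionTable:
    """Clones x assays functional readouts with WT/KO pair structure.

    ``values`` is indexed by (clone, condition) with condition in {WT, KO};
    every clone must have exactly one row per condition and no missing
    assay values.
    """

    values: pd.DataFrame
    cytokine_group: pd.Series | None = None  # clone -> e.g. SCF | GM-CSF

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.nlevels != 2:
            raise ValueError("values must be indexed by (clone, condition)")
        conds = idx.get_level_values(1)
        if not set(conds) <= {"WT", "KO"}:
            raise ValueError("condition level must be WT or KO")
        counts = pd.Series(1, index=idx).groupby(level=0).sum()
        per = self.values.groupby(level=[0, 1]).size()
        if (counts != 2).any() or (per != 1).any():
            raise ValueError("every clone needs exactly one WT and one KO row")
        if self.values.isna().any().any():
            raise ValueError("missing assay values")

    @property
    def clones(self) -> list:
        return sorted(self.values.index.get_level_values(0).unique())


@dataclass
class PerturbationScores:
    scores: pd.Series  # clone -> score >= 0
    ranking: pd.Series = field(init=False)  # dense rank, 1 = largest
    dropped_assays: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ranking = self.scores.rank(method="dense", ascending=False).astype(int)


def functional_perturbation_score(
    table: CloneFunctionTable, per_genotype_scale: bool = False
) -> PerturbationScores:
    """Euclidean WT-KO distance in standardised assay space, per clone.

    Each assay column is z-standardised (sample sd, ddof=1) across all rows —
    WT and KO pooled by default, within genotype if ``per_genotype_scale``.
    Constant columns are dropped with a warning; scores are therefore only
    comparable within one call.
    """
    V = table.values.copy()
    if len(V) < 2:
        raise ValueError("need at least 2 rows to standardise")
    dropped = [c for c in V.columns if V[c].std(ddof=1) == 0]
    if dropped:
        warnings.warn(f"constant assay columns dropped: {dropped}", stacklevel=2)
        V = V.drop(columns=dropped)
    if per_genotype_scale:
        Z = V.groupby(level=1, group_keys=False).apply(
            lambda g: (g - g.mean()) / g.std(ddof=1)
        )
    else:
        Z = (V - V.mean()) / V.std(ddof=1)
    wt = Z.xs("WT", level=1)
    ko = Z.xs("KO", level=1).reindex(wt.index)
    d = np.sqrt(((wt - ko) ** 2).sum(axis=1))
    return PerturbationScores(scores=d.rename("fps"), dropped_assays=dropped)


def correlate_function_with_tf(
    clone_assays: pd.DataFrame, clone_tf_z: pd.DataFrame
) -> pd.DataFrame:
    """Assays x TFs Pearson correlation matrix across clones.

    Rows of both inputs are clones (aligned by index); entries with fewer
    than 3 jointly observed clones are masked as NaN.
    """
    common = clone_assays.index.intersection(clone_tf_z.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} shared clones; need >= 3")
    A = clone_assays.loc[common]
    B = clone_tf_z.loc[common]
    out = pd.DataFrame(index=A.columns, columns=B.columns, dtype=float)
    for a in A.columns:
        for t in B.columns:
            x, y = A[a].to_numpy(float), B[t].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            out.loc[a, t] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return out


def correlate_score_with_features(
    scores: PerturbationScores, clone_features: pd.DataFrame
) -> pd.DataFrame:
    """Rank chromatin features by Spearman correlation with the FPS.

    ``clone_features`` is clones x features (e.g. DORC accessibility or
    signature deviations).  Returns a table (feature, r, p, fdr) sorted by r
    descending: top positive features mark a sensitised clone state, top
    negative a de-sensitised one.  All-tied features are masked.
    """
    common = scores.scores.index.intersection(clone_features.index)
    if len(common) < 3:
        raise ValueError("need >= 3 clones shared between scores and features")
    s = scores.scores.loc[common].to_numpy(float)
    rows = []
    for f in clone_features.columns:
        x = clone_features.loc[common, f].to_numpy(float)
        if np.all(x == x[0]):
            rows.append({"feature": f, "r": np.nan, "p": np.nan})
            continue
        r, p = scipy.stats.spearmanr(s, x)
        rows.append({"feature": f, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows).set_index("feature")
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out.sort_values("r", ascending=False, na_position="last")


# ---------------------------------------------------------------------------
# Barcode clonal abundance
# ---------------------------------------------------------------------------

@dataclass
class BarcodeCounts:
    counts: pd.Series  # barcode -> count
    stage: str  # raw | corrected | filtered
    n_reads_total: int = 0
    n_reads_assigned: int = 0


def extract_barcodes(
    reads,
    flank5: str,
    flank3: str,
    constant_positions: dict[int, str] | None = None,
    bc_len: int = 28,
) -> BarcodeCounts:
    """Isolate lineage barcodes between flanking sequences and count them.

    ``reads`` is an iterable of Bio.SeqRecord or plain sequence strings.  For
    each read the first exact occurrence of ``flank5`` is located, the next
    ``bc_len`` bases taken, and an exact ``flank3`` match required directly
    after; reads failing flank location or the library's constant-base
    pattern are discarded.
    """
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    constant_positions = constant_positions or {}
    for pos, base in constant_positions.items():
        if not (0 <= pos < bc_len) or base not in "ACGT":
            raise ValueError(f"invalid constant position {pos}:{base}")
    counts: dict[str, int] = {}
    total = assigned = 0
    for rec in reads:
        seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        total += 1
        i = seq.find(flank5)
        if i < 0:
            continue
        if seq.find(flank5, i + 1) >= 0:
            log.debug("multiple 5' flank hits; first used")
        start = i + len(flank5)
        bc = seq[start : start + bc_len]
        if len(bc) < bc_len:
            continue
        if seq[start + bc_len : start + bc_len + len(flank3)] != flank3:
            continue
        if any(bc[p] != b for p, b in constant_positions.items()):
            continue
        counts[bc] = counts.get(bc, 0) + 1
        assigned += 1
    ser = pd.Series(counts, dtype=np.int64).sort_values(ascending=False)
    return BarcodeCounts(
        counts=ser, stage="raw", n_reads_total=total, n_reads_assigned=assigned
    )


def correct_and_filter(
    raw: BarcodeCounts,
    radius: int = 2,
    merge_ratio: float = 5.0,
    min_count: int = 10,
) -> BarcodeCounts:
    """Collapse sequencing-error barcode variants and drop rare artifacts.

    Barcodes are visited in descending count order (ties lexicographic); each
    is merged into the most abundant already-kept barcode within Levenshtein
    distance <= ``radius`` whose count is >= ``merge_ratio`` times its own,
    transferring its count.  Survivors with count < ``min_count`` are then
    removed.  Total assigned reads are conserved by the merge step.
    """
    if raw.stage != "raw":
        raise ValueError("correct_and_filter expects raw-stage counts")
    items = sorted(raw.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept: list[str] = []
    kept_counts: dict[str, int] = {}
    for bc, cnt in items:
        target = None
        for cand in kept:  # kept is in descending original-count order
            if kept_counts[cand] >= merge_ratio * cnt and (
                edlib.align(bc, cand, task="distance", k=radius)["editDistance"] != -1
            ):
                target = cand
                break
        if target is None:
            kept.append(bc)
            kept_counts[bc] = cnt
        else:
            kept_counts[target] += cnt
    corrected = pd.Series(kept_counts, dtype=np.int64).sort_values(ascending=False)
    filtered = corrected[corrected >= min_count]
    return BarcodeCounts(
        counts=filtered,
        stage="filtered",
        n_reads_total=raw.n_reads_total,
        n_reads_assigned=int(corrected.sum()),
    )


def paired_clone_sizes(
    sample_a: BarcodeCounts, sample_b: BarcodeCounts
) -> tuple[pd.DataFrame, float, float]:
    """Compare clonal abundances between sister samples.

    Counts are converted to fractional abundances per sample and inner-joined
    on barcode; returns (table, OLS slope, intercept) of B's fractions
    regressed on A's.  The table carries a ``residual`` column (above the
    regression line = expanded in B) and unmatched barcodes flagged in
    ``only_in`` attr.
    """
    if sample_a.stage != "filtered" or sample_b.stage != "filtered":
        raise ValueError("paired_clone_sizes expects filtered-stage counts")
    fa = sample_a.counts / sample_a.counts.sum()
    fb = sample_b.counts / sample_b.counts.sum()
    common = fa.index.intersection(fb.index)
    if len(common) == 0:
        raise ValueError("no shared barcodes between samples")
    table = pd.DataFrame({"frac_a": fa.loc[common], "frac_b": fb.loc[common]})
    fit = scipy.stats.linregress(table["frac_a"], table["frac_b"])
    table["residual"] = table["frac_b"] - (fit.intercept + fit.slope * table["frac_a"])
    table.attrs["only_in"] = {
        "a": fa.index.difference(fb.index).tolist(),
        "b": fb.index.difference(fa.index).tolist(),
    }
    return table, float(fit.slope), float(fit.intercept)
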