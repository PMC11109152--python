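"""Synthetic paired multiome generator with planted ground truth.

Emulates the statistical structure of a bifurcating myeloid differentiation
experiment read out by paired single-cell ATAC + RNA: cells sit on a
stem -> monocytic / neutrophilic trajectory; a handful of TF activity
programs vary along it and are carried by motif-bearing peaks; designated
genes have >= 3 correlated cis peaks within 10 kb of their TSS (with
chromatin optionally leading expression by a pseudotime lag); a genotype
(KO) effect multiplies a planted peak subset; clones carry small heritable
chromatin offsets.  Counts follow a negative-binomial (Gamma-Poisson)
observation model with a shared dispersion and per-cell depths.  Everything
downstream of the generator can therefore be tested against known truth.

The generator's companion functions produce paired WT/KO clone functional
assay tables with planted perturbation magnitudes, and lineage-barcode
sequencing reads with substitution errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .clonal import CloneFunctionTable
from .io_peaks import CellCountMatrix, PeakSet, PEAK_COLUMNS

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_multiome",
    "simulate_clone_function",
    "simulate_barcode_reads",
    "DEFAULT_CONSTANT_POSITIONS",
    "DEFAULT_FLANK5",
    "DEFAULT_FLANK3",
    "write_simulation",
]

# amplitude of the planted TF activity programs (natural-log units on peak rates)
PROGRAM_AMPLITUDE = 1.5
# sd of per-peak log baseline accessibility; real ATAC peak means span orders
# of magnitude, and this spread is what makes accessibility-matched background
# pools representative of the whole atlas rather than of the planted programs
BASELINE_LOG_SD = 1.0
# intergenic carrier peaks per TF program
CARRIERS_PER_MOTIF = 60
# sd of per-cell activity noise around the program shape
ACTIVITY_NOISE_SD = 0.1
# Bernoulli rate of spurious motif-peak matches outside carrier peaks
MOTIF_BACKGROUND_RATE = 0.02
# lognormal sigma of per-cell sequencing depth around depth_mean
DEPTH_LOGNORM_SIGMA = 0.3

ASSAY_NAMES = [
    "Ly6G",
    "CD115",
    "CD11b",
    "IL6",
    "ROS",
    "phago_ecoli",
    "phago_saureus",
    "proliferation",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic paired multiome."""

    n_cells: int = 2000
    n_peaks: int = 4000
    n_genes: int = 300
    n_motifs: int = 12
    n_clones: int = 8
    frac_ko: float = 0.5
    n_samples: int = 8
    traj_branches: int = 2
    dorc_genes: int = 40
    peaks_per_dorc: int = 6
    ko_effect_peaks: int = 100
    ko_log_fc: float = 1.0
    clone_offset_sd: float = 0.1
    depth_mean: float = 5000.0
    nb_dispersion: float = 10.0
    lead_lag: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cells",
            "n_peaks",
            "n_genes",
            "n_motifs",
            "n_clones",
            "n_samples",
            "traj_branches",
            "dorc_genes",
            "peaks_per_dorc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.frac_ko <= 1.0:
            raise ValueError("frac_ko must lie in [0, 1]")
        if self.peaks_per_dorc < 3:
            raise ValueError("peaks_per_dorc must be >= 3")
        if self.dorc_genes * self.peaks_per_dorc > self.n_peaks:
            raise ValueError("dorc_genes * peaks_per_dorc exceeds n_peaks")
        if self.dorc_genes > self.n_genes:
            raise ValueError("dorc_genes exceeds n_genes")
        if self.ko_effect_peaks < 0 or self.clone_offset_sd < 0:
            raise ValueError("ko_effect_peaks and clone_offset_sd must be >= 0")
        if self.depth_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("depth_mean and nb_dispersion must be positive")


@dataclass
class GroundTruth:
    """Planted quantities the pipeline is expected to recover."""

    cell_pseudotime: np.ndarray
    cell_branch: pd.Series
    tf_activity: pd.DataFrame  # motifs x cells
    dorc_links: dict[str, list[int]]
    ko_peaks: np.ndarray
    clone_of_cell: pd.Series
    clone_chromatin_offset: np.ndarray  # clones x peaks
    decoy_peaks: dict[str, list[int]] = field(default_factory=dict)
    program_motifs: list[str] = field(default_factory=list)
    motif_carriers: dict[str, list[int]] = field(default_factory=dict)
    dorc_gene_motif: dict[str, str] = field(default_factory=dict)
    true_barcode_abundance: dict[str, int] | None = None
    assay_perturbation: pd.Series | None = None


def _program_shapes(n_programs: int, traj_branches: int):
    """Smooth activity programs over (pseudotime, branch).

    Program 0 decays out of the stem state; the rest rise along one of the
    committed branches, cycling over branches.
    """

    def make(i):
        if i == 0:
            return lambda pt, br: 1.0 - pt
        b = (i - 1) % traj_branches
        return lambda pt, br: np.where((br == b) & (pt > 0.5), (pt - 0.5) * 2.0, 0.0)

    return [make(i) for i in range(n_programs)]


def simulate_multiome(
    config: SimConfig,
) -> tuple[
    CellCountMatrix, CellCountMatrix, PeakSet, sp.csr_matrix, pd.DataFrame, GroundTruth
]:
    """Generate a paired ATAC + RNA multiome with planted structure.

    Returns (atac, rna, peaks, motif_match, tss_table, truth).  The log-rate
    of peak p in cell i is baseline(p) + sum_m loading(p,m) * activity(m,i)
    + clone_offset(clone_i, p) + ln2 * ko_log_fc * [KO and p planted], rates
    are normalised per cell to the cell's depth, and counts drawn
    Gamma-Poisson with shared dispersion.  DORC-gene expression rates track
    the mean log accessibility of their linked peaks evaluated at pseudotime
    minus ``lead_lag``.  Identical seed gives bit-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- cells: trajectory, clone, sample, genotype -----------------------
    pt = rng.uniform(0.0, 1.0, cfg.n_cells)
    branch = rng.integers(0, cfg.traj_branches, cfg.n_cells)
    branch_names = (
        ["mono", "neut"]
        if cfg.traj_branches == 2
        else [f"branch{b}" for b in range(cfg.traj_branches)]
    )
    celltype = np.where(
        pt <= 0.5, "stem", np.asarray(branch_names, dtype=object)[branch]
    )
    clone = rng.integers(0, cfg.n_clones, cfg.n_cells)
    sample = rng.integers(0, cfg.n_samples, cfg.n_cells)
    n_ko_samples = int(round(cfg.frac_ko * cfg.n_samples))
    ko_sample = np.zeros(cfg.n_samples, bool)
    ko_sample[:n_ko_samples] = True
    genotype = np.where(ko_sample[sample], "KO", "WT")

    cell_ids = pd.Index([f"cell_{i:05d}" for i in range(cfg.n_cells)])
    mito = rng.beta(2.0, 98.0, cfg.n_cells)
    cells = pd.DataFrame(
        {
            "sample": [f"sample_{s}" for s in sample],
            "celltype": celltype,
            "genotype": genotype,
            "clone": [f"clone_{c}" for c in clone],
            "mito_frac": mito,
            "pseudotime": pt,
        },
        index=cell_ids,
    )

    # --- genome layout ----------------------------------------------------
    gene_ids = [f"gene_{g:04d}" for g in range(cfg.n_genes)]
    gene_tss = 100_000 + 50_000 * np.arange(cfg.n_genes)
    tss_table = pd.DataFrame(
        {"chrom": "chr1", "tss": gene_tss, "strand": "+"}, index=pd.Index(gene_ids)
    )

    dorc_gene_ids = gene_ids[: cfg.dorc_genes]
    n_planted = cfg.dorc_genes * cfg.peaks_per_dorc
    n_decoys = min(cfg.dorc_genes, cfg.n_peaks - n_planted)
    n_free = cfg.n_peaks - n_planted - n_decoys

    summits = np.empty(cfg.n_peaks, dtype=np.int64)
    dorc_links: dict[str, list[int]] = {}
    decoy_peaks: dict[str, list[int]] = {}
    # planted cis peaks spread across the 10 kb TSS window
    offsets = np.linspace(-9_000, 9_000, cfg.peaks_per_dorc).astype(np.int64)
    idx = 0
    for g, gid in enumerate(dorc_gene_ids):
        dorc_links[gid] = list(range(idx, idx + cfg.peaks_per_dorc))
        summits[idx : idx + cfg.peaks_per_dorc] = gene_tss[g] + offsets
        idx += cfg.peaks_per_dorc
    for g in range(n_decoys):
        decoy_peaks[dorc_gene_ids[g]] = [idx]
        summits[idx] = gene_tss[g] + 9_600  # in-window but uncorrelated
        idx += 1
    intergenic_start = int(gene_tss[-1] + 50_000)
    free_idx = np.arange(idx, cfg.n_peaks)
    summits[free_idx] = intergenic_start + 2_000 * np.arange(n_free)

    peaks_df = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": summits - 150,
            "end": summits + 151,
            "summit": summits,
            "score": rng.uniform(5.0, 100.0, cfg.n_peaks),
            "gc": rng.uniform(0.3, 0.7, cfg.n_peaks),
            "mean_access": np.nan,
        }
    )

    # --- TF programs and carrier peaks ------------------------------------
    motif_ids = [f"motif_{m:03d}" for m in range(cfg.n_motifs)]
    n_programs = min(cfg.n_motifs, 1 + cfg.traj_branches)
    shapes = _program_shapes(n_programs, cfg.traj_branches)
    activity = np.zeros((cfg.n_motifs, cfg.n_cells))
    for m in range(n_programs):
        activity[m] = PROGRAM_AMPLITUDE * shapes[m](pt, branch)
    activity += rng.normal(0.0, ACTIVITY_NOISE_SD, activity.shape)

    loading = np.zeros((cfg.n_peaks, cfg.n_motifs))
    motif_carriers: dict[str, list[int]] = {m: [] for m in motif_ids[:n_programs]}
    dorc_gene_motif: dict[str, str] = {}
    for g, gid in enumerate(dorc_gene_ids):
        m = g % n_programs
        loading[dorc_links[gid], m] = 1.0
        motif_carriers[motif_ids[m]].extend(dorc_links[gid])
        dorc_gene_motif[gid] = motif_ids[m]
    # intergenic carriers, disjoint across programs
    if n_free > 0 and n_programs > 0:
        per = min(CARRIERS_PER_MOTIF, n_free // n_programs)
        pool = rng.permutation(free_idx)
        for m in range(n_programs):
            carriers = pool[m * per : (m + 1) * per]
            loading[carriers, m] = 1.0
            motif_carriers[motif_ids[m]].extend(carriers.tolist())

    match = (rng.uniform(size=(cfg.n_peaks, cfg.n_motifs)) < MOTIF_BACKGROUND_RATE) | (
        loading > 0
    )
    motif_match = sp.csr_matrix(match.astype(np.int8))

    # --- KO peaks and clone offsets ---------------------------------------
    non_carrier_free = np.setdiff1d(free_idx, np.flatnonzero(loading.any(axis=1)))
    if cfg.ko_effect_peaks > len(non_carrier_free):
        extra = np.setdiff1d(
            np.arange(cfg.n_peaks), np.flatnonzero(loading.any(axis=1))
        )
        pool = extra
    else:
        pool = non_carrier_free
    ko_peaks = np.sort(
        rng.choice(pool, size=min(cfg.ko_effect_peaks, len(pool)), replace=False)
    )
    clone_offset = rng.normal(0.0, cfg.clone_offset_sd, (cfg.n_clones, cfg.n_peaks))

    # --- ATAC counts -------------------------------------------------------
    baseline = rng.normal(0.0, BASELINE_LOG_SD, cfg.n_peaks)
    logw = (
        baseline[:, None]
        + loading @ activity
        + clone_offset[clone].T
    )
    is_ko = genotype == "KO"
    logw[np.ix_(ko_peaks, np.flatnonzero(is_ko))] += np.log(2.0) * cfg.ko_log_fc
    atac_counts = _nb_sample(rng, logw, cfg.depth_mean, cfg.nb_dispersion)

    # --- RNA counts --------------------------------------------------------
    gene_base = rng.normal(0.0, 0.3, cfg.n_genes)
    pt_lag = np.clip(pt - cfg.lead_lag, 0.0, 1.0)
    act_lag = np.zeros((n_programs, cfg.n_cells))
    for m in range(n_programs):
        act_lag[m] = PROGRAM_AMPLITUDE * shapes[m](pt_lag, branch)
    logr = np.tile(gene_base[:, None], (1, cfg.n_cells)).astype(float)
    for g, gid in enumerate(dorc_gene_ids):
        lp = dorc_links[gid]
        # mean planted log accessibility of the linked peaks, at lagged pseudotime
        logr[g] += (
            baseline[lp].mean()
            + (loading[lp][:, :n_programs] @ act_lag).mean(axis=0)
        )
    rna_counts = _nb_sample(rng, logr, cfg.depth_mean, cfg.nb_dispersion)

    peaks_df["mean_access"] = atac_counts.mean(axis=1)
    peaks = PeakSet(peaks_df[PEAK_COLUMNS])

    peak_ids = pd.Index([f"peak_{p:05d}" for p in range(cfg.n_peaks)])
    atac = CellCountMatrix(
        sp.csr_matrix(atac_counts), peak_ids, cell_ids, cells.copy()
    )
    rna = CellCountMatrix(
        sp.csr_matrix(rna_counts), pd.Index(gene_ids), cell_ids, cells.copy()
    )

    truth = GroundTruth(
        cell_pseudotime=pt,
        cell_branch=pd.Series(
            np.asarray(branch_names, dtype=object)[branch], index=cell_ids
        ),
        tf_activity=pd.DataFrame(activity, index=motif_ids, columns=cell_ids),
        dorc_links=dorc_links,
        ko_peaks=ko_peaks,
        clone_of_cell=cells["clone"],
        clone_chromatin_offset=clone_offset,
        decoy_peaks=decoy_peaks,
        program_motifs=motif_ids[:n_programs],
        motif_carriers=motif_carriers,
        dorc_gene_motif=dorc_gene_motif,
    )
    return atac, rna, peaks, motif_match, tss_table, truth


def _nb_sample(
    rng: np.random.Generator, logw: np.ndarray, depth_mean: float, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson counts with per-cell depths and softmax rate normalisation.

    ``dispersion`` is the negative-binomial size parameter r (variance
    mu + mu^2 / r); r -> inf is the Poisson limit.
    """
    n_cells = logw.shape[1]
    depth = depth_mean * rng.lognormal(
        -0.5 * DEPTH_LOGNORM_SIGMA**2, DEPTH_LOGNORM_SIGMA, n_cells
    )
    w = np.exp(logw - logw.max(axis=0, keepdims=True))
    rate = depth[None, :] * w / w.sum(axis=0, keepdims=True)
    if np.isinf(dispersion):
        return rng.poisson(rate).astype(np.int64)
    lam = rng.gamma(dispersion, rate / dispersion)
    return rng.poisson(lam).astype(np.int64)


# ---------------------------------------------------------------------------
# Clone functional assays
# ---------------------------------------------------------------------------

def simulate_clone_function(
    config: SimConfig,
    n_assays: int = 8,
    perturbations: Mapping[str, float] | Sequence[float] | None = None,
    noise_sd: float = 0.3,
) -> tuple[CloneFunctionTable, pd.Series]:
    """Paired WT/KO functional assay table with planted perturbations.

    Each clone gets a WT profile over ``n_assays`` assay columns; its KO row
    is WT + perturbation(clone) * unit direction + Gaussian noise.  Returns
    (table, assay_perturbation).  Perturbation magnitudes default to
    |N(0, 1)| draws and may be supplied explicitly per clone.
    """
    if config.n_clones < 2:
        raise ValueError("need at least 2 clones")
    if n_assays < 2:
        raise ValueError("need at least 2 assays")
    rng = np.random.default_rng(config.seed + 1_000_003)
    clones = [f"clone_{c}" for c in range(config.n_clones)]
    assays = (ASSAY_NAMES * ((n_assays // len(ASSAY_NAMES)) + 1))[:n_assays]
    assays = [a if assays.count(a) == 1 else f"{a}_{i}" for i, a in enumerate(assays)]

    if perturbations is None:
        pert = pd.Series(np.abs(rng.normal(0.0, 1.0, config.n_clones)), index=clones)
    elif isinstance(perturbations, Mapping):
        pert = pd.Series({c: float(perturbations[c]) for c in clones})
    else:
        pert = pd.Series([float(x) for x in perturbations], index=clones)

    direction = rng.normal(0.0, 1.0, n_assays)
    direction /= np.linalg.norm(direction)
    wt = rng.normal(0.0, 1.0, (config.n_clones, n_assays))
    noise = (
        rng.normal(0.0, noise_sd, (config.n_clones, n_assays)) if noise_sd > 0 else 0.0
    )
    ko = wt + pert.to_numpy()[:, None] * direction[None, :] + noise

    idx = pd.MultiIndex.from_product([clones, ["WT", "KO"]], names=["clone", "condition"])
    values = pd.DataFrame(
        np.empty((2 * config.n_clones, n_assays)), index=idx, columns=assays
    )
    for i, c in enumerate(clones):
        values.loc[(c, "WT")] = wt[i]
        values.loc[(c, "KO")] = ko[i]
    return CloneFunctionTable(values=values), pert.rename("assay_perturbation")


# ---------------------------------------------------------------------------
# Barcode reads
# ---------------------------------------------------------------------------

DEFAULT_CONSTANT_POSITIONS = {4: "T", 14: "A", 24: "C"}
DEFAULT_FLANK5 = "AGGACGACGGCAAC"
DEFAULT_FLANK3 = "GTCTTGTAGTTCCC"
_BASES = np.array(list("ACGT"))


def _random_barcode(
    rng: np.random.Generator, bc_len: int, constant_positions: Mapping[int, str]
) -> str:
    bc = _BASES[rng.integers(0, 4, bc_len)]
    for p, b in constant_positions.items():
        bc[p] = b
    return "".join(bc)


def simulate_barcode_reads(
    n_clones: int,
    abundance: Mapping | Sequence[int],
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
    error_rate: float = 0.0,
    seed: int = 0,
    bc_len: int = 28,
    constant_positions: Mapping[int, str] | None = None,
    pad: int = 10,
):
    """Simulate lineage-barcode sequencing reads.

    One distinct barcode (28-mer with fixed constant bases) is generated per
    clone; each read is random-prefix + flank5 + barcode-with-substitution-
    errors + flank3 + random-suffix.  ``abundance`` maps clone index (or
    position) to its read count.  Returns (list of Bio.SeqRecord, truth map
    barcode -> count).
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    for fl in (flank5, flank3):
        if not fl or set(fl) - set("ACGT"):
            raise ValueError(f"invalid DNA flank: {fl!r}")
    constant_positions = (
        DEFAULT_CONSTANT_POSITIONS if constant_positions is None else constant_positions
    )
    rng = np.random.default_rng(seed)
    if isinstance(abundance, Mapping):
        counts = [int(abundance[k]) for k in sorted(abundance)]
    else:
        counts = [int(x) for x in abundance]
    if len(counts) != n_clones:
        raise ValueError("abundance must give one count per clone")

    barcodes: list[str] = []
    seen = set()
    while len(barcodes) < n_clones:
        bc = _random_barcode(rng, bc_len, constant_positions)
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)

    records = []
    truth = dict(zip(barcodes, counts))
    r = 0
    for bc, cnt in zip(barcodes, counts):
        arr = np.array(list(bc))
        for _ in range(cnt):
            read_bc = arr.copy()
            if error_rate > 0:
                hit = rng.uniform(size=bc_len) < error_rate
                for p in np.flatnonzero(hit):
                    read_bc[p] = rng.choice(_BASES[_BASES != read_bc[p]])
            prefix = "".join(_BASES[rng.integers(0, 4, pad)])
            suffix = "".join(_BASES[rng.integers(0, 4, pad)])
            seq = prefix + flank5 + "".join(read_bc) + flank3 + suffix
            records.append(
                SeqRecord(
                    Seq(seq),
                    id=f"read_{r:07d}",
                    description="",
                    letter_annotations={"phred_quality": [30] * len(seq)},
                )
            )
            r += 1
    order = rng.permutation(len(records))
    return [records[i] for i in order], truth


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def write_simulation(
    outdir: str | Path,
    atac: CellCountMatrix,
    rna: CellCountMatrix,
    peaks: PeakSet,
    motif_match: sp.spmatrix,
    tss_table: pd.DataFrame,
    truth: GroundTruth,
) -> None:
    """Write every simulated input in its standard on-disk form."""
    import scipy.io

    from .io_peaks import write_bed, write_mtx

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mtx(atac, outdir / "atac")
    write_mtx(rna, outdir / "rna")
    write_bed(peaks, outdir / "peaks.bed")
    scipy.io.mmwrite(outdir / "motif_match.mtx", sp.coo_matrix(motif_match))
    tss_table.to_csv(outdir / "tss.tsv", sep="\t")
    atac.cell_meta.to_csv(outdir / "cells.tsv", sep="\t")

    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    pd.DataFrame(
        {
            "pseudotime": truth.cell_pseudotime,
            "branch": truth.cell_branch.to_numpy(),
            "clone": truth.clone_of_cell.to_numpy(),
        },
        index=truth.cell_branch.index,
    ).to_csv(tdir / "cells.tsv", sep="\t")
    truth.tf_activity.to_csv(tdir / "tf_activity.tsv", sep="\t")
    pd.Series(truth.ko_peaks, name="ko_peak").to_csv(
        tdir / "ko_peaks.tsv", sep="\t", index=False
    )
    rows = [
        {"gene": g, "peak": p} for g, pl in truth.dorc_links.items() for p in pl
    ]
    pd.DataFrame(rows).to_csv(tdir / "dorc_links.tsv", sep="\t", index=False)
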