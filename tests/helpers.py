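"""Shared builders for small in-memory test objects."""

import numpy as np
import pandas as pd
import scipy.sparse as sp

from chromclone import CellCountMatrix, PeakSet
from chromclone.activity import BackgroundSets
from chromclone.io_peaks import PEAK_COLUMNS


def make_peaks(centers, gc=None, mean_access=None, chrom="chr1"):
    centers = np.asarray(centers)
    n = len(centers)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": centers - 150,
            "end": centers + 151,
            "summit": centers,
            "score": 1.0,
            "gc": gc if gc is not None else np.full(n, 0.5),
            "mean_access": mean_access if mean_access is not None else np.ones(n),
        }
    )
    return PeakSet(df[PEAK_COLUMNS])


def make_atac(values, meta=None):
    values = sp.csr_matrix(np.asarray(values))
    return CellCountMatrix(
        values,
        pd.Index([f"p{i}" for i in range(values.shape[0])]),
        pd.Index([f"c{i}" for i in range(values.shape[1])]),
        meta if meta is not None else pd.DataFrame(),
    )


def uniform_bg(n_peaks, n_background=20, seed=0):
    """Backgrounds drawn uniformly over all other peaks (no covariate matching)."""
    rng = np.random.default_rng(seed)
    draws = np.empty((n_peaks, n_background), dtype=np.int64)
    for p in range(n_peaks):
        draws[p] = rng.choice(np.delete(np.arange(n_peaks), p), size=n_background)
    return BackgroundSets(draws=draws)
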