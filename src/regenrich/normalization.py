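"""Fragment counting in consensus peaks and TMM count normalization.

TMM (trimmed mean of M-values; Robinson & Oshlack 2010) computes a
per-sample scale factor from a doubly-trimmed weighted mean of feature-wise
log-ratios against a reference sample, so composition bias (a minority of
features genuinely up in one library) does not distort between-sample
comparisons.  "Full library size" — the total fragments sequenced per
sample, not the column sum over peaks — is used when supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "read_fragments",
    "count_fragments_in_peaks",
    "tmm_factors",
    "normalized_cpm",
]


@dataclass
class CountMatrix:
    """Features × samples non-negative integer counts.

    ``library_sizes`` defaults to column sums; pass full library sizes
    (total fragments per sample) to match the "full library size" option.
    """

    counts: pd.DataFrame
    kind: str = "peak"  # peak | gene
    library_sizes: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.library_sizes is None:
            logger.warning("library sizes not supplied; falling back to "
                           "column sums of the %s matrix", self.kind)
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                raise ValueError("library_sizes missing some samples")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "peak",
                 library_sizes: pd.Series | None = None) -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), kind=kind,
                   library_sizes=library_sizes)


def read_fragments(path: str | Path, strip_chr: bool = True
                   ) -> dict[str, np.ndarray]:
    """Read BED fragment intervals into per-chromosome (n, 2) arrays."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    if strip_chr:
        df["chrom"] = df["chrom"].str.replace("^chr", "", regex=True, case=False)
    out = {}
    for chrom, sub in df.groupby("chrom"):
        arr = sub[["start", "end"]].to_numpy(dtype=np.int64)
        out[str(chrom)] = arr[np.argsort(arr[:, 0], kind="stable")]
    return out


def count_fragments_in_peaks(
        fragments_per_sample: dict[str, dict[str, np.ndarray]],
        consensus: PeakSet,
        library_sizes: pd.Series | None = None) -> CountMatrix:
    """Count fragments overlapping each consensus peak by ≥1 bp.

    A fragment overlapping k peaks increments all k.  Keys of
    ``fragments_per_sample`` become sample names; values are per-chromosome
    (n, 2) interval arrays as returned by :func:`read_fragments`.
    """
    peak_ids = [iv.name or f"peak_{i}" for i, iv in enumerate(consensus)]
    data = {}
    for sample, frags in fragments_per_sample.items():
        starts_sorted = {c: np.sort(a[:, 0]) for c, a in frags.items()}
        ends_sorted = {c: np.sort(a[:, 1]) for c, a in frags.items()}
        col = np.zeros(len(consensus), dtype=np.int64)
        for i, iv in enumerate(consensus):
            ss = starts_sorted.get(iv.chrom)
            if ss is None:
                continue
            # overlap ≥1bp  ⇔  frag.start < peak.end and frag.end > peak.start
            n_start_before_end = np.searchsorted(ss, iv.end, side="left")
            n_end_at_or_before_start = np.searchsorted(
                ends_sorted[iv.chrom], iv.start, side="right")
            col[i] = n_start_before_end - n_end_at_or_before_start
        data[sample] = col
    counts = pd.DataFrame(data, index=peak_ids)
    return CountMatrix(counts, kind="peak", library_sizes=library_sizes)


def _quantile_depth(col: np.ndarray, lib: float, p: float = 0.75) -> float:
    return float(np.quantile(col, p) / lib)


def tmm_factors(counts: CountMatrix, ref_sample: str | None = None,
                logratio_trim: float = 0.30, sum_trim: float = 0.05
                ) -> pd.Series:
    """TMM normalization factors, re-centered to geometric mean 1.

    The reference is the sample whose upper-quartile (of library-scaled
    counts) is closest to the mean upper-quartile.  For each sample, genes
    positive in both it and the reference contribute an M-value (log2 ratio
    of depth-scaled proportions) and an A-value (mean log2 abundance); the
    top/bottom ``logratio_trim`` of M and ``sum_trim`` of A are discarded
    and the remaining M-values averaged with inverse-variance weights.
    """
    if counts.counts.shape[1] < 2:
        raise ValueError("TMM needs ≥2 samples")
    mat = counts.counts.to_numpy(dtype=float)
    libs = counts.library_sizes.to_numpy(dtype=float)
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("sample with all-zero counts")
    samples = counts.samples
    if ref_sample is None:
        uq = np.array([_quantile_depth(mat[:, j], libs[j]) for j in range(len(samples))])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = samples.index(ref_sample)
    ref, ref_lib = mat[:, ref_idx], libs[ref_idx]

    log_factors = np.zeros(len(samples))
    for j in range(len(samples)):
        if j == ref_idx:
            continue
        obs, lib = mat[:, j], libs[j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() == 0:
            raise ValueError(f"no co-expressed features between {samples[j]} and reference")
        p_obs, p_ref = obs[ok] / lib, ref[ok] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic (delta-method) variance of M
        w = (lib - obs[ok]) / (lib * obs[ok]) + (ref_lib - ref[ok]) / (ref_lib * ref[ok])
        if np.allclose(m, m[0], atol=1e-10):
            log_factors[j] = m[0]
            continue
        n = len(m)
        lo_m = np.floor(n * logratio_trim) + 1
        lo_a = np.floor(n * sum_trim) + 1
        keep = (_rank_keep(m, lo_m, n + 1 - lo_m)
                & _rank_keep(a, lo_a, n + 1 - lo_a))
        if keep.sum() == 0:
            keep = np.ones(n, dtype=bool)
        log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])

    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=samples, name="tmm_factor")


def _rank_keep(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Keep 1-based tie-averaged ranks in [lo, hi]."""
    from scipy.stats import rankdata
    ranks = rankdata(x, method="average")
    return (ranks >= lo) & (ranks <= hi)


def normalized_cpm(counts: CountMatrix, factors: pd.Series | None = None,
                   prior_count: float = 0.5, log2: bool = False) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes.

    cpm = (count + prior) / (library_size × factor) × 1e6; with ``log2``
    the base-2 log is returned (the prior keeps zeros finite).
    """
    if factors is None:
        factors = pd.Series(1.0, index=counts.counts.columns)
    factors = factors.reindex(counts.counts.columns)
    if (factors <= 0).any():
        raise ValueError("normalization factors must be positive")
    eff = counts.library_sizes * factors
    cpm = (counts.counts + prior_count).div(eff, axis=1) * 1e6
    return np.log2(cpm) if log2 else cpm
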