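"""Peak–gene pairing within a TSS window and Pearson correlation screening.

Every consensus peak whose anchor (summit for narrow marks, midpoint for
broad) lies within 100 kb of a gene's TSS is paired with that gene; peak
height (normalized CPM) is then correlated with the gene's expression
across matched samples.  With small sample panels (16–18) the screen is
deliberately uncorrected: the scientific readout is the exceedance of the
significant fraction over the 5% chance level and the sign balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneModel, tss_by_chrom
from .intervals import PeakSet, peak_anchor

__all__ = [
    "PeakGenePair",
    "CorrelationResult",
    "pair_peaks_genes",
    "correlate_peak_gene",
    "correlated_peak_set",
    "direction_summary",
]


@dataclass(frozen=True)
class PeakGenePair:
    peak_id: str
    gene_id: str
    tss_distance: int  # anchor-to-TSS, unsigned bp


@dataclass(frozen=True)
class CorrelationResult:
    pair: PeakGenePair
    r: float
    p_value: float
    n_samples: int
    significant: bool


def pair_peaks_genes(consensus: PeakSet, genes: Sequence[GeneModel],
                     window: int = 100_000) -> list[PeakGenePair]:
    """All (peak, gene) pairs with anchor-to-TSS distance ≤ ``window``.

    A peak may pair with many genes and vice versa.  Peaks without a gene
    within the window simply produce no pairs.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for v in by_chrom.values():
        v.sort()
    pairs: list[PeakGenePair] = []
    for i, iv in enumerate(consensus):
        glist = by_chrom.get(iv.chrom)
        if not glist:
            continue
        anchor = peak_anchor(iv, consensus.shape_class)
        tss = np.array([t for t, _ in glist], dtype=np.int64)
        lo = np.searchsorted(tss, anchor - window, side="left")
        hi = np.searchsorted(tss, anchor + window, side="right")
        peak_id = iv.name or f"peak_{i}"
        for j in range(lo, hi):
            t, gid = glist[j]
            pairs.append(PeakGenePair(peak_id, gid, int(abs(anchor - t))))
    return pairs


def correlate_peak_gene(pairs: Sequence[PeakGenePair],
                        peak_cpm: pd.DataFrame, gene_counts: pd.DataFrame,
                        matched_samples: Sequence[str],
                        alpha: float = 0.05) -> list[CorrelationResult]:
    """Pearson r and two-sided p (t-transform, n−2 df) for each pair.

    ``matched_samples`` names the columns shared by both matrices in the
    order they should be aligned.  Pairs where either vector has zero
    variance get r = NaN and are excluded from downstream summaries.
    """
    cols = list(matched_samples)
    n = len(cols)
    if n < 3:
        raise ValueError("need ≥3 matched samples for a defined p-value")
    X = peak_cpm[cols].to_numpy(dtype=float)
    Y = gene_counts[cols].to_numpy(dtype=float)
    xi = peak_cpm.index.get_indexer([p.peak_id for p in pairs])
    yi = gene_counts.index.get_indexer([p.gene_id for p in pairs])
    if (xi < 0).any() or (yi < 0).any():
        raise KeyError("pair refers to peak/gene absent from matrices")
    x, y = X[xi], Y[yi]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    zero_var = (sx == 0) | (sy == 0)
    r = np.where(zero_var, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, p))
    return [CorrelationResult(pair, float(r[i]), float(p[i]), n,
                              bool(not np.isnan(p[i]) and p[i] < alpha))
            for i, pair in enumerate(pairs)]


def correlated_peak_set(results: Sequence[CorrelationResult],
                        consensus: PeakSet, direction: str = "any",
                        alpha: float = 0.05) -> PeakSet:
    """Unique peaks participating in ≥1 significant pair of a direction.

    ``direction`` is "any", "positive" or "negative".
    """
    if direction not in ("any", "positive", "negative"):
        raise ValueError(f"bad direction {direction!r}")
    keep_ids = set()
    for res in results:
        if np.isnan(res.r) or not (res.p_value < alpha):
            continue
        if direction == "positive" and res.r <= 0:
            continue
        if direction == "negative" and res.r >= 0:
            continue
        keep_ids.add(res.pair.peak_id)
    ivs = [iv for i, iv in enumerate(consensus)
           if (iv.name or f"peak_{i}") in keep_ids]
    return PeakSet(ivs, shape_class=consensus.shape_class,
                   label=f"correlated_{direction}")


def direction_summary(results: Sequence[CorrelationResult],
                      alpha: float = 0.05) -> dict[str, float | int | str]:
    """Counts of significant positive/negative correlations and the
    majority direction (repressive marks come out "negative")."""
    pos = sum(1 for r in results if not np.isnan(r.r)
              and r.p_value < alpha and r.r > 0)
    neg = sum(1 for r in results if not np.isnan(r.r)
              and r.p_value < alpha and r.r < 0)
    tested = sum(1 for r in results if not np.isnan(r.r))
    return {
        "n_tested": tested,
        "n_significant": pos + neg,
        "n_positive": pos,
        "n_negative": neg,
        "significant_fraction": (pos + neg) / tested if tested else float("nan"),
        "majority_direction": "positive" if pos >= neg else "negative",
    }
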