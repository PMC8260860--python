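"""Windowed LD pruning of SNP sets from genotype dosages.

Within each 1-Mb window, advancing by 50 SNPs, SNPs are retained only if
their pairwise dosage r² with every already-retained SNP in the window is
below 0.5 — the windowed-pruning parameters from the plink
``--indep-pairwise``-style filter.  The normative contract is the
post-condition: no retained pair within any window reaches the r²
threshold.  In ``by_pvalue`` mode the scan order within a window is
ascending association p-value, so each LD block keeps its most significant
SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import SnpSet

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "pairwise_r2", "window_prune", "read_genotypes"]

MISSING = -1  # sentinel for a missing dosage


@dataclass
class GenotypeMatrix:
    """SNPs × individuals dosages (0/1/2; −1 = missing), position-aligned.

    ``positions`` holds (chrom, 1-based pos) per row, sorted; ``dosages``
    is an int array with one row per SNP.
    """

    positions: list[tuple[str, int]]
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2 or len(self.positions) != self.dosages.shape[0]:
            raise ValueError("dosages must be (n_snps, n_individuals)")
        valid = np.isin(self.dosages, [MISSING, 0, 1, 2])
        if not valid.all():
            raise ValueError("dosages must be 0/1/2 or missing (-1)")
        order = sorted(range(len(self.positions)),
                       key=lambda i: (self.positions[i][0], self.positions[i][1]))
        self.positions = [self.positions[i] for i in order]
        self.dosages = self.dosages[order]

    def row_index(self) -> dict[tuple[str, int], int]:
        return {pos: i for i, pos in enumerate(self.positions)}


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a genotype TSV: columns chrom, pos, then one per individual."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos"} <= set(df.columns):
        raise ValueError("genotype table needs chrom, pos + individual columns")
    indiv = [c for c in df.columns if c not in ("chrom", "pos")]
    dos = df[indiv].fillna(MISSING).to_numpy(dtype=np.int64)
    return GenotypeMatrix(list(zip(df["chrom"], df["pos"].astype(int))), dos)


def pairwise_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs.

    A zero-variance vector gives r² = 0 (with a warning): such a SNP can
    never prune, nor be pruned by, another.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        raise ValueError("need ≥2 complete pairs for r²")
    a, b = g1[ok], g2[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        logger.warning("zero-variance dosage vector; r² treated as 0")
        return 0.0
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov ** 2 / (va * vb))


def window_prune(snps: SnpSet, genotypes: GenotypeMatrix,
                 window_bp: int = 1_000_000, step_snps: int = 50,
                 r2_max: float = 0.5, mode: str = "positional") -> SnpSet:
    """Greedy windowed LD pruning; returns the retained SnpSet in input order.

    Windows start every ``step_snps`` SNPs along each chromosome and span
    ``window_bp``.  Within a window, SNPs are scanned in genomic order
    ("positional") or ascending p-value ("by_pvalue"); a SNP is dropped if
    its r² with any already-retained SNP in the window is ≥ ``r2_max``.
    The sweep repeats until no further SNP is dropped.
    """
    if step_snps < 1:
        raise ValueError("step_snps must be ≥ 1")
    if mode not in ("positional", "by_pvalue"):
        raise ValueError("mode must be positional|by_pvalue")
    if mode == "by_pvalue" and snps.p_values is None:
        raise ValueError("by_pvalue mode requires SNP p-values")
    row_of = genotypes.row_index()
    missing = [p for p in snps.positions if p not in row_of]
    if missing:
        raise ValueError(f"genotypes missing for {len(missing)} SNPs, "
                         f"e.g. {missing[0]}")

    keep = {p: True for p in snps.positions}
    pvals = dict(zip(snps.positions, snps.p_values)) if snps.p_values else {}

    by_chrom: dict[str, list[tuple[str, int]]] = {}
    for p in snps.positions:
        by_chrom.setdefault(p[0], []).append(p)
    for v in by_chrom.values():
        v.sort(key=lambda p: p[1])

    changed = True
    while changed:
        changed = False
        for chrom, plist in by_chrom.items():
            n = len(plist)
            for w0 in range(0, n, step_snps):
                start_pos = plist[w0][1]
                win = [p for p in plist[w0:] if p[1] - start_pos < window_bp]
                cand = [p for p in win if keep[p]]
                if mode == "by_pvalue":
                    cand.sort(key=lambda p: (pvals[p], p[1]))
                retained_rows: list[int] = []
                for p in cand:
                    row = row_of[p]
                    pruned = False
                    for rr in retained_rows:
                        if pairwise_r2(genotypes.dosages[row],
                                       genotypes.dosages[rr]) >= r2_max:
                            keep[p] = False
                            changed = True
                            pruned = True
                            break
                    if not pruned:
                        retained_rows.append(row)
    retained = [p for p in snps.positions if keep[p]]
    return SnpSet(retained,
                  [pvals[p] for p in retained] if snps.p_values else None,
                  label=f"{snps.label}_pruned")
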