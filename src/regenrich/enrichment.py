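"""Base-pair enrichment of SNP sets in functional regions.

The central statistic is the fold enrichment

    fold = (C/A) / (B/D) = C·D / (A·B)

where A is the number of autosomal base positions under the region set, B
the number of SNP positions, C the number of SNPs falling under regions,
and D the autosomal genome size.  Treating base positions as exchangeable
units, C under the null is Hypergeometric(N=D, K=B, n=A), giving one-sided
enrichment (P(X ≥ C)) and depletion (P(X ≤ C)) p-values.

Distance stratification restricts regions and SNPs (and, by default, D) to
bands of distance from the nearest TSS — 0–100 kb, 100–200 kb, … up to
1 Mb — to control for both peaks and trait-associated variants clustering
near genes.  Bands with fewer than ``min_snps`` SNPs are reported as NA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneModel, tss_by_chrom
from .intervals import (Genome, GenomicInterval, PeakSet, StateSegmentation,
                        coverage_bp, distance_to_nearest_tss, intersect_bp,
                        peak_anchor, _merge_array)

logger = logging.getLogger(__name__)

__all__ = [
    "SnpSet",
    "EnrichmentResult",
    "DistanceBand",
    "default_bands",
    "read_snp_table",
    "snp_enrichment",
    "distance_stratified_enrichment",
    "state_overlap_enrichment",
    "enrichment_report",
]


@dataclass
class SnpSet:
    """Unique single-base variant positions, optionally with p-values.

    ``positions`` holds (chrom, pos) with 1-based positions as in the
    source tables; conversion to 0-based happens inside the overlap test.
    Duplicate positions are dropped on construction (keeping the smaller
    p-value when present) so enrichment is invariant to duplicated records.
    """

    positions: list[tuple[str, int]]
    p_values: list[float] | None = None
    label: str = ""

    def __post_init__(self):
        if self.p_values is not None and len(self.p_values) != len(self.positions):
            raise ValueError("p_values length mismatch")
        seen: dict[tuple[str, int], float] = {}
        order: list[tuple[str, int]] = []
        for i, key in enumerate(self.positions):
            key = (str(key[0]), int(key[1]))
            p = self.p_values[i] if self.p_values is not None else np.nan
            if key not in seen:
                seen[key] = p
                order.append(key)
            elif self.p_values is not None and p < seen[key]:
                seen[key] = p
        order.sort()
        self.positions = order
        self.p_values = [seen[k] for k in order] if self.p_values is not None else None

    def __len__(self) -> int:
        return len(self.positions)

    def restrict(self, chrom_names: Sequence[str]) -> "SnpSet":
        keep = set(chrom_names)
        idx = [i for i, (c, _) in enumerate(self.positions) if c in keep]
        return SnpSet([self.positions[i] for i in idx],
                      [self.p_values[i] for i in idx] if self.p_values else None,
                      label=self.label)

    def by_chrom(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for c, p in self.positions:
            out.setdefault(c, []).append(p)
        return {c: np.array(v, dtype=np.int64) for c, v in out.items()}


@dataclass(frozen=True)
class EnrichmentResult:
    """The (A, B, C, D) quadruple with fold and one-sided tail p-values."""

    A: int  # bp under regions
    B: int  # SNP count
    C: int  # SNPs under regions
    D: int  # autosomal bp
    fold: float
    p_enrich: float
    p_deplete: float
    label: str = ""
    defined: bool = True

    @classmethod
    def undefined(cls, A: int, B: int, D: int, label: str = "") -> "EnrichmentResult":
        return cls(A, B, 0, D, float("nan"), float("nan"), float("nan"),
                   label=label, defined=False)


@dataclass(frozen=True)
class DistanceBand:
    """Half-open distance band [lower, upper) in bp from the nearest TSS."""
    lower: int
    upper: int

    def __post_init__(self):
        if not (0 <= self.lower < self.upper):
            raise ValueError("band must satisfy 0 ≤ lower < upper")

    def __str__(self) -> str:
        return f"{self.lower}-{self.upper}"


def default_bands(width: int = 100_000, n: int = 10) -> list[DistanceBand]:
    """Ten 100-kb bands: [0,100kb), [100,200kb), … [900kb,1Mb)."""
    return [DistanceBand(i * width, (i + 1) * width) for i in range(n)]


def read_snp_table(path: str | Path, label: str = "",
                   strip_chr: bool = True) -> SnpSet:
    """Read a SNP TSV with columns chrom, pos (1-based) and optional pvalue."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos"} <= set(df.columns):
        raise ValueError("SNP table needs columns: chrom, pos[, pvalue]")
    if strip_chr:
        df["chrom"] = df["chrom"].str.replace("^chr", "", regex=True, case=False)
    pvals = df["pvalue"].tolist() if "pvalue" in df.columns else None
    return SnpSet(list(zip(df["chrom"], df["pos"].astype(int))), pvals,
                  label=label or str(path))


# ---------------------------------------------------------------------------

def _snps_under(snps_by_chrom: dict[str, np.ndarray],
                merged: dict[str, np.ndarray]) -> int:
    """Count SNPs (1-based pos) whose 0-based position is inside a region."""
    c_total = 0
    for chrom, pos in snps_by_chrom.items():
        arr = merged.get(chrom)
        if arr is None or arr.size == 0:
            continue
        p0 = pos - 1  # regions are half-open 0-based; SNP "under" iff start ≤ p0 < end
        idx = np.searchsorted(arr[:, 0], p0, side="right") - 1
        ok = (idx >= 0) & (p0 < arr[np.maximum(idx, 0), 1])
        c_total += int(ok.sum())
    return c_total


def _hypergeom_tails(C: int, D: int, B: int, A: int) -> tuple[float, float]:
    hg = stats.hypergeom(D, B, A)
    return float(hg.sf(C - 1)), float(hg.cdf(C))


def snp_enrichment(snps: SnpSet, regions: PeakSet, genome: Genome,
                   label: str = "") -> EnrichmentResult:
    """Fold (C/A)/(B/D) and hypergeometric tail p-values for one SNP set
    against one region set, restricted to autosomes."""
    autos = genome.autosome_names
    regions_a = regions.restrict(autos)
    snps_a = snps.restrict(autos)
    D = genome.total_autosomal_bp
    A = coverage_bp(regions_a)
    B = len(snps_a)
    label = label or f"{snps.label}|{regions.label}"
    if A == 0 or B == 0:
        logger.warning("enrichment undefined for %s (A=%d, B=%d)", label, A, B)
        return EnrichmentResult.undefined(A, B, D, label=label)
    C = _snps_under(snps_a.by_chrom(), regions_a.merged_by_chrom())
    fold = (C * D) / (A * B)  # exact algebraic form of (C/A)/(B/D)
    p_en, p_de = _hypergeom_tails(C, D, B, A)
    return EnrichmentResult(A, B, C, D, fold, p_en, p_de, label=label)


# ---------------------------------------------------------------------------
# Distance stratification

def _distance_coverage(tss: dict[str, np.ndarray], genome: Genome,
                       radius: int) -> dict[str, np.ndarray]:
    """Merged intervals of bases within ``radius`` bp of a TSS per autosome."""
    sizes = genome.sizes
    out = {}
    for chrom in genome.autosome_names:
        t = tss.get(chrom)
        if t is None or t.size == 0:
            continue
        arr = np.stack([np.maximum(t - radius, 0),
                        np.minimum(t + radius + 1, sizes[chrom])], axis=1)
        out[chrom] = _merge_array(arr)
    return out


def band_genome_bp(genes: Sequence[GeneModel], genome: Genome,
                   band: DistanceBand) -> int:
    """Autosomal bp whose distance to the nearest TSS lies in the band."""
    tss = tss_by_chrom(genes)
    hi_cov = _distance_coverage(tss, genome, band.upper - 1)
    hi = sum(int((a[:, 1] - a[:, 0]).sum()) for a in hi_cov.values())
    if band.lower == 0:
        lo = 0
    else:
        lo_cov = _distance_coverage(tss, genome, band.lower - 1)
        lo = sum(int((a[:, 1] - a[:, 0]).sum()) for a in lo_cov.values())
    return hi - lo


def distance_stratified_enrichment(
        snps: SnpSet, regions: PeakSet, genes: Sequence[GeneModel],
        genome: Genome, bands: Sequence[DistanceBand] | None = None,
        min_snps: int = 10, global_d: bool = False) -> list[EnrichmentResult]:
    """Enrichment within bands of distance from the nearest TSS.

    Regions enter a band by their anchor's distance, SNPs by their own
    distance; A/B/C are computed from the band's members and D is the bp of
    the genome at that distance (or the whole autosomal genome when
    ``global_d``).  Bands with fewer than ``min_snps`` SNPs, or with no
    regions, come back as undefined (NA) rows rather than errors.
    Positions on chromosomes without any TSS are excluded with a log line.
    """
    if bands is None:
        bands = default_bands()
    tss = tss_by_chrom(genes)
    autos = set(genome.autosome_names)

    regions_a = regions.restrict(autos)
    snps_a = snps.restrict(autos)

    peak_dist: list[float] = []
    skipped = 0
    for iv in regions_a:
        t = tss.get(iv.chrom)
        if t is None or t.size == 0:
            peak_dist.append(np.nan)
            skipped += 1
            continue
        anchor = peak_anchor(iv, regions_a.shape_class)
        peak_dist.append(float(distance_to_nearest_tss([anchor], t)[0]))
    snp_dist_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in snps_a.by_chrom().items():
        t = tss.get(chrom)
        if t is None or t.size == 0:
            snp_dist_by_chrom[chrom] = np.full(len(pos), np.nan)
            skipped += len(pos)
            continue
        snp_dist_by_chrom[chrom] = distance_to_nearest_tss(pos - 1, t).astype(float)
    # snps_a.positions is sorted by (chrom, pos), matching by_chrom order
    counters = {c: 0 for c in snp_dist_by_chrom}
    snp_dist: list[float] = []
    for chrom, _ in snps_a.positions:
        snp_dist.append(float(snp_dist_by_chrom[chrom][counters[chrom]]))
        counters[chrom] += 1
    if skipped:
        logger.warning("%d positions on chromosomes without a TSS were "
                       "excluded from stratification", skipped)

    results = []
    for band in bands:
        band_regions = PeakSet(
            [iv for iv, d in zip(regions_a.intervals, peak_dist)
             if not np.isnan(d) and band.lower <= d < band.upper],
            shape_class=regions_a.shape_class, label=f"{regions.label}[{band}]")
        band_snp_idx = [i for i, d in enumerate(snp_dist)
                        if not np.isnan(d) and band.lower <= d < band.upper]
        band_snps = SnpSet([snps_a.positions[i] for i in band_snp_idx],
                           label=f"{snps.label}[{band}]")
        D = genome.total_autosomal_bp if global_d else band_genome_bp(genes, genome, band)
        A = coverage_bp(band_regions)
        B = len(band_snps)
        lbl = f"{snps.label}|{regions.label}|{band}"
        if B < min_snps or A == 0 or D == 0:
            results.append(EnrichmentResult.undefined(A, B, D, label=lbl))
            continue
        C = _snps_under(band_snps.by_chrom(), band_regions.merged_by_chrom())
        fold = (C * D) / (A * B)
        p_en, p_de = _hypergeom_tails(C, D, B, A)
        results.append(EnrichmentResult(A, B, C, D, fold, p_en, p_de, label=lbl))
    return results


# ---------------------------------------------------------------------------
# Chromatin-state overlap enrichment

def state_overlap_enrichment(seg: StateSegmentation,
                             annotations: dict[str, PeakSet],
                             genome: Genome) -> pd.DataFrame:
    """Fold enrichment of each chromatin state in each annotation class.

    Same arithmetic with bp in both roles: A = state bp, B = annotation bp,
    C = their intersection bp, D = autosomal genome bp.  Returns a long
    DataFrame with one row per (state, annotation) plus the per-state
    genome fraction A/D; states covering 0 bp yield NaN folds.
    """
    D = genome.total_autosomal_bp
    rows = []
    for state in seg.state_labels:
        sp = seg.state_peakset(state).restrict(genome.autosome_names)
        A = coverage_bp(sp)
        for ann_label, ann in annotations.items():
            ann_a = ann.restrict(genome.autosome_names)
            B = coverage_bp(ann_a)
            if A == 0 or B == 0:
                rows.append((state, ann_label, A, B, 0, D, np.nan, A / D))
                continue
            C = intersect_bp(sp, ann_a)
            rows.append((state, ann_label, A, B, C, D, (C * D) / (A * B), A / D))
    return pd.DataFrame(rows, columns=["state", "annotation", "A", "B", "C",
                                       "D", "fold", "genome_fraction"])


def enrichment_report(results: Sequence[EnrichmentResult],
                      group_keys: Sequence[dict] | None = None) -> pd.DataFrame:
    """Long-format table of enrichment results with optional grouping keys
    (e.g. mark/tissue) and per-group average folds appended as extra rows."""
    if not results:
        raise ValueError("no results to report")
    rows = []
    for i, r in enumerate(results):
        row = {"label": r.label, "A": r.A, "B": r.B, "C": r.C, "D": r.D,
               "fold": r.fold, "p_enrich": r.p_enrich, "p_deplete": r.p_deplete,
               "defined": r.defined}
        if group_keys is not None:
            row.update(group_keys[i])
        rows.append(row)
    df = pd.DataFrame(rows)
    if group_keys:
        keys = [k for k in group_keys[0] if k != "tissue"]
        if "tissue" in group_keys[0] and keys:
            avg = (df[df["defined"]]
                   .groupby(keys, as_index=False)["fold"].mean())
            avg["label"] = "average_across_tissues"
            df = pd.concat([df, avg], ignore_index=True)
    return df
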