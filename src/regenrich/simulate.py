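"""Seeded synthetic-data generators with planted ground truth.

Emulates the study design this package analyses: replicated histone-mark /
transcription-factor peak calls from several tissues of a few animals,
negative-binomial ChIP and RNA count matrices, SNP sets with a planted
base-pair fold enrichment inside functional regions, block-LD genotypes,
and a chromatin-state tiling.  Every generator is a pure function of its
config (seed included): reruns are byte-identical.

Planted effects are labelled in :class:`GroundTruth` so each pipeline stage
can be closed-loop tested: differentially bound peaks carry a known fold in
one tissue, designated peak–gene pairs share a latent gamma factor mixed to
hit a target Pearson r, active/inactive genes are drawn to satisfy the
all-samples >200 / <10 count rules exactly, and SNP density inside regions
is a known multiple of the outside density.

The default genome is 10 chromosomes x 5 Mb with genes confined to the
first half of each chromosome, so distance-to-TSS bands out to 1 Mb are all
populated.  Default peak widths follow the marks being emulated: ~500 bp
for narrow (point-source) marks, ~1100 bp for broad domains.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .enrichment import SnpSet, DistanceBand
from .genes import ExpressionMatrix, GeneModel, tss_by_chrom
from .intervals import (Genome, GenomicInterval, PeakSet, StateSegmentation,
                        _merge_array)
from .ldprune import GenotypeMatrix
from .normalization import CountMatrix

import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_peaks",
    "simulate_counts",
    "simulate_snps",
    "simulate_genotypes",
    "simulate_segmentation",
]

STATE_LABELS = [
    "inactive_promoter", "repressed", "no_signal", "hyperchipable",
    "active_enhancer", "permissive", "active_promoter",
]


@dataclass
class MarkConfig:
    name: str
    shape_class: str  # narrow | broad
    mean_width: int   # narrow ≈ 500 bp, broad ≈ 1100 bp


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with study-like defaults."""

    seed: int = 0
    # genome / annotation
    n_chroms: int = 10
    chrom_length_bp: int = 5_000_000
    n_genes: int = 100
    gene_region_fraction: float = 0.5  # genes live in the first half of each chrom
    # marks and replicate structure
    marks: list[MarkConfig] = field(default_factory=lambda: [
        MarkConfig("narrow_mark", "narrow", 500),
        MarkConfig("broad_mark", "broad", 1100),
    ])
    n_tissues: int = 6
    n_animals: int = 3
    # peak skeleton
    peaks_per_chrom: int = 60
    peak_dropout: float = 0.15     # per-sample chance a skeleton peak is missed
    peak_jitter_bp: int = 50       # per-sample edge jitter
    # counts
    nb_dispersion: float = 0.1
    library_size_mean: float = 1_000_000.0
    library_size_sigma: float = 0.2
    # planted effects
    tissue_effect_fold: float = 4.0
    n_db_peaks: int = 40
    db_tissue_index: int = 0
    n_correlated_pairs: int = 30
    target_r: float = 0.9
    n_active_genes: int = 15
    n_inactive_genes: int = 30
    n_tissue_specific: int = 5
    # SNPs
    n_snps: int = 2000
    snp_rho: float = 3.0
    snp_band_rho: dict[int, float] | None = None  # band index → rho (else snp_rho)
    # genotypes / LD
    n_individuals: int = 60
    ld_block_snps: int = 20
    ld_within_r2: float = 0.9
    # segmentation
    mean_state_len: int = 3000
    promoter_state_bias: float = 0.85

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))

    @property
    def sample_names(self) -> list[str]:
        return [f"t{t}_a{a}" for t in range(self.n_tissues)
                for a in range(self.n_animals)]

    @property
    def sample_sheet(self) -> pd.DataFrame:
        rows = [(f"t{t}_a{a}", f"a{a}", f"t{t}")
                for t in range(self.n_tissues) for a in range(self.n_animals)]
        return pd.DataFrame(rows, columns=["sample", "animal", "tissue"])


@dataclass
class GroundTruth:
    """Labels of every planted effect, aligned with the emitted data."""

    db_peaks: list[str] = field(default_factory=list)
    db_tissue: str = ""
    db_fold: float = 1.0
    correlated_pairs: list[tuple[str, str]] = field(default_factory=list)
    target_r: float = 0.0
    active_genes: dict[str, list[str]] = field(default_factory=dict)
    inactive_genes: dict[str, list[str]] = field(default_factory=dict)
    tissue_specific_genes: dict[str, list[str]] = field(default_factory=dict)
    snp_rho: float = 1.0
    snp_band_rho: dict[str, float] = field(default_factory=dict)
    n_snps_in_regions: int = 0
    ld_blocks: list[list[tuple[str, int]]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)


# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig) -> tuple[Genome, list[GeneModel]]:
    """Synthetic genome and non-overlapping gene models with mixed strands.

    Genes occupy the first ``gene_region_fraction`` of each chromosome so
    that large distances to the nearest TSS exist in the remainder.
    """
    rng = config.rng(1)
    genome = Genome.from_sizes(
        [(str(i + 1), config.chrom_length_bp) for i in range(config.n_chroms)])
    if config.n_genes == 0:
        return genome, []
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    region = int(config.chrom_length_bp * config.gene_region_fraction)
    slot = region // per_chrom
    genes: list[GeneModel] = []
    gid = 0
    for ci in range(config.n_chroms):
        chrom = str(ci + 1)
        for k in range(per_chrom):
            if gid >= config.n_genes:
                break
            length = int(rng.integers(2_000, 20_000))
            if length + 10 >= slot:
                raise ValueError("genes don't fit; use a larger genome or fewer genes")
            offset = int(rng.integers(0, slot - length))
            start = k * slot + offset
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{gid:04d}", chrom, start, start + length, strand))
            gid += 1
    return genome, genes


def _skeleton(config: SimConfig, genome: Genome, mark: MarkConfig,
              rng: np.random.Generator) -> list[GenomicInterval]:
    ivs = []
    pid = 0
    for chrom, length in genome.chromosomes:
        slot = length // config.peaks_per_chrom
        for k in range(config.peaks_per_chrom):
            w = max(100, int(rng.normal(mark.mean_width, mark.mean_width / 4)))
            if w + 2 * config.peak_jitter_bp + 10 >= slot:
                w = slot - 2 * config.peak_jitter_bp - 10
            lo = k * slot + config.peak_jitter_bp
            hi = (k + 1) * slot - w - config.peak_jitter_bp
            start = int(rng.integers(lo, max(lo + 1, hi)))
            ivs.append(GenomicInterval(chrom, start, start + w,
                                       name=f"{mark.name}_p{pid:05d}"))
            pid += 1
    return ivs


def simulate_peaks(config: SimConfig, genome: Genome,
                   mark: MarkConfig | None = None,
                   dropout: float | None = None,
                   jitter_bp: int | None = None,
                   ) -> tuple[list[PeakSet], PeakSet]:
    """Per-sample replicate peak sets sharing a latent consensus skeleton.

    Each sample keeps each skeleton peak with probability 1 − dropout and
    jitters both edges by up to ``jitter_bp``, so a min-support-2 consensus
    is non-trivial.  Narrow peaks get a summit sampled inside the interval.
    Returns (per-sample peak sets, skeleton).
    """
    import zlib

    mark = mark or config.marks[0]
    dropout = config.peak_dropout if dropout is None else dropout
    jitter = config.peak_jitter_bp if jitter_bp is None else jitter_bp
    # stable per-mark stream: zlib.crc32 is process-independent, unlike hash()
    rng = config.rng(2 + zlib.crc32(mark.name.encode()) % 1000)
    skeleton = _skeleton(config, genome, mark, rng)
    sizes = genome.sizes
    samples = []
    for s in range(config.n_tissues * config.n_animals):
        ivs = []
        for iv in skeleton:
            if rng.random() < dropout:
                continue
            j1 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            j2 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            start = max(0, iv.start + j1)
            end = min(sizes[iv.chrom], iv.end + j2)
            if end <= start:
                continue
            summit = None
            if mark.shape_class == "narrow":
                summit = int(rng.integers(0, end - start))
            ivs.append(GenomicInterval(iv.chrom, start, end, name=iv.name,
                                       summit=summit))
        samples.append(PeakSet(ivs, shape_class=mark.shape_class,
                               label=f"{mark.name}_s{s}"))
    return samples, PeakSet(skeleton, shape_class=mark.shape_class,
                            label=f"{mark.name}_skeleton")


def _nb(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion φ
    (variance = μ + φ μ²); φ → 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(config: SimConfig, consensus: PeakSet,
                    genes: Sequence[GeneModel]
                    ) -> tuple[CountMatrix, ExpressionMatrix, GroundTruth]:
    """NB peak and gene count matrices with planted effects.

    Planted structure: ``n_db_peaks`` peaks carry ``tissue_effect_fold`` in
    tissue ``db_tissue_index``; ``n_correlated_pairs`` (peak, gene) pairs
    within the 100-kb pairing window share a latent gamma factor whose
    mixing weight is solved analytically so the count-scale Pearson r hits
    ``target_r``; activity-rule genes are drawn so every sample of the
    designated tissue is strictly >200 (active) or <10 (inactive).
    """
    rng = config.rng(3)
    truth = GroundTruth()
    samples = config.sample_names
    sheet = config.sample_sheet
    n_s = len(samples)
    tissue_of = dict(zip(sheet["sample"], sheet["tissue"]))
    focal_tissue = f"t{config.db_tissue_index}"

    libs = config.library_size_mean * np.exp(
        rng.normal(0, config.library_size_sigma, n_s))
    lib_scale = libs / 1e6

    peak_ids = [iv.name or f"peak_{i}" for i, iv in enumerate(consensus)]
    n_p = len(peak_ids)
    base_cpm = np.exp(rng.normal(np.log(50), 0.8, n_p))

    db_idx = rng.choice(n_p, size=min(config.n_db_peaks, n_p), replace=False)
    truth.db_peaks = [peak_ids[i] for i in db_idx]
    truth.db_tissue = focal_tissue
    truth.db_fold = config.tissue_effect_fold

    mean_mat = np.outer(base_cpm, lib_scale)
    focal_cols = np.array([tissue_of[s] == focal_tissue for s in samples])
    mean_mat[np.ix_(db_idx, np.where(focal_cols)[0])] *= config.tissue_effect_fold

    peak_counts = _nb(rng, mean_mat, config.nb_dispersion)

    # gene expression: moderate baseline on a "normalized" scale
    gene_ids = [g.gene_id for g in genes]
    n_g = len(gene_ids)
    gene_base = np.exp(rng.normal(np.log(60), 0.8, n_g))
    gene_counts = _nb(rng, np.tile(gene_base[:, None], (1, n_s)),
                      config.nb_dispersion).astype(float)

    # planted peak-gene correlations via a shared gamma component
    from .expression_link import pair_peaks_genes
    candidate_pairs = pair_peaks_genes(consensus, list(genes), window=100_000)
    rng.shuffle(candidate_pairs)
    used_peaks: set[str] = set()
    used_genes: set[str] = set()
    chosen = []
    for pr in candidate_pairs:
        if pr.peak_id in used_peaks or pr.gene_id in used_genes:
            continue
        chosen.append(pr)
        used_peaks.add(pr.peak_id)
        used_genes.add(pr.gene_id)
        if len(chosen) >= config.n_correlated_pairs:
            break
    truth.correlated_pairs = [(p.peak_id, p.gene_id) for p in chosen]
    truth.target_r = config.target_r

    phi = max(config.nb_dispersion, 1e-6)
    mu_pair = 2000.0  # high mean so Poisson noise is negligible next to φ
    # corr(x, y) = a_shared·φ² / (φ + 1/μ) for Poisson(μ·γ) with γ split into
    # shared + independent Gamma(·, φ) components totalling shape 1/φ
    a_shared = config.target_r * (phi + 1.0 / mu_pair) / phi ** 2
    a_shared = min(a_shared, 1.0 / phi)
    a_ind = 1.0 / phi - a_shared
    peak_pos = {pid: i for i, pid in enumerate(peak_ids)}
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    for pr in chosen:
        g_shared = rng.gamma(a_shared, phi, n_s)
        gx = g_shared + (rng.gamma(a_ind, phi, n_s) if a_ind > 1e-9 else 0.0)
        gy = g_shared + (rng.gamma(a_ind, phi, n_s) if a_ind > 1e-9 else 0.0)
        peak_counts[peak_pos[pr.peak_id]] = rng.poisson(mu_pair * lib_scale * gx)
        gene_counts[gene_pos[pr.gene_id]] = rng.poisson(mu_pair * gy)

    # planted activity-rule genes (never among the correlated pairs)
    free = [g for g in gene_ids if g not in used_genes]
    rng.shuffle(free)
    need = config.n_active_genes + config.n_inactive_genes + config.n_tissue_specific
    if len(free) < need:
        raise ValueError("not enough genes to plant activity labels")
    act = free[:config.n_active_genes]
    inact = free[config.n_active_genes:config.n_active_genes + config.n_inactive_genes]
    tspec = free[config.n_active_genes + config.n_inactive_genes:need]
    focal_mask = np.array([tissue_of[s] == focal_tissue for s in samples])
    for gid in act:  # >200 in every sample of the focal tissue, guaranteed
        row = gene_counts[gene_pos[gid]]
        row[focal_mask] = 201 + _nb(rng, np.full(focal_mask.sum(), 600.0), phi)
    for gid in inact:  # <10 in every focal-tissue sample, guaranteed
        row = gene_counts[gene_pos[gid]]
        row[focal_mask] = np.minimum(rng.poisson(2.0, focal_mask.sum()), 9)
    for gid in tspec:  # active in focal tissue, <10 everywhere else
        row = gene_counts[gene_pos[gid]]
        row[focal_mask] = 201 + _nb(rng, np.full(focal_mask.sum(), 600.0), phi)
        row[~focal_mask] = np.minimum(rng.poisson(2.0, (~focal_mask).sum()), 9)
    truth.active_genes = {focal_tissue: sorted(act + tspec)}
    truth.inactive_genes = {focal_tissue: sorted(inact)}
    truth.tissue_specific_genes = {focal_tissue: sorted(tspec)}

    cm = CountMatrix(pd.DataFrame(peak_counts.astype(np.int64),
                                  index=peak_ids, columns=samples),
                     kind="peak",
                     library_sizes=pd.Series(libs, index=samples))
    em = ExpressionMatrix(pd.DataFrame(gene_counts.astype(np.int64),
                                       index=gene_ids, columns=samples),
                          samples=sheet)
    return cm, em, truth


def _interval_list(merged: dict[str, np.ndarray]) -> list[tuple[str, int, int]]:
    return [(c, int(s), int(e)) for c in sorted(merged)
            for s, e in merged[c]]


def _sample_in_intervals(rng: np.random.Generator,
                         ivs: list[tuple[str, int, int]],
                         n: int) -> list[tuple[str, int]]:
    """n uniform 0-based positions within a list of disjoint intervals."""
    lens = np.array([e - s for _, s, e in ivs], dtype=np.int64)
    cum = np.cumsum(lens)
    u = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right")
    out = []
    for k in range(n):
        c, s, _ = ivs[idx[k]]
        prev = cum[idx[k] - 1] if idx[k] else 0
        out.append((c, int(s + (u[k] - prev))))
    return out


def _intersect_merged(a: dict[str, np.ndarray],
                      b: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for chrom in set(a) & set(b):
        xa, xb = a[chrom], b[chrom]
        i = j = 0
        acc = []
        while i < len(xa) and j < len(xb):
            lo, hi = max(xa[i, 0], xb[j, 0]), min(xa[i, 1], xb[j, 1])
            if hi > lo:
                acc.append((lo, hi))
            if xa[i, 1] < xb[j, 1]:
                i += 1
            else:
                j += 1
        if acc:
            out[chrom] = np.array(acc, dtype=np.int64)
    return out


def simulate_snps(config: SimConfig, genome: Genome, regions: PeakSet,
                  genes: Sequence[GeneModel] | None = None,
                  rho: float | None = None,
                  band_rho: dict[int, float] | None = None,
                  with_pvalues: bool = False) -> tuple[SnpSet, GroundTruth]:
    """SNP positions with a planted fold enrichment ρ inside ``regions``.

    ρ is the target of the fold estimator (C/A)/(B/D): each SNP lands
    inside the region set with probability ρ·A/D and otherwise uniformly
    outside, so the measured fold is unbiased for ρ at any region
    coverage.  With ``band_rho`` (band index → ρ, 100-kb distance-to-TSS
    bands) the boost applies only to region bases within the stated bands;
    bases elsewhere keep background density.  ρ=1 reduces to a uniform
    draw; an empty region set is uniform too.
    """
    rho = config.snp_rho if rho is None else rho
    band_rho = config.snp_band_rho if band_rho is None else band_rho
    rng = config.rng(4)
    autos = list(genome.autosome_names)
    sizes = genome.sizes
    D = genome.total_autosomal_bp
    genome_merged = {c: np.array([[0, sizes[c]]], dtype=np.int64) for c in autos}
    merged = regions.restrict(autos).merged_by_chrom()
    merged = {c: a for c, a in merged.items() if a.size}

    # boosted classes: (interval list, per-SNP probability)
    classes: list[tuple[list[tuple[str, int, int]], float]] = []
    if merged and band_rho:
        if genes is None:
            raise ValueError("band_rho needs gene models for TSS distances")
        tss = tss_by_chrom(list(genes))
        for band_idx, r in sorted(band_rho.items()):
            radius_hi = (band_idx + 1) * 100_000 - 1
            hi_cov = {}
            lo_cov = {}
            for chrom in autos:
                t = tss.get(chrom)
                if t is None or t.size == 0:
                    continue
                hi_cov[chrom] = _merge_array(np.stack(
                    [np.maximum(t - radius_hi, 0),
                     np.minimum(t + radius_hi + 1, sizes[chrom])], axis=1))
                if band_idx > 0:
                    radius_lo = band_idx * 100_000 - 1
                    lo_cov[chrom] = _merge_array(np.stack(
                        [np.maximum(t - radius_lo, 0),
                         np.minimum(t + radius_lo + 1, sizes[chrom])], axis=1))
            band_cov = hi_cov if band_idx == 0 else _subtract_merged(hi_cov, lo_cov)
            boosted = _intersect_merged(merged, band_cov)
            a_bp = sum(int((x[:, 1] - x[:, 0]).sum()) for x in boosted.values())
            if a_bp:
                classes.append((_interval_list(boosted), r * a_bp / D))
    elif merged:
        a_bp = sum(int((x[:, 1] - x[:, 0]).sum()) for x in merged.values())
        classes.append((_interval_list(merged), rho * a_bp / D))

    p_boost = sum(p for _, p in classes)
    if p_boost > 1:
        raise ValueError("planted fold too large for region coverage (ρ·A/D > 1)")
    background = _subtract_merged(
        genome_merged,
        {c: _merge_array(np.concatenate([arr for arr in covs]))
         for c, covs in _group_class_arrays(classes).items()}) \
        if classes else genome_merged

    positions: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    n_inside = 0
    bg_list = _interval_list(background)
    probs = np.array([p for _, p in classes] + [1.0 - p_boost])
    while len(positions) < config.n_snps:
        n_left = config.n_snps - len(positions)
        which = rng.choice(len(probs), size=n_left, p=probs)
        draws: list[tuple[tuple[str, int], bool]] = []
        for ci in range(len(probs)):
            n_c = int((which == ci).sum())
            if n_c == 0:
                continue
            ivs = classes[ci][0] if ci < len(classes) else bg_list
            draws += [(pos, ci < len(classes))
                      for pos in _sample_in_intervals(rng, ivs, n_c)]
        for (chrom, pos0), boosted in draws:
            key = (chrom, pos0 + 1)
            if key in seen:
                continue
            seen.add(key)
            positions.append(key)
            if boosted:
                n_inside += 1
    pvals = list(10 ** rng.uniform(-12, -7, len(positions))) if with_pvalues else None
    truth = GroundTruth(snp_rho=rho,
                        snp_band_rho={str(k): v for k, v in (band_rho or {}).items()},
                        n_snps_in_regions=n_inside)
    return SnpSet(positions, pvals, label="sim_snps"), truth


def _group_class_arrays(classes) -> dict[str, list[np.ndarray]]:
    grouped: dict[str, list[np.ndarray]] = {}
    for ivs, _ in classes:
        for c, s, e in ivs:
            grouped.setdefault(c, []).append(np.array([[s, e]], dtype=np.int64))
    return grouped


def _subtract_merged(a: dict[str, np.ndarray],
                     b: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Set difference a \\ b of merged interval dicts."""
    out: dict[str, np.ndarray] = {}
    for chrom, xa in a.items():
        xb = b.get(chrom)
        if xb is None or xb.size == 0:
            out[chrom] = xa
            continue
        acc = []
        j = 0
        for s, e in xa:
            cur = int(s)
            while j < len(xb) and xb[j, 1] <= cur:
                j += 1
            jj = j
            while jj < len(xb) and xb[jj, 0] < e:
                if xb[jj, 0] > cur:
                    acc.append((cur, int(xb[jj, 0])))
                cur = max(cur, int(xb[jj, 1]))
                jj += 1
            if cur < e:
                acc.append((cur, int(e)))
        if acc:
            out[chrom] = np.array(acc, dtype=np.int64)
    return out


def simulate_genotypes(config: SimConfig, snps: SnpSet) -> tuple[GenotypeMatrix, GroundTruth]:
    """Block-structured dosages: within a block each SNP copies a latent
    haplotype pair with a flip probability solved from the target r²
    (r² = (1 − 2ε)⁴ for dosages); blocks are independent."""
    rng = config.rng(5)
    eps = 0.5 * (1.0 - config.ld_within_r2 ** 0.25)
    n_i = config.n_individuals
    by_chrom: dict[str, list[tuple[str, int]]] = {}
    for p in snps.positions:
        by_chrom.setdefault(p[0], []).append(p)
    rows: list[tuple[str, int]] = []
    dosages: list[np.ndarray] = []
    blocks: list[list[tuple[str, int]]] = []
    for chrom in sorted(by_chrom):
        plist = sorted(by_chrom[chrom], key=lambda p: p[1])
        for b0 in range(0, len(plist), config.ld_block_snps):
            block = plist[b0:b0 + config.ld_block_snps]
            hap = rng.random((2, n_i)) < 0.5  # latent haplotype pair
            blocks.append(block)
            for p in block:
                flips = rng.random((2, n_i)) < eps
                alleles = hap ^ flips
                rows.append(p)
                dosages.append(alleles.sum(axis=0).astype(np.int64))
    truth = GroundTruth(ld_blocks=blocks)
    return GenotypeMatrix(rows, np.array(dosages)), truth


def simulate_segmentation(config: SimConfig, genome: Genome,
                          genes: Sequence[GeneModel],
                          active_gene_ids: Sequence[str] = (),
                          uniform: bool = False) -> StateSegmentation:
    """Tile the genome with 7 chromatin-state labels.

    Promoter windows (2 kb upstream of the TSS) of ``active_gene_ids`` get
    the "active_promoter" label with probability ``promoter_state_bias``;
    the rest of the genome is tiled with exponential-length segments and
    uniform state choice.  ``uniform=True`` disables the promoter bias.
    """
    rng = config.rng(6)
    active = set(active_gene_ids)
    promoters: dict[str, list[tuple[int, int]]] = {}
    if not uniform:
        sizes = genome.sizes
        for g in genes:
            if g.gene_id not in active:
                continue
            if g.strand == "+":
                s, e = max(0, g.tss - 2000), g.tss
            else:
                s, e = g.tss + 1, min(sizes[g.chrom], g.tss + 2001)
            if e > s:
                promoters.setdefault(g.chrom, []).append((s, e))
    segs: list[tuple[GenomicInterval, str]] = []
    for chrom, length in genome.chromosomes:
        proms = sorted(promoters.get(chrom, []))
        cuts = {0, length}
        for s, e in proms:
            cuts.update((s, e))
        pos = 0
        while pos < length:
            nxt = min(pos + max(200, int(rng.exponential(config.mean_state_len))), length)
            in_prom = any(s <= pos < e for s, e in proms)
            if in_prom:
                nxt = min(nxt, next(e for s, e in proms if s <= pos < e))
                if rng.random() < config.promoter_state_bias:
                    label = "active_promoter"
                else:
                    label = STATE_LABELS[int(rng.integers(0, len(STATE_LABELS)))]
            else:
                upcoming = [s for s, _ in proms if s > pos]
                if upcoming:
                    nxt = min(nxt, upcoming[0])
                label = STATE_LABELS[int(rng.integers(0, len(STATE_LABELS)))]
            segs.append((GenomicInterval(chrom, pos, nxt), label))
            pos = nxt
    return StateSegmentation(segs, n_states=len(STATE_LABELS))
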