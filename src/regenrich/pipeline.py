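"""Stage orchestration: simulate → consensus → annotate → diffbind →
correlate → enrich → prune, with a checksum manifest.

Each stage reads only files written by earlier stages (or supplied by the
user), writes TSV/BED/JSON artifacts under the run directory, and records
them in ``manifest.json`` together with the parameters and seed, so a rerun
with the same config is byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffbind, enrichment, expression_link, genes as genes_mod
from .enrichment import DistanceBand, SnpSet, default_bands
from .genes import ExpressionMatrix, read_gene_table, write_gene_table
from .intervals import (Genome, PeakSet, consensus_peaks, read_chrom_sizes,
                        read_peaks, read_segmentation, write_peaks)
from .ldprune import read_genotypes, window_prune
from .normalization import CountMatrix, normalized_cpm, tmm_factors
from .simulate import (SimConfig, simulate_annotation, simulate_counts,
                       simulate_genotypes, simulate_peaks,
                       simulate_segmentation, simulate_snps)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "consensus", "annotate", "diffbind", "correlate",
          "enrich", "prune"]


@dataclass
class PipelineConfig:
    """Thresholds and paths; every default is the analysis's standard value."""

    outdir: str = "regenrich_run"
    seed: int = 0
    active_min: float = 200.0
    inactive_max: float = 10.0
    promoter_bp: int = 2000
    proximal_bp: int = 8000
    pairing_window: int = 100_000
    alpha: float = 0.05
    min_fold: float = 2.0
    band_width: int = 100_000
    n_bands: int = 10
    min_snps: int = 10
    r2_max: float = 0.5
    window_bp: int = 1_000_000
    step_snps: int = 50
    min_support: int = 2
    sim: dict = field(default_factory=dict)  # overrides for SimConfig

    def __post_init__(self):
        for name in ("active_min", "promoter_bp", "proximal_bp",
                     "pairing_window", "alpha", "min_fold", "band_width",
                     "n_bands", "min_snps", "r2_max", "window_bp",
                     "step_snps", "min_support"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def bands(self) -> list[DistanceBand]:
        return default_bands(self.band_width, self.n_bands)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """One run directory; stages append artifacts to the manifest."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": _pkg_version(),
            "seed": config.seed,
            "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                           if k != "outdir"},
            "stages": {},
        }

    def path(self, name: str) -> Path:
        return self.outdir / name

    def require(self, name: str, producer: str) -> Path:
        p = self.path(name)
        if not p.exists():
            raise FileNotFoundError(
                f"missing artifact {name!r}; run the {producer!r} subcommand first")
        return p

    def record(self, stage: str, files: list[Path], n_records: dict | None = None):
        self.manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in sorted(files)},
            "records": n_records or {},
        }
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)

    # ------------------------------------------------------------------
    def stage_simulate(self) -> list[Path]:
        t0 = time.monotonic()
        sim = self.config.sim_config()
        genome, genes = simulate_annotation(sim)
        pd.DataFrame(genome.chromosomes).to_csv(
            self.path("chrom_sizes.tsv"), sep="\t", index=False, header=False)
        write_gene_table(genes, self.path("genes.tsv"))
        mark = sim.marks[0]
        samples, skeleton = simulate_peaks(sim, genome, mark)
        fmt = "narrowPeak" if mark.shape_class == "narrow" else "broadPeak"
        peak_files = []
        for i, ps in enumerate(samples):
            f = self.path(f"peaks_sample{i:02d}.{fmt}")
            write_peaks(ps, f, format=fmt)
            peak_files.append(f)
        consensus = consensus_peaks(samples, min_support=self.config.min_support)
        counts, expr, truth = simulate_counts(sim, consensus, genes)
        counts.to_tsv(self.path("peak_counts.tsv"))
        counts.library_sizes.to_csv(self.path("library_sizes.tsv"), sep="\t",
                                    header=["library_size"])
        expr.counts.to_csv(self.path("gene_counts.tsv"), sep="\t")
        expr.samples.to_csv(self.path("sample_sheet.tsv"), sep="\t", index=False)
        snps, snp_truth = simulate_snps(sim, genome, consensus, genes,
                                        with_pvalues=True)
        pd.DataFrame([(c, p, v) for (c, p), v in
                      zip(snps.positions, snps.p_values)],
                     columns=["chrom", "pos", "pvalue"]).to_csv(
            self.path("snps.tsv"), sep="\t", index=False)
        geno, geno_truth = simulate_genotypes(sim, snps)
        gdf = pd.DataFrame(geno.dosages,
                           columns=[f"ind{i:03d}" for i in range(geno.dosages.shape[1])])
        gdf.insert(0, "pos", [p for _, p in geno.positions])
        gdf.insert(0, "chrom", [c for c, _ in geno.positions])
        gdf.to_csv(self.path("genotypes.tsv"), sep="\t", index=False)
        seg = simulate_segmentation(
            sim, genome, genes,
            active_gene_ids=truth.active_genes.get(truth.db_tissue, []))
        with open(self.path("segmentation.bed"), "w") as fh:
            for iv, lab in seg.segments:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lab}\n")
        truth.snp_rho = snp_truth.snp_rho
        truth.snp_band_rho = snp_truth.snp_band_rho
        truth.n_snps_in_regions = snp_truth.n_snps_in_regions
        truth.ld_blocks = geno_truth.ld_blocks
        truth.to_json(self.path("ground_truth.json"))
        files = peak_files + [self.path(n) for n in (
            "chrom_sizes.tsv", "genes.tsv", "peak_counts.tsv",
            "library_sizes.tsv", "gene_counts.tsv", "sample_sheet.tsv",
            "snps.tsv", "genotypes.tsv", "segmentation.bed",
            "ground_truth.json")]
        self.record("simulate", files,
                    {"genes": len(genes), "samples": len(samples),
                     "snps": len(snps)})
        logger.info("simulate: %d files in %.1fs", len(files), time.monotonic() - t0)
        return files

    def _genome(self) -> Genome:
        return read_chrom_sizes(self.require("chrom_sizes.tsv", "simulate"))

    def _peak_samples(self) -> list[PeakSet]:
        files = sorted(self.outdir.glob("peaks_sample*.narrowPeak")) or \
            sorted(self.outdir.glob("peaks_sample*.broadPeak"))
        if not files:
            raise FileNotFoundError(
                "no per-sample peak files; run the 'simulate' subcommand first")
        fmt = "narrowPeak" if files[0].suffix == ".narrowPeak" else "broadPeak"
        genome = self._genome()
        return [read_peaks(f, format=fmt, genome=genome) for f in files]

    def stage_consensus(self) -> list[Path]:
        t0 = time.monotonic()
        samples = self._peak_samples()
        cons = consensus_peaks(samples, min_support=self.config.min_support)
        f = self.path("consensus.bed")
        write_peaks(cons, f, format="bed")
        self.record("consensus", [f], {"consensus_peaks": len(cons)})
        logger.info("consensus: %d peaks in %.1fs", len(cons), time.monotonic() - t0)
        return [f]

    def _expression(self) -> ExpressionMatrix:
        counts = pd.read_csv(self.require("gene_counts.tsv", "simulate"),
                             sep="\t", index_col=0)
        sheet = pd.read_csv(self.require("sample_sheet.tsv", "simulate"), sep="\t")
        return ExpressionMatrix(counts, sheet)

    def stage_annotate(self) -> list[Path]:
        t0 = time.monotonic()
        genome = self._genome()
        genes = read_gene_table(self.require("genes.tsv", "simulate"))
        expr = self._expression()
        rows = []
        for tissue in expr.tissues:
            calls = genes_mod.classify_gene_activity(
                expr, tissue, self.config.active_min, self.config.inactive_max)
            tspec = set(genes_mod.tissue_specific_active(
                expr, tissue, self.config.active_min, self.config.inactive_max))
            rows += [(c.gene_id, c.tissue, c.status, c.gene_id in tspec)
                     for c in calls]
        act = pd.DataFrame(rows, columns=["gene_id", "tissue", "status",
                                          "tissue_specific"])
        f1 = self.path("activity_calls.tsv")
        act.to_csv(f1, sep="\t", index=False)
        f2, f3 = self.path("promoters.bed"), self.path("proximal.bed")
        write_peaks(genes_mod.build_promoters(genes, genome,
                                              self.config.promoter_bp), f2)
        write_peaks(genes_mod.build_proximal(genes, genome,
                                             self.config.promoter_bp,
                                             self.config.proximal_bp), f3)
        self.record("annotate", [f1, f2, f3],
                    {"active": int((act["status"] == "active").sum()),
                     "inactive": int((act["status"] == "inactive").sum())})
        logger.info("annotate in %.1fs", time.monotonic() - t0)
        return [f1, f2, f3]

    def _peak_counts(self) -> CountMatrix:
        counts = pd.read_csv(self.require("peak_counts.tsv", "simulate"),
                             sep="\t", index_col=0)
        libs = pd.read_csv(self.require("library_sizes.tsv", "simulate"),
                           sep="\t", index_col=0)["library_size"]
        return CountMatrix(counts, kind="peak", library_sizes=libs)

    def stage_diffbind(self) -> list[Path]:
        t0 = time.monotonic()
        counts = self._peak_counts()
        sheet = pd.read_csv(self.require("sample_sheet.tsv", "simulate"), sep="\t")
        factors = tmm_factors(counts)
        frames = []
        for tissue in sorted(sheet["tissue"].unique()):
            res = diffbind.differential_binding_test(
                counts, sheet, tissue, alpha=self.config.alpha,
                min_fold=self.config.min_fold, factors=factors)
            frames.append(diffbind.db_results_frame(res))
        out = pd.concat(frames, ignore_index=True)
        f = self.path("differential_binding.tsv")
        out.to_csv(f, sep="\t", index=False)
        self.record("diffbind", [f],
                    {"tested": len(out), "significant": int(out["significant"].sum())})
        logger.info("diffbind in %.1fs", time.monotonic() - t0)
        return [f]

    def stage_correlate(self) -> list[Path]:
        t0 = time.monotonic()
        genome = self._genome()
        genes = read_gene_table(self.require("genes.tsv", "simulate"))
        cons = read_peaks(self.require("consensus.bed", "consensus"),
                          format="bed", genome=genome)
        counts = self._peak_counts()
        factors = tmm_factors(counts)
        cpm = normalized_cpm(counts, factors)
        expr = self._expression()
        matched = [s for s in cpm.columns if s in expr.counts.columns]
        pairs = expression_link.pair_peaks_genes(cons, genes,
                                                 self.config.pairing_window)
        results = expression_link.correlate_peak_gene(
            pairs, cpm, expr.counts, matched, alpha=self.config.alpha)
        df = pd.DataFrame(
            [(r.pair.peak_id, r.pair.gene_id, r.pair.tss_distance, r.r,
              r.p_value, r.significant) for r in results],
            columns=["peak_id", "gene_id", "distance", "r", "p", "significant"])
        f1 = self.path("peak_gene_correlations.tsv")
        df.to_csv(f1, sep="\t", index=False)
        summ = expression_link.direction_summary(results, self.config.alpha)
        f2 = self.path("correlation_summary.tsv")
        pd.DataFrame([summ]).to_csv(f2, sep="\t", index=False)
        corr = expression_link.correlated_peak_set(results, cons,
                                                   alpha=self.config.alpha)
        f3 = self.path("correlated_peaks.bed")
        write_peaks(corr, f3)
        self.record("correlate", [f1, f2, f3],
                    {"pairs": len(results),
                     "significant": int(df["significant"].sum())})
        logger.info("correlate in %.1fs", time.monotonic() - t0)
        return [f1, f2, f3]

    def stage_enrich(self) -> list[Path]:
        t0 = time.monotonic()
        genome = self._genome()
        genes = read_gene_table(self.require("genes.tsv", "simulate"))
        cons = read_peaks(self.require("consensus.bed", "consensus"),
                          format="bed", genome=genome, label="consensus")
        snps = enrichment.read_snp_table(self.require("snps.tsv", "simulate"),
                                         label="snps")
        region_sets = {"consensus": cons}
        corr_bed = self.path("correlated_peaks.bed")
        if corr_bed.exists():
            region_sets["correlated"] = read_peaks(corr_bed, format="bed",
                                                   genome=genome,
                                                   label="correlated")
        results = [enrichment.snp_enrichment(snps, ps, genome, label=lab)
                   for lab, ps in region_sets.items()]
        rep = enrichment.enrichment_report(results)
        f1 = self.path("enrichment.tsv")
        rep.to_csv(f1, sep="\t", index=False)
        strat = enrichment.distance_stratified_enrichment(
            snps, cons, genes, genome, self.config.bands(),
            min_snps=self.config.min_snps)
        f2 = self.path("enrichment_by_distance.tsv")
        enrichment.enrichment_report(strat).to_csv(f2, sep="\t", index=False)
        files = [f1, f2]
        seg_bed = self.path("segmentation.bed")
        if seg_bed.exists():
            seg = read_segmentation(seg_bed, genome)
            genes_ps = {"promoters": genes_mod.build_promoters(
                genes, genome, self.config.promoter_bp)}
            f3 = self.path("state_enrichment.tsv")
            enrichment.state_overlap_enrichment(seg, genes_ps, genome).to_csv(
                f3, sep="\t", index=False)
            files.append(f3)
        self.record("enrich", files,
                    {"region_sets": len(region_sets), "bands": len(strat)})
        logger.info("enrich in %.1fs", time.monotonic() - t0)
        return files

    def stage_prune(self) -> list[Path]:
        t0 = time.monotonic()
        snps = enrichment.read_snp_table(self.require("snps.tsv", "simulate"),
                                         label="snps")
        geno = read_genotypes(self.require("genotypes.tsv", "simulate"))
        pruned = window_prune(snps, geno, window_bp=self.config.window_bp,
                              step_snps=self.config.step_snps,
                              r2_max=self.config.r2_max)
        f = self.path("snps_pruned.tsv")
        rows = [(c, p) + ((pruned.p_values[i],) if pruned.p_values else ())
                for i, (c, p) in enumerate(pruned.positions)]
        cols = ["chrom", "pos"] + (["pvalue"] if pruned.p_values else [])
        pd.DataFrame(rows, columns=cols).to_csv(f, sep="\t", index=False)
        self.record("prune", [f], {"retained": len(pruned),
                                   "input": len(snps)})
        logger.info("prune in %.1fs", time.monotonic() - t0)
        return [f]

    def run(self, stage: str) -> list[Path]:
        if stage == "all":
            files = []
            for s in STAGES:
                files += self.run(s)
            return files
        fn = getattr(self, f"stage_{stage}", None)
        if fn is None:
            raise ValueError(f"unknown stage {stage!r}")
        return fn()


def _pkg_version() -> str:
    from . import __version__
    return __version__
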