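"""Generators: determinism and recoverability of planted structure."""

import numpy as np
import pytest

from regenrich.enrichment import snp_enrichment
from regenrich.genes import classify_gene_activity
from regenrich.intervals import consensus_peaks, coverage_bp
from regenrich.ldprune import pairwise_r2
from regenrich.simulate import (STATE_LABELS, MarkConfig, SimConfig,
                                simulate_annotation, simulate_counts,
                                simulate_genotypes, simulate_peaks,
                                simulate_segmentation, simulate_snps)


class TestDeterminism:
    def test_annotation_reproducible(self):
        a = simulate_annotation(SimConfig(seed=3))
        b = simulate_annotation(SimConfig(seed=3))
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_counts_and_snps_reproducible(self):
        cfg = SimConfig(seed=4)
        genome, genes = simulate_annotation(cfg)
        s1, _ = simulate_peaks(cfg, genome)
        s2, _ = simulate_peaks(cfg, genome)
        assert [[(iv.chrom, iv.start, iv.end) for iv in ps] for ps in s1] == \
               [[(iv.chrom, iv.start, iv.end) for iv in ps] for ps in s2]
        cons = consensus_peaks(s1, 2)
        cm1, em1, t1 = simulate_counts(cfg, cons, genes)
        cm2, em2, t2 = simulate_counts(cfg, cons, genes)
        assert cm1.counts.equals(cm2.counts)
        assert em1.counts.equals(em2.counts)
        assert t1.db_peaks == t2.db_peaks
        sn1, _ = simulate_snps(cfg, genome, cons)
        sn2, _ = simulate_snps(cfg, genome, cons)
        assert sn1.positions == sn2.positions

    def test_different_seeds_differ(self):
        g1, _ = simulate_annotation(SimConfig(seed=1))
        a = simulate_peaks(SimConfig(seed=1), g1)[0]
        b = simulate_peaks(SimConfig(seed=2), g1)[0]
        assert [(iv.start, iv.end) for iv in a[0]] != \
               [(iv.start, iv.end) for iv in b[0]]


class TestAnnotation:
    def test_gene_count_and_no_overlap(self):
        cfg = SimConfig(seed=0, n_genes=100)
        _, genes = simulate_annotation(cfg)
        assert len(genes) == 100
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gl in by_chrom.values():
            gl.sort(key=lambda g: g.start)
            for a, b in zip(gl, gl[1:]):
                assert a.end <= b.start

    def test_empty_gene_config(self):
        genome, genes = simulate_annotation(SimConfig(seed=0, n_genes=0))
        assert genes == [] and len(genome.names) == 10

    def test_too_many_genes_errors(self):
        with pytest.raises(ValueError, match="larger genome"):
            simulate_annotation(SimConfig(seed=0, n_genes=100,
                                          chrom_length_bp=50_000))


class TestPeaks:
    def test_no_dropout_no_jitter_consensus_is_skeleton(self):
        cfg = SimConfig(seed=1)
        genome, _ = simulate_annotation(cfg)
        samples, skeleton = simulate_peaks(cfg, genome, dropout=0.0,
                                           jitter_bp=0)
        cons = consensus_peaks(samples, 2)
        assert [(iv.chrom, iv.start, iv.end) for iv in cons] == \
               [(iv.chrom, iv.start, iv.end) for iv in skeleton]

    def test_full_dropout_empty_consensus(self):
        cfg = SimConfig(seed=1)
        genome, _ = simulate_annotation(cfg)
        samples, _ = simulate_peaks(cfg, genome, dropout=1.0)
        assert len(consensus_peaks(samples, 2)) == 0

    def test_narrow_peaks_carry_summits(self):
        cfg = SimConfig(seed=1)
        genome, _ = simulate_annotation(cfg)
        samples, _ = simulate_peaks(cfg, genome, cfg.marks[0])
        assert all(iv.summit is not None for iv in samples[0])


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(seed=6)
    genome, genes = simulate_annotation(cfg)
    samples, _ = simulate_peaks(cfg, genome)
    cons = consensus_peaks(samples, 2)
    cm, em, truth = simulate_counts(cfg, cons, genes)
    return cfg, cons, cm, em, truth


class TestCounts:
    def test_planted_active_genes_classified_active(self, sim):
        cfg, cons, cm, em, truth = sim
        tissue = truth.db_tissue
        calls = {c.gene_id: c.status
                 for c in classify_gene_activity(em, tissue)}
        for gid in truth.active_genes[tissue]:
            assert calls[gid] == "active"
        for gid in truth.inactive_genes[tissue]:
            assert calls[gid] == "inactive"

    def test_planted_correlations_near_target(self):
        # mean realized count-scale r within 0.05 of the 0.9 target
        # (Fisher-z SE at n=18 over ≥300 pairs is well under 0.02)
        cfg = SimConfig(seed=7, n_genes=900, n_correlated_pairs=400,
                        n_active_genes=5, n_inactive_genes=5,
                        n_tissue_specific=2, peaks_per_chrom=100)
        genome, genes = simulate_annotation(cfg)
        samples, _ = simulate_peaks(cfg, genome)
        cons = consensus_peaks(samples, 2)
        cm, em, truth = simulate_counts(cfg, cons, genes)
        assert len(truth.correlated_pairs) >= 300
        lib = cm.library_sizes
        cpm = cm.counts.div(lib / 1e6, axis=1)
        rs = []
        for pk, gn in truth.correlated_pairs:
            rs.append(np.corrcoef(cpm.loc[pk], em.counts.loc[gn])[0, 1])
        assert np.mean(rs) == pytest.approx(0.9, abs=0.05)


class TestSnps:
    def test_rho_one_is_uniform(self):
        cfg = SimConfig(seed=8, n_snps=5000)
        genome, genes = simulate_annotation(cfg)
        samples, _ = simulate_peaks(cfg, genome)
        cons = consensus_peaks(samples, 2)
        snps, _ = simulate_snps(cfg, genome, cons, rho=1.0)
        res = snp_enrichment(snps, cons, genome)
        assert res.fold == pytest.approx(1.0, abs=0.35)  # B·A/D ≈ 35 ⇒ sd≈0.17

    def test_empty_regions_uniform(self):
        from regenrich.intervals import PeakSet
        cfg = SimConfig(seed=8, n_snps=100)
        genome, _ = simulate_annotation(cfg)
        snps, truth = simulate_snps(cfg, genome, PeakSet([], shape_class="broad"))
        assert len(snps) == 100
        assert truth.n_snps_in_regions == 0

    def test_positions_unique_and_in_bounds(self):
        cfg = SimConfig(seed=9, n_snps=2000)
        genome, _ = simulate_annotation(cfg)
        samples, _ = simulate_peaks(cfg, genome)
        cons = consensus_peaks(samples, 2)
        snps, _ = simulate_snps(cfg, genome, cons)
        assert len(set(snps.positions)) == len(snps)
        sizes = genome.sizes
        for c, p in snps.positions:
            assert 1 <= p <= sizes[c]


class TestGenotypes:
    def test_zero_flip_gives_unit_r2_within_block(self):
        cfg = SimConfig(seed=10, ld_within_r2=1.0, n_individuals=40)
        snps_pos = [("1", 100 + i) for i in range(20)]
        from regenrich.enrichment import SnpSet
        geno, truth = simulate_genotypes(cfg, SnpSet(snps_pos))
        row = geno.row_index()
        blk = truth.ld_blocks[0]
        r2 = pairwise_r2(geno.dosages[row[tuple(blk[0])]],
                         geno.dosages[row[tuple(blk[1])]])
        assert r2 == pytest.approx(1.0)

    def test_cross_block_r2_near_independence(self):
        cfg = SimConfig(seed=11, n_individuals=50, ld_block_snps=10)
        from regenrich.enrichment import SnpSet
        pos = [("1", 100 + i * 10) for i in range(100)]
        geno, truth = simulate_genotypes(cfg, SnpSet(pos))
        row = geno.row_index()
        rng = np.random.default_rng(0)
        r2s = []
        for _ in range(200):
            b1, b2 = rng.choice(len(truth.ld_blocks), 2, replace=False)
            p1 = tuple(truth.ld_blocks[b1][int(rng.integers(10))])
            p2 = tuple(truth.ld_blocks[b2][int(rng.integers(10))])
            r2s.append(pairwise_r2(geno.dosages[row[p1]], geno.dosages[row[p2]]))
        # E[r²] ≈ 1/n_individuals for independent vectors
        assert np.mean(r2s) == pytest.approx(1 / 50, abs=0.015)


class TestSegmentation:
    def test_full_tiling(self):
        cfg = SimConfig(seed=12)
        genome, genes = simulate_annotation(cfg)
        seg = simulate_segmentation(cfg, genome, genes, uniform=True)
        covered = sum(iv.end - iv.start for iv, _ in seg.segments)
        assert covered == genome.total_autosomal_bp

    def test_uniform_placement_folds_near_one(self):
        from regenrich.enrichment import state_overlap_enrichment
        from regenrich.genes import build_promoters
        cfg = SimConfig(seed=13, mean_state_len=1000)
        genome, genes = simulate_annotation(cfg)
        seg = simulate_segmentation(cfg, genome, genes, uniform=True)
        ann = {"promoters": build_promoters(genes, genome)}
        df = state_overlap_enrichment(seg, ann, genome)
        assert np.nanmax(np.abs(df["fold"] - 1.0)) < 0.5

    def test_promoter_bias_enriches_active_promoter_state(self):
        from regenrich.enrichment import state_overlap_enrichment
        from regenrich.genes import build_promoters
        cfg = SimConfig(seed=14)
        genome, genes = simulate_annotation(cfg)
        active = [g.gene_id for g in genes[:30]]
        seg = simulate_segmentation(cfg, genome, genes, active_gene_ids=active)
        ann = {"active_promoters": build_promoters(
            [g for g in genes if g.gene_id in set(active)], genome)}
        df = state_overlap_enrichment(seg, ann, genome)
        cell = df[(df.state == "active_promoter")].iloc[0]
        assert cell.fold > 2.0
        assert set(df["state"]) == set(STATE_LABELS)
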