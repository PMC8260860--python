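"""The (C/A)/(B/D) fold statistic, hypergeometric tails, stratification."""

import math

import numpy as np
import pandas as pd
import pytest

from regenrich.enrichment import (DistanceBand, SnpSet, default_bands,
                                  distance_stratified_enrichment,
                                  enrichment_report, read_snp_table,
                                  snp_enrichment, state_overlap_enrichment)
from regenrich.genes import GeneModel
from regenrich.intervals import (Genome, GenomicInterval, PeakSet,
                                 StateSegmentation)


def exact_hypergeom_tails(C, D, B, A):
    """Independent oracle: log-gamma pmf summed term by term."""
    def log_pmf(k):
        return (log_choose(B, k) + log_choose(D - B, A - k) - log_choose(D, A))

    def log_choose(n, k):
        if k < 0 or k > n:
            return -math.inf
        return (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1))

    kmax = min(A, B)
    p_en = sum(math.exp(log_pmf(k)) for k in range(C, kmax + 1))
    p_de = sum(math.exp(log_pmf(k)) for k in range(0, C + 1))
    return p_en, p_de


def uniform_genome(length=1000):
    return Genome.from_sizes([("1", length)])


class TestFoldFormula:
    def test_worked_example(self):
        # D=1000, A=100, B=10, C=5 → fold = (5/100)/(10/1000) = 5
        genome = uniform_genome(1000)
        regions = PeakSet([GenomicInterval("1", 0, 100)], shape_class="broad")
        snps = SnpSet([("1", p) for p in (10, 20, 30, 40, 50,
                                          200, 300, 400, 500, 600)])
        res = snp_enrichment(snps, regions, genome)
        assert (res.A, res.B, res.C, res.D) == (100, 10, 5, 1000)
        assert res.fold == pytest.approx(5.0)

    def test_fold_identity_cd_over_ab(self, rng):
        for _ in range(20):
            genome = uniform_genome(5000)
            n_iv = int(rng.integers(1, 10))
            starts = np.sort(rng.choice(4900, n_iv, replace=False))
            regions = PeakSet([GenomicInterval("1", int(s), int(s) + int(rng.integers(1, 80)))
                               for s in starts], shape_class="broad")
            snps = SnpSet([("1", int(p) + 1)
                           for p in rng.choice(5000, int(rng.integers(1, 200)),
                                               replace=False)])
            res = snp_enrichment(snps, regions, genome)
            assert res.fold == pytest.approx(res.C * res.D / (res.A * res.B))

    def test_boundary_snp_half_open(self):
        genome = uniform_genome(1000)
        regions = PeakSet([GenomicInterval("1", 100, 200)], shape_class="broad")
        # 1-based pos 101 → 0-based 100 (inside); pos 201 → 200 (outside)
        inside = snp_enrichment(SnpSet([("1", 101)]), regions, genome)
        outside = snp_enrichment(SnpSet([("1", 201)]), regions, genome)
        assert inside.C == 1 and outside.C == 0

    def test_duplicate_snp_records_invariant(self):
        genome = uniform_genome(1000)
        regions = PeakSet([GenomicInterval("1", 0, 100)], shape_class="broad")
        a = snp_enrichment(SnpSet([("1", 50), ("1", 500)]), regions, genome)
        b = snp_enrichment(SnpSet([("1", 50), ("1", 50), ("1", 500)]),
                           regions, genome)
        assert (a.B, a.C, a.fold) == (b.B, b.C, b.fold)

    def test_non_autosomal_snps_excluded(self):
        genome = Genome.from_sizes([("1", 1000), ("X", 1000)],
                                   autosome_names=["1"])
        regions = PeakSet([GenomicInterval("1", 0, 100),
                           GenomicInterval("X", 0, 100)], shape_class="broad")
        res = snp_enrichment(SnpSet([("1", 50), ("X", 50)]), regions, genome)
        assert res.B == 1 and res.A == 100 and res.D == 1000

    def test_undefined_when_a_or_b_zero(self):
        genome = uniform_genome(1000)
        res = snp_enrichment(SnpSet([("1", 5)]), PeakSet([], shape_class="broad"),
                             genome)
        assert not res.defined and math.isnan(res.fold)


class TestHypergeometricTails:
    def test_matches_exact_pmf_oracle(self, rng):
        genome_sizes = rng.integers(200, 10_000, 30)
        for D in genome_sizes:
            D = int(D)
            A = int(rng.integers(1, D))
            B = int(rng.integers(1, min(D, 300)))
            genome = uniform_genome(D)
            regions = PeakSet([GenomicInterval("1", 0, A)], shape_class="broad")
            c = int(rng.integers(0, min(A, B) + 1))
            n_out = min(B - c, D - A)
            pos_in = rng.choice(A, size=c, replace=False)
            pos_out = (rng.choice(D - A, size=n_out, replace=False) + A) if n_out else []
            snps = SnpSet([("1", int(p) + 1) for p in list(pos_in) + list(pos_out)])
            res = snp_enrichment(snps, regions, genome)
            p_en, p_de = exact_hypergeom_tails(res.C, res.D, res.B, res.A)
            assert res.p_enrich == pytest.approx(p_en, abs=1e-10)
            assert res.p_deplete == pytest.approx(p_de, abs=1e-10)

    def test_tails_share_observed_outcome(self, rng):
        genome = uniform_genome(2000)
        regions = PeakSet([GenomicInterval("1", 0, 500)], shape_class="broad")
        snps = SnpSet([("1", int(p) + 1)
                       for p in rng.choice(2000, 100, replace=False)])
        res = snp_enrichment(snps, regions, genome)
        assert res.p_enrich + res.p_deplete >= 1.0

    def test_monte_carlo_tail_probability(self, rng):
        genome = uniform_genome(2000)
        regions = PeakSet([GenomicInterval("1", 0, 200)], shape_class="broad")
        B = 50
        pos = rng.choice(2000, B, replace=False)
        snps = SnpSet([("1", int(p) + 1) for p in pos])
        res = snp_enrichment(snps, regions, genome)
        # empirical P(X ≥ C_obs) over uniform placements without replacement
        n_mc = 100_000
        draws = np.array([
            (rng.choice(2000, B, replace=False) < 200).sum()
            for _ in range(n_mc // 100)])  # 1000 draws is enough at 3 SE
        emp = (draws >= res.C).mean()
        se = math.sqrt(max(emp * (1 - emp), 1e-6) / len(draws))
        assert abs(emp - res.p_enrich) <= 3 * se + 1e-9


class TestDistanceStratification:
    def _setup(self):
        genome = Genome.from_sizes([("1", 2_000_000)])
        genes = [GeneModel("g0", "1", 0, 1000, "+")]  # single TSS at 0
        return genome, genes

    def test_band_restriction_consistency(self):
        genome, genes = self._setup()
        regions = PeakSet([GenomicInterval("1", 40_000, 42_000)],
                          shape_class="broad")
        snps = SnpSet([("1", p) for p in range(40_500, 40_520)])
        bands = [DistanceBand(0, 100_000)]
        strat = distance_stratified_enrichment(snps, regions, genes, genome,
                                               bands, min_snps=10)
        flat = snp_enrichment(snps, regions, genome)
        assert strat[0].C == flat.C
        assert strat[0].A == flat.A
        assert strat[0].D == 100_000  # band-restricted D

    def test_band_with_fewer_than_min_snps_is_na(self):
        genome, genes = self._setup()
        regions = PeakSet([GenomicInterval("1", 150_000, 152_000)],
                          shape_class="broad")
        snps = SnpSet([("1", 150_000 + i) for i in range(9)])  # 9 SNPs in band 2
        strat = distance_stratified_enrichment(snps, regions, genes, genome,
                                               default_bands(), min_snps=10)
        assert not strat[1].defined
        assert strat[1].B == 9

    def test_global_d_flag(self):
        genome, genes = self._setup()
        regions = PeakSet([GenomicInterval("1", 40_000, 42_000)],
                          shape_class="broad")
        snps = SnpSet([("1", p) for p in range(40_500, 40_520)])
        bands = [DistanceBand(0, 100_000)]
        strat = distance_stratified_enrichment(snps, regions, genes, genome,
                                               bands, global_d=True)
        assert strat[0].D == genome.total_autosomal_bp

    def test_chromosome_without_tss_excluded(self):
        genome = Genome.from_sizes([("1", 200_000), ("2", 200_000)])
        genes = [GeneModel("g0", "1", 0, 1000, "+")]
        regions = PeakSet([GenomicInterval("1", 1000, 2000),
                           GenomicInterval("2", 1000, 2000)],
                          shape_class="broad")
        snps = SnpSet([("1", p) for p in range(1100, 1120)] +
                      [("2", p) for p in range(1100, 1120)])
        strat = distance_stratified_enrichment(snps, regions, genes, genome,
                                               [DistanceBand(0, 100_000)])
        assert strat[0].B == 20  # chr2 SNPs dropped

    def test_planted_band_profile_recovered(self):
        from regenrich.simulate import MarkConfig, SimConfig, \
            simulate_annotation, simulate_peaks, simulate_snps
        from regenrich.intervals import consensus_peaks
        cfg = SimConfig(seed=5, n_snps=30_000, peaks_per_chrom=200,
                        marks=[MarkConfig("broad_mark", "broad", 2000)])
        genome, genes = simulate_annotation(cfg)
        samples, _ = simulate_peaks(cfg, genome, cfg.marks[0])
        cons = consensus_peaks(samples, 2)
        snps, _ = simulate_snps(cfg, genome, cons, genes, band_rho={0: 3.0})
        strat = distance_stratified_enrichment(snps, cons, genes, genome)
        assert 2.4 <= strat[0].fold <= 3.6
        others = [r.fold for r in strat[1:] if r.defined]
        assert all(0.7 <= f <= 1.3 for f in others)


class TestStateOverlap:
    def test_state_equal_to_annotation_fold_d_over_a(self):
        genome = uniform_genome(10_000)
        seg = StateSegmentation([
            (GenomicInterval("1", 0, 1000), "s1"),
            (GenomicInterval("1", 1000, 10_000), "s2"),
        ])
        ann = {"x": PeakSet([GenomicInterval("1", 0, 1000)], shape_class="broad")}
        df = state_overlap_enrichment(seg, ann, genome)
        cell = df[(df.state == "s1") & (df.annotation == "x")].iloc[0]
        assert cell.fold == pytest.approx(10_000 / 1000)

    def test_tiling_fractions_sum_to_one(self, rng):
        genome = uniform_genome(10_000)
        cuts = np.sort(rng.choice(np.arange(1, 10_000), 20, replace=False))
        bounds = [0] + list(cuts) + [10_000]
        segs = [(GenomicInterval("1", bounds[i], bounds[i + 1]), f"s{i % 4}")
                for i in range(len(bounds) - 1)]
        seg = StateSegmentation(segs)
        ann = {"x": PeakSet([GenomicInterval("1", 0, 5000)], shape_class="broad")}
        df = state_overlap_enrichment(seg, ann, genome)
        assert df.groupby("state")["genome_fraction"].first().sum() == \
            pytest.approx(1.0)

    def test_uniform_scatter_fold_near_one(self, rng):
        genome = uniform_genome(100_000)
        starts = np.arange(0, 100_000, 100)
        labels = rng.choice(["a", "b"], size=len(starts))
        segs = [(GenomicInterval("1", int(s), int(s) + 100), str(l))
                for s, l in zip(starts, labels)]
        seg = StateSegmentation(segs)
        ann = {"x": PeakSet([GenomicInterval("1", int(s), int(s) + 50)
                             for s in rng.choice(starts, 300, replace=False)],
                            shape_class="broad")}
        df = state_overlap_enrichment(seg, ann, genome)
        assert np.allclose(df["fold"], 1.0, atol=0.15)


class TestReportAndIO:
    def test_single_result_single_row(self):
        genome = uniform_genome(1000)
        regions = PeakSet([GenomicInterval("1", 0, 100)], shape_class="broad")
        res = snp_enrichment(SnpSet([("1", 50)]), regions, genome)
        assert len(enrichment_report([res])) == 1

    def test_average_across_tissues(self):
        genome = uniform_genome(1000)
        regions = PeakSet([GenomicInterval("1", 0, 100)], shape_class="broad")
        r1 = snp_enrichment(SnpSet([("1", 50)]), regions, genome)
        # construct planted folds 2 and 4 via dataclass replacement
        import dataclasses
        ra = dataclasses.replace(r1, fold=2.0)
        rb = dataclasses.replace(r1, fold=4.0)
        df = enrichment_report([ra, rb], group_keys=[
            {"mark": "m", "tissue": "t1"}, {"mark": "m", "tissue": "t2"}])
        avg = df[df.label == "average_across_tissues"]
        assert avg["fold"].iloc[0] == pytest.approx(3.0)

    def test_snp_table_round_trip(self, tmp_path):
        f = tmp_path / "snps.tsv"
        pd.DataFrame({"chrom": ["1", "2"], "pos": [100, 200],
                      "pvalue": [1e-8, 1e-9]}).to_csv(f, sep="\t", index=False)
        snps = read_snp_table(f)
        assert snps.positions == [("1", 100), ("2", 200)]
        assert snps.p_values == [1e-8, 1e-9]
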