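"""Distance-to-TSS stratified enrichment.

Both regulatory peaks and trait-associated variants cluster near genes, so
raw enrichment could simply reflect shared proximity to TSS.  Stratifying
into 100-kb bands of distance from the nearest TSS (out to 1 Mb) tests
enrichment within each band separately: peaks enter a band by their anchor
(summit or midpoint), SNPs by their own distance, and D is restricted to
the genome at that distance.  Bands with fewer than 10 SNPs are NA.

Here the SNP excess (fold 3) is planted only inside peaks within 100 kb of
a TSS, so band 1 shows enrichment and the far bands stay at 1.
"""

from regenrich import (SimConfig, consensus_peaks, default_bands,
                       distance_stratified_enrichment, simulate_annotation,
                       simulate_peaks, simulate_snps)
from regenrich.simulate import MarkConfig

cfg = SimConfig(seed=3, n_snps=50_000, peaks_per_chrom=200,
                marks=[MarkConfig("broad_mark", "broad", 2000)])
genome, genes = simulate_annotation(cfg)
samples, _ = simulate_peaks(cfg, genome, cfg.marks[0])
consensus = consensus_peaks(samples, min_support=2)
snps, _ = simulate_snps(cfg, genome, consensus, genes, band_rho={0: 3.0})

results = distance_stratified_enrichment(snps, consensus, genes, genome,
                                         default_bands(), min_snps=10)
print(f"{'band (kb)':>12} {'B':>7} {'C':>6} {'fold':>6}")
for band, r in zip(default_bands(), results):
    fold = f"{r.fold:.2f}" if r.defined else "NA"
    print(f"{band.lower // 1000:>5}-{band.upper // 1000:<6} {r.B:>7} "
          f"{r.C:>6} {fold:>6}")
# Band 0-100 kb recovers the planted enrichment; every other band sits
# near fold 1, showing the statistic is not confounded by TSS proximity.
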