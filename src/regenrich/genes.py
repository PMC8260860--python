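"""Gene models, TSS extraction, RNA-based activity calls and upstream regions.

Genes are classified per tissue from a normalized count matrix: *active*
when every sample of that tissue exceeds ``active_min`` (default 200),
*inactive* when every sample is below ``inactive_max`` (default 10),
*ambiguous* otherwise.  Tissue-specific active genes are active in the focal
tissue and below ``inactive_max`` in every sample of every other tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import Genome, GenomicInterval, PeakSet

__all__ = [
    "GeneModel",
    "ExpressionMatrix",
    "ActivityCall",
    "read_gene_table",
    "read_gtf_genes",
    "write_gene_table",
    "tss_by_chrom",
    "classify_gene_activity",
    "tissue_specific_active",
    "build_promoters",
    "build_proximal",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene: coordinates, strand and the derived TSS.

    The TSS is ``start`` on the + strand and ``end − 1`` on the − strand
    (0-based half-open coordinates).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start ≥ end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class ExpressionMatrix:
    """Genes × samples normalized counts with (animal, tissue) metadata.

    ``counts`` index = gene_id, columns = sample names; ``samples`` must map
    every column to exactly one (animal, tissue).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame  # columns: sample, animal, tissue

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative expression counts")
        req = {"sample", "animal", "tissue"}
        if not req <= set(self.samples.columns):
            raise ValueError(f"sample sheet needs columns {sorted(req)}")
        if self.samples["sample"].duplicated().any():
            raise ValueError("duplicate sample names in sample sheet")
        missing = set(self.counts.columns) - set(self.samples["sample"])
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())

    def tissue_samples(self, tissue: str) -> list[str]:
        hits = self.samples.loc[self.samples["tissue"] == tissue, "sample"].tolist()
        if not hits:
            raise ValueError(f"tissue {tissue!r} absent from sample sheet")
        return [s for s in hits if s in self.counts.columns]


@dataclass(frozen=True)
class ActivityCall:
    gene_id: str
    tissue: str
    status: str  # active | inactive | ambiguous
    tissue_specific: bool = False


# ---------------------------------------------------------------------------
# I/O

def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a minimal 5-column TSV: gene_id, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    req = ["gene_id", "chrom", "start", "end", "strand"]
    if not set(req) <= set(df.columns):
        raise ValueError(f"gene table needs columns {req}")
    return [GeneModel(r.gene_id, str(r.chrom), int(r.start), int(r.end), r.strand)
            for r in df.itertuples()]


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_gtf_genes(path: str | Path, strip_chr: bool = True) -> list[GeneModel]:
    """Extract gene-level models from a GTF (Ensembl dialect, 1-based).

    When transcripts are annotated, the gene TSS is the 5'-most transcript
    start on the gene's strand; gffutils does the parsing.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        chrom = g.seqid[3:] if strip_chr and g.seqid.lower().startswith("chr") else g.seqid
        start0, end = g.start - 1, g.end  # GTF is 1-based inclusive
        tx_starts = [(t.start - 1, t.end) for t in db.children(g, featuretype="transcript")]
        if tx_starts:
            if g.strand == "+":
                start0 = min(s for s, _ in tx_starts)
            else:
                end = max(e for _, e in tx_starts)
        gid = g.attributes.get("gene_id", [g.id])[0]
        genes.append(GeneModel(gid, chrom, start0, end, g.strand))
    return genes


def tss_by_chrom(genes: Sequence[GeneModel]) -> dict[str, np.ndarray]:
    """Sorted TSS positions per chromosome."""
    out: dict[str, list[int]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g.tss)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in out.items()}


# ---------------------------------------------------------------------------
# Activity classification

def classify_gene_activity(expr: ExpressionMatrix, tissue: str,
                           active_min: float = 200.0,
                           inactive_max: float = 10.0) -> list[ActivityCall]:
    """Per-gene activity in one tissue from the all-samples threshold rule.

    Active: count > ``active_min`` in ALL samples of the tissue (strict).
    Inactive: count < ``inactive_max`` in ALL samples (strict).
    Anything else is ambiguous.
    """
    cols = expr.tissue_samples(tissue)
    sub = expr.counts[cols]
    active = (sub > active_min).all(axis=1)
    inactive = (sub < inactive_max).all(axis=1)
    calls = []
    for gene_id in expr.counts.index:
        if active[gene_id]:
            status = "active"
        elif inactive[gene_id]:
            status = "inactive"
        else:
            status = "ambiguous"
        calls.append(ActivityCall(gene_id, tissue, status))
    return calls


def tissue_specific_active(expr: ExpressionMatrix, tissue: str,
                           active_min: float = 200.0,
                           inactive_max: float = 10.0) -> list[str]:
    """Genes active in the focal tissue and below the inactive threshold
    in every sample of every other tissue."""
    if len(expr.tissues) < 2:
        raise ValueError("tissue specificity needs ≥2 tissues")
    focal = expr.tissue_samples(tissue)
    others = [s for s in expr.counts.columns if s not in focal]
    active = (expr.counts[focal] > active_min).all(axis=1)
    silent_elsewhere = (expr.counts[others] < inactive_max).all(axis=1)
    mask = active & silent_elsewhere
    return list(expr.counts.index[mask])


# ---------------------------------------------------------------------------
# Upstream regions

def _upstream_window(g: GeneModel, offset: int, width: int,
                     chrom_len: int) -> tuple[int, int] | None:
    """Window of ``width`` bp starting ``offset`` bp upstream of the TSS,
    extending further upstream; clipped to [0, chrom_len)."""
    if g.strand == "+":
        end = g.tss - offset
        start = end - width
    else:
        start = g.tss + 1 + offset
        end = start + width
    start, end = max(0, start), min(chrom_len, end)
    if end <= start:
        return None
    return start, end


def build_promoters(genes: Sequence[GeneModel], genome: Genome,
                    promoter_bp: int = 2000) -> PeakSet:
    """Promoters: the ``promoter_bp`` (default 2 kb) immediately upstream of
    each TSS, strand-aware, clipped to chromosome bounds."""
    sizes = genome.sizes
    ivs = []
    for g in genes:
        w = _upstream_window(g, 0, promoter_bp, sizes[g.chrom])
        if w is not None:
            ivs.append(GenomicInterval(g.chrom, w[0], w[1], name=g.gene_id))
    return PeakSet(ivs, shape_class="broad", label="promoters")


def build_proximal(genes: Sequence[GeneModel], genome: Genome,
                   promoter_bp: int = 2000, proximal_bp: int = 8000) -> PeakSet:
    """Proximal regions: ``proximal_bp`` (default 8 kb) immediately upstream
    of the promoter's upstream edge; never overlaps the promoter."""
    sizes = genome.sizes
    ivs = []
    for g in genes:
        w = _upstream_window(g, promoter_bp, proximal_bp, sizes[g.chrom])
        if w is not None:
            ivs.append(GenomicInterval(g.chrom, w[0], w[1], name=g.gene_id))
    return PeakSet(ivs, shape_class="broad", label="proximal")
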