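"""Genome model and interval arithmetic for ChIP-seq peak sets.

Coordinates are 0-based half-open (BED convention) everywhere internally.
1-based inputs (SNP tables, GTF) are converted at the reader boundary.
Peaks are strand-less; gene strand only matters in :mod:`regenrich.genes`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Genome",
    "GenomicInterval",
    "PeakSet",
    "StateSegmentation",
    "read_chrom_sizes",
    "read_peaks",
    "write_peaks",
    "read_segmentation",
    "coverage_bp",
    "merge_intervals",
    "consensus_peaks",
    "peak_anchor",
    "peak_anchors",
    "distance_to_nearest_tss",
    "intersect_bp",
]


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome sizes plus the autosome subset used for enrichment.

    ``autosome_names`` defaults to every chromosome; the bovine analysis uses
    autosomes named "1".."29" and computes the genome size D as their sum.
    """

    chromosomes: tuple[tuple[str, int], ...]
    autosome_names: tuple[str, ...] = ()

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for n, ln in self.chromosomes:
            if ln <= 0:
                raise ValueError(f"chromosome {n} has non-positive length {ln}")
        if not self.autosome_names:
            object.__setattr__(self, "autosome_names", tuple(names))
        unknown = set(self.autosome_names) - set(names)
        if unknown:
            raise ValueError(f"autosome_names not in genome: {sorted(unknown)}")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def total_autosomal_bp(self) -> int:
        """Genome size D: sum of autosome lengths."""
        s = self.sizes
        return int(sum(s[n] for n in self.autosome_names))

    @classmethod
    def from_sizes(cls, sizes: dict[str, int] | Sequence[tuple[str, int]],
                   autosome_names: Sequence[str] = ()) -> "Genome":
        items = tuple(sizes.items()) if isinstance(sizes, dict) else tuple(sizes)
        return cls(chromosomes=items, autosome_names=tuple(autosome_names))


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on one chromosome.

    ``summit`` is an offset from ``start`` (narrowPeak column-10 semantics);
    it is ``None`` for broad peaks and plain BED records.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    summit: int | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValueError(
                f"summit offset {self.summit} outside interval of length "
                f"{self.end - self.start}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """A sorted collection of intervals for one sample / mark / region class.

    Intervals may overlap in storage; coverage counts each base once.
    ``shape_class`` decides the anchor: summit for "narrow", midpoint for
    "broad".
    """

    intervals: list[GenomicInterval]
    shape_class: str = "narrow"
    label: str = ""

    def __post_init__(self):
        if self.shape_class not in ("narrow", "broad"):
            raise ValueError(f"shape_class must be narrow|broad, got {self.shape_class!r}")
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """(n, 2) start/end arrays keyed by chromosome, sorted by start."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.array(v, dtype=np.int64) for c, v in out.items()}

    def merged_by_chrom(self) -> dict[str, np.ndarray]:
        return {c: _merge_array(a) for c, a in self.by_chrom().items()}

    def restrict(self, chrom_names: Iterable[str]) -> "PeakSet":
        keep = set(chrom_names)
        return PeakSet([iv for iv in self.intervals if iv.chrom in keep],
                       shape_class=self.shape_class, label=self.label)


@dataclass
class StateSegmentation:
    """A chromatin-state tiling: non-overlapping labelled segments."""

    segments: list[tuple[GenomicInterval, str]]
    n_states: int = 0

    def __post_init__(self):
        self.segments = sorted(self.segments, key=lambda s: (s[0].chrom, s[0].start))
        labels = {lab for _, lab in self.segments}
        if not self.n_states:
            self.n_states = len(labels)
        prev: dict[str, int] = {}
        for iv, _ in self.segments:
            if iv.start < prev.get(iv.chrom, 0):
                raise ValueError(f"overlapping segments on {iv.chrom} at {iv.start}")
            prev[iv.chrom] = iv.end

    @property
    def state_labels(self) -> list[str]:
        return sorted({lab for _, lab in self.segments})

    def state_peakset(self, label: str) -> PeakSet:
        return PeakSet([iv for iv, lab in self.segments if lab == label],
                       shape_class="broad", label=label)


# ---------------------------------------------------------------------------
# I/O

def read_chrom_sizes(path: str | Path, autosome_names: Sequence[str] = ()) -> Genome:
    """Read a 2-column TSV (name, length) into a :class:`Genome`."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str})
    return Genome.from_sizes([(r.chrom, int(r.length)) for r in df.itertuples()],
                             autosome_names=autosome_names)


_N_COLS = {"bed": 3, "narrowPeak": 10, "broadPeak": 9}


def _normalize_chrom(name: str, strip_chr: bool) -> str:
    return name[3:] if strip_chr and name.lower().startswith("chr") else name


def read_peaks(path: str | Path, format: str = "narrowPeak",
               genome: Genome | None = None, *, label: str = "",
               strip_chr: bool = True,
               on_unknown_chrom: str = "error") -> PeakSet:
    """Read a BED / ENCODE narrowPeak / broadPeak file into a PeakSet.

    narrowPeak column 10 (point-source offset) populates ``summit`` when
    ≥ 0.  ``on_unknown_chrom`` is "error" or "skip" (skips with a log line).
    Malformed lines and intervals beyond the chromosome end raise
    ``ValueError`` naming the line number.
    """
    if format not in _N_COLS:
        raise ValueError(f"unknown format {format!r}")
    min_cols = _N_COLS[format]
    shape = "broad" if format == "broadPeak" else "narrow"
    sizes = genome.sizes if genome is not None else None
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected ≥{min_cols} columns for "
                    f"{format}, got {len(parts)}")
            try:
                chrom = _normalize_chrom(parts[0], strip_chr)
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed coordinates ({e})")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} ≤ start {start}")
            if sizes is not None:
                if chrom not in sizes:
                    if on_unknown_chrom == "skip":
                        logger.warning("%s:%d: skipping unknown chromosome %s",
                                       path, lineno, chrom)
                        continue
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > sizes[chrom]:
                    raise ValueError(
                        f"{path}:{lineno}: interval end {end} beyond chromosome "
                        f"{chrom} length {sizes[chrom]}")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            summit = None
            if format == "narrowPeak":
                off = int(parts[9])
                if off >= 0:
                    summit = off
            intervals.append(GenomicInterval(chrom, start, end, name=name,
                                             score=score, summit=summit))
    return PeakSet(intervals, shape_class=shape, label=label or str(path))


def write_peaks(peaks: PeakSet, path: str | Path, format: str = "bed") -> None:
    """Write a PeakSet as BED / narrowPeak / broadPeak (round-trip exact)."""
    if format not in _N_COLS:
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks):
            name = iv.name or f"peak_{i}"
            score = 0 if iv.score is None else iv.score
            if format == "bed":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{_fmt(score)}\t.\n")
            elif format == "narrowPeak":
                summit = -1 if iv.summit is None else iv.summit
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{_fmt(score)}"
                         f"\t.\t0\t-1\t-1\t{summit}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{_fmt(score)}"
                         f"\t.\t0\t-1\t-1\n")


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_segmentation(path: str | Path, genome: Genome | None = None,
                      strip_chr: bool = True) -> StateSegmentation:
    """Read a BED4 chromatin-state segmentation (column 4 = state label)."""
    segs: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED4 needs 4 columns")
            chrom = _normalize_chrom(parts[0], strip_chr)
            if genome is not None and chrom not in genome.sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            segs.append((GenomicInterval(chrom, int(parts[1]), int(parts[2])), parts[3]))
    return StateSegmentation(segs)


# ---------------------------------------------------------------------------
# Interval arithmetic

def _merge_array(arr: np.ndarray) -> np.ndarray:
    """Merge possibly-overlapping (n, 2) intervals into maximal runs."""
    if arr.size == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = []
    cs, ce = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        if s <= ce:  # touching intervals merge: coverage is identical
            ce = max(ce, int(e))
        else:
            out.append((cs, ce))
            cs, ce = int(s), int(e)
    out.append((cs, ce))
    return np.array(out, dtype=np.int64)


def merge_intervals(peaks: PeakSet) -> PeakSet:
    """Union of a peak set's bases as maximal non-overlapping intervals."""
    ivs = [GenomicInterval(c, int(s), int(e))
           for c, arr in sorted(peaks.merged_by_chrom().items())
           for s, e in arr]
    return PeakSet(ivs, shape_class=peaks.shape_class, label=peaks.label)


def coverage_bp(peaks: PeakSet, genome: Genome | None = None,
                autosomes_only: bool = False) -> int:
    """Distinct bases covered by ≥1 interval (symbol A of the enrichment)."""
    merged = peaks.merged_by_chrom()
    if autosomes_only:
        if genome is None:
            raise ValueError("autosomes_only requires a genome")
        merged = {c: a for c, a in merged.items() if c in genome.autosome_names}
    return int(sum((a[:, 1] - a[:, 0]).sum() for a in merged.values()))


def consensus_peaks(peaksets: Sequence[PeakSet], min_support: int = 2,
                    label: str = "consensus") -> PeakSet:
    """Maximal intervals of bases under a peak in ≥ ``min_support`` samples.

    Support is per-sample: overlapping intervals within one sample count
    once.  Output intervals carry the maximum per-base support as ``score``.
    """
    if min_support < 1:
        raise ValueError("min_support must be ≥ 1")
    if min_support > len(peaksets):
        logger.warning("min_support %d exceeds number of samples %d; "
                       "consensus is empty", min_support, len(peaksets))
        return PeakSet([], shape_class=peaksets[0].shape_class if peaksets else "narrow",
                       label=label)
    shape = peaksets[0].shape_class
    chroms: set[str] = set()
    merged_per_sample = [ps.merged_by_chrom() for ps in peaksets]
    for m in merged_per_sample:
        chroms.update(m)
    out: list[GenomicInterval] = []
    for chrom in sorted(chroms):
        events: list[np.ndarray] = []
        for m in merged_per_sample:
            arr = m.get(chrom)
            if arr is None or arr.size == 0:
                continue
            ev = np.empty((2 * len(arr), 2), dtype=np.int64)
            ev[0::2, 0], ev[0::2, 1] = arr[:, 0], 1
            ev[1::2, 0], ev[1::2, 1] = arr[:, 1], -1
            events.append(ev)
        if not events:
            continue
        ev = np.concatenate(events)
        pos = np.unique(ev[:, 0])
        delta = np.zeros(len(pos), dtype=np.int64)
        idx = np.searchsorted(pos, ev[:, 0])
        np.add.at(delta, idx, ev[:, 1])
        support = np.cumsum(delta)  # support on [pos[i], pos[i+1])
        above = support >= min_support
        i = 0
        while i < len(pos):
            if above[i]:
                j = i
                while j + 1 < len(pos) and above[j + 1]:
                    j += 1
                out.append(GenomicInterval(
                    chrom, int(pos[i]), int(pos[j + 1]),
                    score=float(support[i:j + 1].max())))
                i = j + 1
            else:
                i += 1
    return PeakSet(out, shape_class=shape, label=label)


_warned_no_summit = False


def peak_anchor(interval: GenomicInterval, shape_class: str) -> int:
    """Single-bp anchor: summit for narrow peaks, midpoint for broad.

    A narrow peak without a summit falls back to the midpoint with a warning.
    """
    if shape_class == "narrow":
        if interval.summit is not None:
            return interval.start + interval.summit
        global _warned_no_summit
        if not _warned_no_summit:
            logger.warning("narrow peak %s:%d-%d lacks a summit; using midpoint "
                           "(further occurrences logged at DEBUG)",
                           interval.chrom, interval.start, interval.end)
            _warned_no_summit = True
        else:
            logger.debug("narrow peak %s:%d-%d lacks a summit; using midpoint",
                         interval.chrom, interval.start, interval.end)
    return (interval.start + interval.end) // 2


def peak_anchors(peaks: PeakSet) -> list[tuple[str, int]]:
    return [(iv.chrom, peak_anchor(iv, peaks.shape_class)) for iv in peaks]


def distance_to_nearest_tss(positions: Sequence[int], tss_list: Sequence[int]
                            ) -> np.ndarray:
    """Unsigned bp distance from each position to the nearest TSS.

    Both arguments are positions on ONE chromosome.  A position exactly at a
    TSS has distance 0.  Raises if ``tss_list`` is empty (the caller flags
    and excludes chromosomes with no TSS).
    """
    tss = np.sort(np.asarray(tss_list, dtype=np.int64))
    if tss.size == 0:
        raise ValueError("no TSS on this chromosome; distance undefined")
    pos = np.asarray(positions, dtype=np.int64)
    idx = np.searchsorted(tss, pos)
    left = np.where(idx > 0, np.abs(pos - tss[np.maximum(idx - 1, 0)]), np.iinfo(np.int64).max)
    right = np.where(idx < tss.size, np.abs(tss[np.minimum(idx, tss.size - 1)] - pos),
                     np.iinfo(np.int64).max)
    return np.minimum(left, right)


def intersect_bp(a: PeakSet, b: PeakSet) -> int:
    """Number of bases covered by both peak sets."""
    ma, mb = a.merged_by_chrom(), b.merged_by_chrom()
    total = 0
    for chrom in set(ma) & set(mb):
        xa, xb = ma[chrom], mb[chrom]
        i = j = 0
        while i < len(xa) and j < len(xb):
            lo = max(xa[i, 0], xb[j, 0])
            hi = min(xa[i, 1], xb[j, 1])
            if hi > lo:
                total += int(hi - lo)
            if xa[i, 1] < xb[j, 1]:
                i += 1
            else:
                j += 1
    return total
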