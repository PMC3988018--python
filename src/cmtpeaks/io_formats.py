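"""Reading and writing the flat-file formats the caller touches, and the
per-nucleotide coverage pileup built from aligned reads.

Coordinates are 0-based half-open everywhere (BED convention); emitted peak
files are BED, so the internal convention matches the output byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Read",
    "Fragment",
    "CoverageHistogram",
    "Region",
    "BedParseError",
    "read_bed",
    "write_reads_bed",
    "extend_read",
    "extend_reads",
    "build_histogram",
    "write_peaks_bed",
    "read_peaks_bed",
    "read_chrom_sizes",
    "read_fasta",
]


class BedParseError(ValueError):
    """A malformed BED record; the message names the offending line."""


@dataclass(frozen=True)
class Read:
    """One aligned sequencing read: an interval plus the strand it mapped to."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("read has empty chromosome name")
        if self.start >= self.end:
            raise ValueError(
                f"read interval [{self.start}, {self.end}) is empty or inverted"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class Fragment:
    """A read extended to the sonication fragment length (strand-resolved)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad fragment interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CoverageHistogram:
    """Per-chromosome fragment pileup at single-nucleotide resolution.

    ``counts[i]`` is the number of fragments covering genomic position
    ``origin + i``.  The array spans only the data extent
    ``[origin, origin + len(counts))``; positions outside it have coverage 0.
    """

    chrom: str
    origin: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if len(self.counts) and self.counts.min() < 0:
            raise ValueError("coverage counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def end(self) -> int:
        """One past the last covered genomic position."""
        return self.origin + len(self.counts)

    def height(self, pos: int) -> int:
        """Coverage at an absolute genomic position (0 outside the extent)."""
        i = pos - self.origin
        if 0 <= i < len(self.counts):
            return int(self.counts[i])
        return 0

    def slice(self, start: int, end: int) -> np.ndarray:
        """Coverage over [start, end) as an array, zero-padded off-extent."""
        if start >= end:
            raise ValueError(f"empty interval [{start}, {end})")
        out = np.zeros(end - start, dtype=np.int64)
        lo = max(start, self.origin)
        hi = min(end, self.end)
        if lo < hi:
            out[lo - start : hi - start] = self.counts[lo - self.origin : hi - self.origin]
        return out


@dataclass
class Region:
    """A called interval: boundaries, summit position, summit height and the
    experiment/control fold enrichment used for ranking."""

    chrom: str
    start: int
    end: int
    summit: int
    height: int
    fold_enrichment: float = 0.0

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside region [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def read_bed(path: str | Path) -> list[Read]:
    """Parse a BED6 file of aligned reads.

    Every record needs at least six fields (chrom, start, end, name, score,
    strand); strand is required because fragment extension is directional.
    Malformed lines raise :class:`BedParseError` naming the line number.
    """
    reads: list[Read] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=6 BED fields "
                    f"(strand is required for fragment extension), got {len(fields)}"
                )
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            strand = fields[5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                reads.append(Read(chrom, start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return reads


def write_reads_bed(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as BED6 (name ``read_<i>``, score 0)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads, start=1):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread_{i}\t0\t{r.strand}\n")


def extend_read(read: Read, fragment_length: int) -> Fragment:
    """Extend a read to the sonication fragment length in its strand direction.

    Plus-strand reads grow rightward from their 5' end; minus-strand reads
    grow leftward from theirs.  Fragments running past the chromosome origin
    are clipped at 0 (the right end is never clipped: chromosome length is
    unknown from a BED file alone).
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    if read.strand == "+":
        start, end = read.start, read.start + fragment_length
    else:
        start, end = read.end - fragment_length, read.end
    return Fragment(read.chrom, max(start, 0), end)


def extend_reads(reads: Iterable[Read], fragment_length: int) -> list[Fragment]:
    return [extend_read(r, fragment_length) for r in reads]


def build_histogram(fragments: Sequence[Fragment], chrom: str) -> CoverageHistogram:
    """Pile up fragments into a per-nucleotide coverage histogram.

    The array spans [min fragment start, max fragment end); an empty fragment
    set yields a zero-length histogram.  Built by accumulating +1/-1 boundary
    events and taking the cumulative sum, so cost is linear in extent.
    """
    frags = [f for f in fragments]
    for f in frags:
        if f.chrom != chrom:
            raise ValueError(f"fragment on {f.chrom} passed to histogram for {chrom}")
    if not frags:
        return CoverageHistogram(chrom, 0, np.zeros(0, dtype=np.int64))
    origin = min(f.start for f in frags)
    extent = max(f.end for f in frags) - origin
    delta = np.zeros(extent + 1, dtype=np.int64)
    starts = np.fromiter((f.start - origin for f in frags), dtype=np.int64, count=len(frags))
    ends = np.fromiter((f.end - origin for f in frags), dtype=np.int64, count=len(frags))
    np.add.at(delta, starts, 1)
    np.add.at(delta, ends, -1)
    counts = np.cumsum(delta[:-1])
    return CoverageHistogram(chrom, origin, counts)


def write_peaks_bed(regions: Sequence[Region], path: str | Path) -> None:
    """Write called peaks as BED6+1: chrom, start, end, name ``CMT_peak_<i>``,
    score = fold enrichment, strand '.', and the summit offset from start."""
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start))
    if list(ordered) != list(regions):
        warnings.warn("regions were not sorted by (chrom, start); sorting on write")
    with open(path, "w") as fh:
        for i, r in enumerate(ordered, start=1):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tCMT_peak_{i}\t"
                f"{r.fold_enrichment:g}\t.\t{r.summit - r.start}\n"
            )


def read_peaks_bed(path: str | Path) -> list[Region]:
    """Read a peak BED file back into Region objects.

    Accepts our own BED6+1 output (summit offset in column 7) as well as
    plain BED3/BED6 from other callers, in which case the summit defaults to
    the interval midpoint and the score column (if numeric) becomes the fold
    enrichment.
    """
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: empty or inverted interval")
            score = 0.0
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = 0.0
            if len(fields) >= 7:
                try:
                    summit = start + int(fields[6])
                except ValueError:
                    summit = (start + end) // 2
            else:
                summit = (start + end) // 2
            summit = min(max(summit, start), end - 1)
            regions.append(Region(chrom, start, end, summit, 0, score))
    return regions


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column ``<chrom>\\t<length>`` file, as used by UCSC tools."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected '<chrom> <length>'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as a dict of uppercase sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def group_reads_by_chrom(reads: Iterable[Read]) -> dict[str, list[Read]]:
    """Bucket reads per chromosome, preserving input order within each."""
    out: dict[str, list[Read]] = {}
    for r in reads:
        out.setdefault(r.chrom, []).append(r)
    return out


def iter_chromosomes(*read_sets: Sequence[Read]) -> Iterator[str]:
    """Chromosome names present in every given read set, sorted."""
    common: set[str] | None = None
    for rs in read_sets:
        names = {r.chrom for r in rs}
        common = names if common is None else common & names
    yield from sorted(common or ())
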