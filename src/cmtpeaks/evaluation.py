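"""Evaluation machinery: swap-based FDR, IUPAC motif enrichment against
length-matched random intervals, summit-based overlap between peak sets, and
genomic-feature assignment."""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import Region

__all__ = [
    "Motif",
    "PeakSet",
    "OverlapCounts",
    "swap_fdr",
    "count_motif",
    "random_intervals",
    "enrichment_score",
    "summit_overlap",
    "assign_features",
    "read_motifs",
]

# IUPAC degenerate nucleotide codes -> the concrete bases each matches.
# An N (or other degenerate code) in the *sequence* matches nothing, which is
# why the expansions below contain only A/C/G/T.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Motif:
    """An IUPAC-degenerate DNA binding motif, e.g. GANGGGT."""

    pattern: str
    name: str = ""

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not pat:
            raise ValueError("motif pattern must be non-empty")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in motif {pat!r}")
        object.__setattr__(self, "pattern", pat)

    @property
    def reverse_complement(self) -> str:
        return self.pattern.translate(_COMPLEMENT)[::-1]

    def regex(self, pattern: str | None = None) -> re.Pattern:
        pat = pattern if pattern is not None else self.pattern
        body = "".join(
            c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in pat
        )
        return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


@dataclass
class PeakSet:
    """A labelled collection of called regions from one method."""

    label: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start))
        prev: Region | None = None
        for r in self.regions:
            if prev is not None and prev.chrom == r.chrom and r.start < prev.end:
                raise ValueError(
                    f"overlapping regions in peak set {self.label!r}: "
                    f"{prev.chrom}:{prev.start}-{prev.end} and {r.chrom}:{r.start}-{r.end}"
                )
            prev = r

    def __len__(self) -> int:
        return len(self.regions)


def swap_fdr(n_original: int, n_swapped: int) -> float:
    """False-discovery-rate proxy from an experiment/control swap.

    Percentage of peaks surviving when experiment and control are exchanged
    and the caller is re-run with identical parameters:
    ``100 * n_swapped / n_original``.
    """
    if n_original <= 0:
        raise ValueError("swap FDR undefined without original peaks")
    if n_swapped < 0:
        raise ValueError("swapped peak count cannot be negative")
    return 100.0 * n_swapped / n_original


def count_motif(seq: str, motif: Motif, both_strands: bool = True) -> int:
    """Occurrences of an IUPAC motif in a DNA sequence.

    Overlapping matches are all counted.  By default both strands are
    scanned (the forward pattern plus its reverse complement); binding-site
    occurrence is strand-agnostic.  A degenerate code in the *sequence*
    (e.g. N) never matches.  Palindromic motifs are scanned once.
    """
    seq = seq.upper()
    bad = set(seq) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC character(s) {sorted(bad)} in sequence")
    n = len(motif.regex().findall(seq))
    rc = motif.reverse_complement
    if both_strands and rc != motif.pattern:
        n += len(motif.regex(rc).findall(seq))
    return n


def random_intervals(
    peaks: PeakSet,
    chrom_lengths: Mapping[str, int],
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Length-matched null intervals: per chromosome, the same number of
    intervals with the same lengths as the called peaks, uniform random
    starts, fully contained in the chromosome.  Intervals are drawn
    independently and may overlap each other."""
    out: list[tuple[str, int, int]] = []
    for r in peaks.regions:
        clen = chrom_lengths[r.chrom]
        size = len(r)
        if size > clen:
            raise ValueError(
                f"peak of {size} bp cannot fit in chromosome {r.chrom} ({clen} bp)"
            )
        start = int(rng.integers(0, clen - size + 1))
        out.append((r.chrom, start, start + size))
    return out


def enrichment_score(
    peaks: PeakSet,
    genome: Mapping[str, str],
    motifs: Sequence[Motif],
    seed: int,
    both_strands: bool = True,
) -> float:
    """Motif enrichment of called peaks over length-matched random intervals.

    Total motif occurrences (summed over the motif set) in the peak
    sequences, divided by total occurrences in an equally sized set of
    random intervals with the same lengths drawn uniformly from the same
    chromosomes.  Scores above 1 indicate the peaks capture motif-dense
    sequence.  Fully seeded; if the random intervals contain no occurrence
    at all, the denominator gets +1 smoothing and a warning is issued.
    """
    missing = {r.chrom for r in peaks.regions} - set(genome)
    if missing:
        raise ValueError(f"peak chromosome(s) missing from genome: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    lengths = {c: len(s) for c, s in genome.items()}
    null = random_intervals(peaks, lengths, rng)
    n_peaks = sum(
        count_motif(genome[r.chrom][r.start : r.end], m, both_strands)
        for r in peaks.regions
        for m in motifs
    )
    n_null = sum(
        count_motif(genome[c][s:e], m, both_strands) for (c, s, e) in null for m in motifs
    )
    if n_null == 0:
        warnings.warn(
            "no motif occurrences in the random intervals; "
            "using +1 smoothing on the denominator"
        )
        return n_peaks / (n_null + 1.0)
    return n_peaks / n_null


@dataclass
class OverlapCounts:
    """Directional summit-containment overlap between two peak sets.

    A peak of A counts as detected by B when A's summit lies inside some
    region of B (and vice versa); the two directions are generally
    asymmetric.
    """

    a_in_b: int
    a_only: int
    b_in_a: int
    b_only: int

    @property
    def pct_a_in_b(self) -> float:
        """Percentage of A's peaks whose summit B also covers."""
        n_a = self.a_in_b + self.a_only
        return 100.0 * self.a_in_b / n_a if n_a else 0.0

    @property
    def pct_b_in_a(self) -> float:
        n_b = self.b_in_a + self.b_only
        return 100.0 * self.b_in_a / n_b if n_b else 0.0


def _summits_covered(of: PeakSet, by: PeakSet) -> int:
    trees: dict[str, IntervalTree] = {}
    for r in by.regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return sum(
        1 for r in of.regions if r.chrom in trees and trees[r.chrom].overlaps_point(r.summit)
    )


def summit_overlap(a: PeakSet, b: PeakSet) -> OverlapCounts:
    """Count peaks shared between two sets under the summit-containment rule."""
    a_in_b = _summits_covered(a, b)
    b_in_a = _summits_covered(b, a)
    return OverlapCounts(a_in_b, len(a) - a_in_b, b_in_a, len(b) - b_in_a)


def assign_features(
    peaks: PeakSet,
    annotations: Iterable[tuple[str, int, int, str]],
    intergenic_label: str = "inter-genetic",
) -> dict[str, dict[str, float]]:
    """Assign genomic-feature labels (gene/exon/intron/promoter/...) to peaks.

    A peak receives every label whose annotated interval it overlaps by at
    least 1 bp — a peak inside an exon of a gene counts as both gene and
    exon — so the per-label percentages may sum to more than 100.  Peaks
    overlapping nothing are labelled ``inter-genetic``.  Returns
    ``{label: {"regions": count, "pct": percentage-of-peaks}}``.
    """
    trees: dict[str, IntervalTree] = {}
    labels: set[str] = set()
    for chrom, start, end, label in annotations:
        if start >= end:
            raise ValueError(f"empty annotation interval {chrom}:{start}-{end}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end, label)
        labels.add(label)
    counts: dict[str, int] = {lab: 0 for lab in sorted(labels)}
    counts[intergenic_label] = 0
    for r in peaks.regions:
        hits = trees[r.chrom].overlap(r.start, r.end) if r.chrom in trees else set()
        if not hits:
            counts[intergenic_label] += 1
            continue
        for lab in {iv.data for iv in hits}:
            counts[lab] += 1
    n = len(peaks)
    return {
        lab: {"regions": c, "pct": (100.0 * c / n if n else 0.0)}
        for lab, c in counts.items()
    }


def read_motifs(path) -> list[Motif]:
    """Read motifs from a text file: one per line, ``NAME<TAB>PATTERN`` or
    just ``PATTERN``; '#' comments and blank lines ignored.  Comma-separated
    patterns after one name yield one Motif per pattern."""
    motifs: list[Motif] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 1:
                name, pats = "", fields[0]
            else:
                name, pats = fields[0], fields[1]
            for pat in pats.split(","):
                pat = pat.strip()
                if pat:
                    motifs.append(Motif(pat, name))
    return motifs
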