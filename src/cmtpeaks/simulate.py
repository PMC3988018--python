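"""Synthetic ChIP-Seq data with known ground truth.

Generates an experiment read set (uniform background plus planted enriched
regions of configurable width and fold), a matched background-only control,
and optionally a random genome with motif instances planted inside the
enriched regions — enough to exercise every stage of the caller end to end
without external data.

The background is a homogeneous process: fragment start positions are
uniform over the chromosome, so per-base coverage is Poisson with mean
``n_background_reads * fragment_length / chrom_length``.  No chromatin
accessibility bias, mappability structure or sequencing error is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evaluation import IUPAC, Motif
from .io_formats import Read

__all__ = [
    "PlantedPeak",
    "SimulationConfig",
    "GroundTruth",
    "simulate_reads",
    "simulate_genome",
    "plant_positions",
]


@dataclass(frozen=True)
class PlantedPeak:
    """An enriched region to plant: centre (bp), width (bp) and the fold
    enrichment of its expected coverage over background."""

    centre: int
    width: int
    fold: float

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("peak width must be >= 1 bp")
        if self.fold < 1:
            raise ValueError("peak fold must be >= 1")

    @property
    def start(self) -> int:
        return self.centre - self.width // 2

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass
class SimulationConfig:
    """Study conditions for one simulated ChIP-Seq experiment.

    Defaults describe a 1-Mb chromosome sequenced to mean background
    coverage 2 (10,000 single-end 36-bp reads from 200-bp fragments) with an
    equally deep control — a desk-scale stand-in for a transcription-factor
    ChIP experiment.
    """

    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    n_background_reads: int = 10_000
    read_length: int = 36
    fragment_length: int = 200
    planted_peaks: tuple[PlantedPeak, ...] = ()
    control_depth_ratio: float = 1.0
    motif: Optional[Motif] = None
    strand_aware: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_peaks = tuple(
            p if isinstance(p, PlantedPeak) else PlantedPeak(*p)
            for p in self.planted_peaks
        )
        if self.read_length < 1 or self.fragment_length < self.read_length:
            raise ValueError("need 1 <= read_length <= fragment_length")
        if self.chrom_length < self.fragment_length:
            raise ValueError("chromosome shorter than one fragment")
        if self.control_depth_ratio <= 0:
            raise ValueError("control_depth_ratio must be > 0")
        for p in self.planted_peaks:
            if p.start < 0 or p.end > self.chrom_length or p.width > self.chrom_length:
                raise ValueError(
                    f"planted peak [{p.start}, {p.end}) outside chromosome "
                    f"of length {self.chrom_length}"
                )

    @property
    def background_coverage(self) -> float:
        """Expected per-base background coverage after fragment extension."""
        return self.n_background_reads * self.fragment_length / self.chrom_length


@dataclass
class GroundTruth:
    """What was planted: the true regions and, for every experiment read,
    whether it came from background or from peak i."""

    regions: list[PlantedPeak]
    read_labels: list[str]  # "background" or "peak_<i>", one per experiment read


def _read_from_fragment(
    chrom: str, frag_start: int, frag_end: int, strand: str, read_length: int
) -> Read:
    # the sequenced read is the 5'-most read_length bp of the fragment
    if strand == "+":
        return Read(chrom, frag_start, min(frag_start + read_length, frag_end), "+")
    return Read(chrom, max(frag_end - read_length, frag_start), frag_end, "-")


def _background_reads(
    cfg: SimulationConfig, n: int, rng: np.random.Generator
) -> list[Read]:
    starts = rng.integers(0, cfg.chrom_length - cfg.fragment_length + 1, size=n)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    return [
        _read_from_fragment(
            cfg.chrom, int(s), int(s) + cfg.fragment_length, str(st), cfg.read_length
        )
        for s, st in zip(starts, strands)
    ]


def reads_per_peak(cfg: SimulationConfig, peak: PlantedPeak) -> int:
    """Number of extra reads that raise expected peak-centre coverage to
    ``fold`` times background.

    Fragment midpoints are uniform over the peak interval, so the centre is
    covered with probability min(1, L/width); the count is chosen so the
    planted contribution is (fold - 1) * background coverage there.  With no
    background at all, fold is read as the absolute expected peak coverage.
    """
    bg = cfg.background_coverage
    target_extra = (peak.fold - 1.0) * bg if bg > 0 else peak.fold
    per_read = min(1.0, cfg.fragment_length / peak.width)
    return int(round(target_extra / per_read)) if target_extra > 0 else 0


def _peak_reads(
    cfg: SimulationConfig, peak: PlantedPeak, rng: np.random.Generator
) -> list[Read]:
    n = reads_per_peak(cfg, peak)
    L = cfg.fragment_length
    reads = []
    for _ in range(n):
        strand = str(rng.choice(np.array(["+", "-"])))
        if cfg.strand_aware:
            # the immunoprecipitated fragment straddles the bound site:
            # draw its midpoint inside the peak, sequence from the 5' end
            mid = int(rng.integers(peak.start, peak.end))
            fs = max(mid - L // 2, 0)
            fe = fs + L
        else:
            fs = int(rng.integers(peak.start, peak.end))
            fe = fs + L
        reads.append(_read_from_fragment(cfg.chrom, fs, fe, strand, cfg.read_length))
    return reads


def simulate_reads(
    config: SimulationConfig,
) -> tuple[list[Read], list[Read], GroundTruth]:
    """Draw (experiment reads, control reads, ground truth) for a config.

    The experiment holds the uniform background plus, per planted peak,
    extra reads whose fragments concentrate over the peak so its expected
    coverage is fold x background.  The control is background only, with
    ``control_depth_ratio`` times the background read count.  All randomness
    flows from ``config.seed``; identical configs give identical output.
    """
    rng = np.random.default_rng(config.seed)
    exp = _background_reads(config, config.n_background_reads, rng)
    labels = ["background"] * len(exp)
    for i, peak in enumerate(config.planted_peaks):
        pr = _peak_reads(config, peak, rng)
        exp.extend(pr)
        labels.extend([f"peak_{i}"] * len(pr))
    n_ctrl = int(round(config.n_background_reads * config.control_depth_ratio))
    ctrl = _background_reads(config, n_ctrl, rng)
    return exp, ctrl, GroundTruth(list(config.planted_peaks), labels)


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """Resolve degenerate IUPAC codes to concrete bases, uniformly."""
    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][int(rng.integers(len(IUPAC[c])))]
        for c in pattern
    )


def simulate_genome(
    length: int,
    gc: float,
    planted: Sequence[tuple[Motif, Sequence[int]]],
    seed: int,
) -> str:
    """Random genome: i.i.d. bases at the given GC fraction, with motif
    instances overwritten at the stated positions.

    Degenerate codes in a planted motif are instantiated uniformly from
    their matching bases.  Overlapping planted instances are an error.
    """
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=length, p=probs)
    occupied: list[tuple[int, int]] = []
    for motif, positions in planted:
        for pos in positions:
            end = pos + len(motif.pattern)
            if pos < 0 or end > length:
                raise ValueError(f"planted motif at {pos} outside genome of {length} bp")
            for s, e in occupied:
                if pos < e and s < end:
                    raise ValueError(
                        f"planted motif at {pos} overlaps another planted instance"
                    )
            occupied.append((pos, end))
            bases[pos:end] = list(_instantiate(motif.pattern, rng))
    return "".join(bases)


def plant_positions(
    peaks: Sequence[PlantedPeak],
    motif: Motif,
    copies_per_peak: int,
    rng: np.random.Generator,
) -> list[int]:
    """Non-overlapping motif start positions inside each planted peak."""
    w = len(motif.pattern)
    out: list[int] = []
    for p in peaks:
        if p.width < w:
            raise ValueError(f"peak of {p.width} bp too narrow for motif {motif.pattern}")
        placed: list[int] = []
        attempts = 0
        while len(placed) < copies_per_peak and attempts < 1000:
            pos = int(rng.integers(p.start, p.end - w + 1))
            if all(abs(pos - q) >= w for q in placed):
                placed.append(pos)
            attempts += 1
        out.extend(sorted(placed))
    return out
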