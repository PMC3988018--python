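"""End-to-end peak calling: extend reads, pile up, segment, shrink, filter
against the control, rank.  This is the library entry point the CLI wraps."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .core import CMTParams, ScanStats, scan_chromosome
from .io_formats import (
    CoverageHistogram,
    Read,
    Region,
    build_histogram,
    extend_reads,
    group_reads_by_chrom,
)
from .refinement import EnrichmentResult, is_enriched, rank_regions, shrink_region

__all__ = ["CallResult", "call_peaks"]

log = logging.getLogger(__name__)


@dataclass
class CallResult:
    """Everything a calling run produced."""

    peaks: list[Region]                     # passed regions, ranked by fold enrichment
    results: list[EnrichmentResult]         # every shrunk candidate with its densities
    summary: pd.DataFrame                   # per-chromosome counts and mean peak length
    stats: ScanStats = field(default_factory=ScanStats)


def call_peaks(
    experiment: Sequence[Read],
    control: Sequence[Read],
    params: CMTParams,
    normalize_control: bool = True,
    density_mode: Literal["mean_square", "squared_mean"] = "mean_square",
) -> CallResult:
    """Call enriched regions from experiment reads against a control.

    Each chromosome of the experiment is processed independently: reads are
    extended to ``params.fragment_length``, piled up, segmented by
    constrained thresholding, candidates are shrunk to their supported
    footprint (``params.cutoff``) and kept if they pass the size and k-fold
    squared-density filters against the control pileup.  With
    ``normalize_control`` the control heights are rescaled by the ratio of
    total fragment counts before squaring, so unequal sequencing depths do
    not bias the fold test.

    Raises ``ValueError`` when the control is empty or shares no chromosome
    with the experiment.
    """
    if not experiment:
        raise ValueError("experiment read set is empty")
    if not control:
        raise ValueError("control read set is empty; the enrichment filter requires it")
    exp_by_chrom = group_reads_by_chrom(experiment)
    ctrl_by_chrom = group_reads_by_chrom(control)
    if not set(exp_by_chrom) & set(ctrl_by_chrom):
        raise ValueError(
            "experiment and control share no chromosome: "
            f"{sorted(exp_by_chrom)} vs {sorted(ctrl_by_chrom)}"
        )
    ctrl_scale = len(experiment) / len(control) if normalize_control else 1.0

    stats = ScanStats()
    all_results: list[EnrichmentResult] = []
    rows = []
    for chrom in sorted(exp_by_chrom):
        exp_frags = extend_reads(exp_by_chrom[chrom], params.fragment_length)
        ctrl_frags = extend_reads(ctrl_by_chrom.get(chrom, []), params.fragment_length)
        exp_hist = build_histogram(exp_frags, chrom)
        ctrl_hist = build_histogram(ctrl_frags, chrom)
        candidates = scan_chromosome(exp_hist, params, stats)
        chrom_results = []
        for cand in candidates:
            shrunk = shrink_region(exp_hist, cand, params.cutoff)
            chrom_results.append(
                is_enriched(
                    exp_hist, ctrl_hist, shrunk, params,
                    ctrl_scale=ctrl_scale, density_mode=density_mode,
                )
            )
        passed = [r for r in chrom_results if r.passed]
        mean_len = (
            sum(len(r.region) for r in passed) / len(passed) if passed else float("nan")
        )
        rows.append(
            {
                "chrom": chrom,
                "candidates": len(candidates),
                "passed": len(passed),
                "mean_peak_length": mean_len,
            }
        )
        all_results.extend(chrom_results)
        log.info(
            "%s: %d candidates, %d passed (gap jumps so far: %d)",
            chrom, len(candidates), len(passed), stats.gap_jumps,
        )
    summary = pd.DataFrame(rows, columns=["chrom", "candidates", "passed", "mean_peak_length"])
    return CallResult(rank_regions(all_results), all_results, summary, stats)
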