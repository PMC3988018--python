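"""Constrained multi-level thresholding along the genomic axis.

Each chromosome's coverage histogram is segmented left to right.  A window of
``max_region`` bins is anchored at the current position and a single division
point is placed inside it by maximizing the between-class variance of genomic
position, with normalized coverage as the weight: the division therefore falls
in the "valley" that best separates two neighbouring clusters of signal.  The
user's minimum and maximum region sizes constrain where the division may go,
which is what lets the caller target footprints of a chosen scale.  Stretches
whose windows never reach the minimum supported height are skipped wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import CoverageHistogram, Region

__all__ = [
    "CMTParams",
    "ScanStats",
    "GapWindowError",
    "between_class_variance",
    "between_class_variance_sweep",
    "find_division_point",
    "gap_skip",
    "scan_chromosome",
]

# chunk size for the forward scans used by gap skipping
_CHUNK = 1 << 16


@dataclass
class CMTParams:
    """Caller parameters.

    fragment_length
        Average sonication fragment length in bp; each read is extended to
        this length before pileup.
    min_region, max_region
        Bounds (bp) on the size of the regions being targeted.  They double
        as the segmentation constraints: every division point lies at least
        ``min_region`` and less than ``max_region`` from the previous one.
    cutoff
        Border-shrinking height threshold (default 1): region borders are
        pulled inward until every retained bin has coverage >= cutoff.
    min_supported_reads
        Minimum summit height for a window to be analysed at all; windows
        below it are skipped as gaps.
    k_fold
        Minimum fold difference between experiment and control squared
        density for a region to be reported as enriched (default 2).
    """

    fragment_length: int = 200
    min_region: int = 100
    max_region: int = 2000
    cutoff: float = 1.0
    min_supported_reads: float = 10.0
    k_fold: float = 2.0

    def __post_init__(self) -> None:
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        if not (0 < self.min_region <= self.max_region):
            raise ValueError("need 0 < min_region <= max_region")
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if self.min_supported_reads < 0:
            raise ValueError("min_supported_reads must be >= 0")
        if self.k_fold <= 0:
            raise ValueError("k_fold must be > 0")


@dataclass
class ScanStats:
    """Operation counters filled in by :func:`scan_chromosome`.

    ``sigma_evaluations`` counts candidate division points scored, which is
    the quantity that must grow linearly with chromosome length.
    """

    sigma_evaluations: int = 0
    windows: int = 0
    gap_jumps: int = 0
    candidates_emitted: int = 0
    candidates_dropped_low: int = 0


class GapWindowError(ValueError):
    """The requested window holds no signal at the supported height."""


def between_class_variance(hist_window: np.ndarray, t: int) -> float:
    """Between-class variance of bin *position* for a split after index ``t``.

    Bins 0..t form the left class, bins t+1.. the right class; each bin i
    carries weight p_i = counts_i / sum(counts).  Returns

        sigma_B^2(t) = w1*(mu1 - muT)^2 + w2*(mu2 - muT)^2

    which equals w1*w2*(mu1 - mu2)^2 when both classes hold mass, and 0 when
    either class is empty of mass.
    """
    counts = np.asarray(hist_window, dtype=np.float64)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("window must be a 1-D array of at least 2 bins")
    total = counts.sum()
    if total <= 0:
        raise GapWindowError("window has zero total count; gap-skip first")
    if not (0 <= t < len(counts) - 1):
        raise ValueError(f"split index {t} out of range for {len(counts)} bins")
    p = counts / total
    idx = np.arange(len(counts), dtype=np.float64)
    w1 = p[: t + 1].sum()
    w2 = p[t + 1 :].sum()  # direct tail sum: 1 - w1 is inexact at zero tails
    if w1 <= 0.0 or w2 <= 0.0:
        return 0.0
    mu_t = float(idx @ p)
    mu1 = float(idx[: t + 1] @ p[: t + 1]) / w1
    mu2 = float(idx[t + 1 :] @ p[t + 1 :]) / w2
    return float(w1 * (mu1 - mu_t) ** 2 + w2 * (mu2 - mu_t) ** 2)


def between_class_variance_sweep(hist_window: np.ndarray) -> np.ndarray:
    """sigma_B^2 for every split index t = 0 .. n-2 of a window, in one pass.

    Uses running sums (cumulative mass and cumulative position*mass), so the
    whole sweep costs O(n); agrees with :func:`between_class_variance` at
    every t to floating-point accuracy.
    """
    counts = np.asarray(hist_window, dtype=np.float64)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("window must be a 1-D array of at least 2 bins")
    total = counts.sum()
    if total <= 0:
        raise GapWindowError("window has zero total count; gap-skip first")
    p = counts / total
    ip = np.arange(len(counts), dtype=np.float64) * p
    mu_t = float(ip.sum())
    w1 = np.cumsum(p)[:-1]            # class-1 mass after split t
    m1 = np.cumsum(ip)[:-1]           # class-1 first moment
    # tail sums via reverse cumulation, not 1 - w1: subtraction would lose
    # precision exactly where the right class mass is tiny
    w2 = np.cumsum(p[::-1])[::-1][1:]
    m2 = np.cumsum(ip[::-1])[::-1][1:]
    sigma = np.zeros_like(w1)
    ok = (w1 > 0.0) & (w2 > 0.0)
    mu1 = m1[ok] / w1[ok]
    mu2 = m2[ok] / w2[ok]
    sigma[ok] = w1[ok] * (mu1 - mu_t) ** 2 + w2[ok] * (mu2 - mu_t) ** 2
    return sigma


def _plateau_centre(sigma: np.ndarray, rel_tol: float = 1e-9) -> int:
    """Index of the centre of the maximizing plateau of a sigma_B^2 sweep.

    Zero-coverage valleys make sigma_B^2 exactly constant across the valley;
    the centre of the (longest, then leftmost) run of maximizing indices is a
    symmetric, reproducible choice.
    """
    top = sigma.max()
    at_max = np.flatnonzero(sigma >= top - rel_tol * abs(top))
    # split tied indices into contiguous runs, keep the longest (first wins ties)
    breaks = np.flatnonzero(np.diff(at_max) > 1)
    runs = np.split(at_max, breaks + 1)
    best = max(runs, key=len)
    return int((best[0] + best[-1]) // 2)


def find_division_point(
    hist: CoverageHistogram,
    window_start: int,
    params: CMTParams,
    stats: ScanStats | None = None,
) -> int:
    """Best genomic position to end the region starting at ``window_start``.

    Scores every admissible division b in
    ``[window_start + min_region, window_start + max_region)`` by the
    between-class variance of the window ``[window_start, window_start +
    max_region)`` (shrunk at the chromosome's right edge) split at b, and
    returns the argmax; exact ties resolve to the centre of the maximizing
    plateau.  Raises :class:`GapWindowError` if the window never reaches
    ``min_supported_reads`` (the caller should gap-skip instead).
    """
    window_end = min(window_start + params.max_region, hist.end)
    if window_end - window_start < 2:
        raise ValueError("window too small to divide")
    window = hist.slice(window_start, window_end)
    if window.max() < max(params.min_supported_reads, 1):
        raise GapWindowError(
            f"window [{window_start}, {window_end}) is below the supported height"
        )
    n = len(window)
    # split index t puts bins 0..t left: division position b = start + t + 1
    t_lo = max(params.min_region - 1, 0)
    t_hi = min(params.max_region - 1, n - 1)  # exclusive
    if t_lo >= t_hi:
        raise ValueError(
            f"window [{window_start}, {window_end}) shorter than min_region; "
            "emit it as a trailing candidate instead"
        )
    sigma = between_class_variance_sweep(window)[t_lo:t_hi]
    if stats is not None:
        stats.sigma_evaluations += len(sigma)
        stats.windows += 1
    return window_start + t_lo + _plateau_centre(sigma) + 1


def _next_at_least(counts: np.ndarray, start_idx: int, thr: float) -> int:
    """First index >= start_idx with counts >= thr, or len(counts) if none."""
    n = len(counts)
    i = max(start_idx, 0)
    while i < n:
        j = min(i + _CHUNK, n)
        hits = np.flatnonzero(counts[i:j] >= thr)
        if len(hits):
            return i + int(hits[0])
        i = j
    return n


def gap_skip(hist: CoverageHistogram, pos: int, params: CMTParams) -> int:
    """Skip ahead past unsupported territory.

    Returns the smallest position >= ``pos`` whose window of ``max_region``
    bins contains a bin of height >= ``min_supported_reads`` — i.e. for
    signal far downstream the window is placed so it just reaches the signal.
    Returns ``hist.end`` (the end-of-chromosome sentinel) when no such
    window exists.  Zero-coverage stretches are always treated as gaps, even
    at ``min_supported_reads == 0``.
    """
    thr = max(params.min_supported_reads, 1)
    x = _next_at_least(hist.counts, pos - hist.origin, thr)
    if x == len(hist.counts):
        return hist.end
    signal_pos = hist.origin + x
    return max(pos, signal_pos - params.max_region + 1)


def scan_chromosome(
    hist: CoverageHistogram,
    params: CMTParams,
    stats: ScanStats | None = None,
) -> list[Region]:
    """Segment one chromosome into candidate regions (the start/end vectors).

    Walks the histogram left to right: skip gaps, place a division point in
    each window, emit the interval between consecutive division points as a
    candidate carrying its summit and height.  Candidates whose summit never
    reaches ``min_supported_reads`` are dropped (they contain no supported
    signal by construction), so every bin at or above the supported height
    ends up inside exactly one emitted candidate.  Trailing signal shorter
    than ``min_region`` at the chromosome end is emitted as a final candidate
    and left to the downstream size filter.
    """
    regions: list[Region] = []
    if len(hist) == 0:
        return regions
    thr = max(params.min_supported_reads, 1)
    pos = hist.origin
    while pos < hist.end:
        skipped = gap_skip(hist, pos, params)
        if stats is not None and skipped > pos:
            stats.gap_jumps += 1
        pos = skipped
        if pos >= hist.end:
            break
        window_end = min(pos + params.max_region, hist.end)
        if window_end - pos <= params.min_region:
            division = window_end  # no admissible split; trailing candidate
        else:
            try:
                division = find_division_point(hist, pos, params, stats)
            except GapWindowError:  # pragma: no cover - gap_skip precludes this
                pos = window_end
                continue
        segment = hist.slice(pos, division)
        peak_idx = int(np.argmax(segment))  # leftmost maximum
        height = int(segment[peak_idx])
        if height >= thr:
            regions.append(Region(hist.chrom, pos, division, pos + peak_idx, height))
            if stats is not None:
                stats.candidates_emitted += 1
        elif stats is not None:
            stats.candidates_dropped_low += 1
        pos = division
    return regions
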