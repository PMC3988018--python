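"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes quantities from first principles (direct
summation, per-position scanning) without touching the production code
paths, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"),
    "B": set("CGT"), "D": set("AGT"), "H": set("ACT"), "V": set("ACG"),
    "N": set("ACGT"),
}
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def pileup_bruteforce(fragments, origin: int, length: int) -> np.ndarray:
    """Per-position fragment overlap count by direct enumeration."""
    counts = np.zeros(length, dtype=int)
    for f in fragments:
        for pos in range(max(f.start, origin), min(f.end, origin + length)):
            counts[pos - origin] += 1
    return counts


def sigma_b2_direct(counts, t: int) -> float:
    """Between-class variance of bin position for a split after index t,
    recomputing class mass and mean by direct summation."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    p = counts / total
    idx = np.arange(len(counts), dtype=float)
    w1 = p[: t + 1].sum()
    w2 = p[t + 1 :].sum()
    if w1 <= 0.0 or w2 <= 0.0:
        return 0.0
    mu1 = float((idx[: t + 1] * p[: t + 1]).sum()) / w1
    mu2 = float((idx[t + 1 :] * p[t + 1 :]).sum()) / w2
    mu_t = float((idx * p).sum())
    return w1 * (mu1 - mu_t) ** 2 + w2 * (mu2 - mu_t) ** 2


def division_point_oracle(counts, t_lo: int, t_hi: int, rel_tol: float = 1e-9) -> int:
    """Exhaustive sigma_B^2 sweep over admissible splits; ties resolve to the
    centre of the longest (then leftmost) maximizing plateau.  Returns the
    split index t* (window-relative)."""
    sigmas = np.array([sigma_b2_direct(counts, t) for t in range(t_lo, t_hi)])
    top = sigmas.max()
    at_max = np.flatnonzero(sigmas >= top - rel_tol * abs(top))
    runs: list[list[int]] = [[int(at_max[0])]]
    for i in at_max[1:]:
        if i == runs[-1][-1] + 1:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    best = max(runs, key=len)
    return t_lo + (best[0] + best[-1]) // 2


def count_motif_bruteforce(seq: str, pattern: str, both_strands: bool = True) -> int:
    """Position-by-position IUPAC matcher (sequence N matches nothing)."""
    seq = seq.upper()

    def matches(pat: str) -> int:
        n = 0
        for i in range(len(seq) - len(pat) + 1):
            if all(seq[i + j] in IUPAC_SETS[p] for j, p in enumerate(pat)):
                n += 1
        return n

    total = matches(pattern)
    rc = pattern.translate(_COMP)[::-1]
    if both_strands and rc != pattern:
        total += matches(rc)
    return total


def random_signal_window(rng: np.random.Generator, size: int) -> np.ndarray:
    """A coverage-like window: Poisson background with zero runs and a few
    planted rectangular spikes, guaranteeing some supported signal."""
    counts = rng.poisson(2.0, size=size)
    # carve zero-coverage valleys
    n_gaps = rng.integers(0, 4)
    for _ in range(n_gaps):
        g0 = int(rng.integers(0, size))
        g1 = min(size, g0 + int(rng.integers(5, max(6, size // 4))))
        counts[g0:g1] = 0
    # plant 1-3 spikes so the window always holds supported signal
    for _ in range(int(rng.integers(1, 4))):
        w = int(rng.integers(3, max(4, size // 5)))
        s0 = int(rng.integers(0, max(1, size - w)))
        counts[s0 : s0 + w] += int(rng.integers(10, 40))
    return counts.astype(np.int64)
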