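# Methods

## Model and procedure

The caller treats peak finding as one-dimensional clustering of the coverage
signal: each enriched region is a cluster of mass on the genomic axis,
separated from its neighbours by valleys. All stages work on per-chromosome,
per-nucleotide pileups of strand-extended reads.

**Pileup.** Reads are extended to the user-supplied average fragment length
`L` (plus-strand reads rightward from their 5' end, minus-strand reads
leftward), clipped at position 0 on the left only — chromosome length is not
knowable from a BED input, so the right end is never clipped unless a
chrom-sizes file is supplied upstream. The histogram is stored densely over
`[min fragment start, max fragment end)` with an origin offset; this is
equivalent to a whole-chromosome array but bounded by the data extent.
Coordinates are 0-based half-open throughout (BED convention).

**Constrained segmentation.** The scan keeps a current position `c` and
repeatedly places one division point in the window `W = [c, c + max_region)`
(shrunk at the chromosome's right edge). Admissible divisions are
`[c + min_region, c + max_region)`; each is scored by the between-class
variance of *position* with normalized coverage as the weight:

    p_i = h(i) / Σ_W h,   ω₁ = Σ_{i≤t} p_i,   ω₂ = Σ_{i>t} p_i,
    σ_B²(t) = ω₁(μ₁ − μ_T)² + ω₂(μ₂ − μ_T)²

which equals ω₁ω₂(μ₁ − μ₂)² whenever both classes carry mass and is defined
as 0 when either class is empty. The argmax is the valley that best
separates two neighbouring clusters inside the window; the interval between
consecutive division points is a candidate region, annotated with its
summit (leftmost maximum bin) and height. Normalization is per window —
σ_B²'s argmax is invariant under positive scaling of counts, so this is
safe and numerically stable.

The full sweep is computed with running sums (cumulative mass and first
moment from each end), so a window costs O(|W|) regardless of how many
splits are scored. Tail statistics are accumulated by a reverse cumulative
sum rather than as `1 − ω₁`: the subtraction loses all precision exactly
where the right class mass is tiny, and the sweep is required to agree with
direct per-split summation to 1e−9 relative tolerance.

**Gap skipping.** Before each window the scan jumps to the smallest
position whose `max_region` window contains a bin of height
≥ `min_supported_reads` (found by a chunked forward scan; the end of the
chromosome acts as the sentinel). Zero-coverage stretches are always treated
as gaps, even at `min_supported_reads = 0` — analysing windows with no mass
is vacuous. Candidate segments whose summit never reaches the supported
height are dropped at scan time; every bin at or above the supported height
still lands inside exactly one emitted candidate, and the number of σ_B²
evaluations grows linearly with chromosome length at fixed signal density.

**Refinement and selection.** Each candidate is shrunk from its summit
outward: the borders move until the first bin *strictly below* `cutoff` on
each side, keeping the maximal contiguous run of bins ≥ cutoff that contains
the summit. Disconnected signal blocks inside the original candidate are
dropped; they are only re-captured if the scanner emitted them separately.
A shrunk region is reported as enriched when

1. `min_region ≤ size ≤ max_region`, and
2. `D_exp ≥ k_fold · D_ctrl`, where `D = (1/n) Σ h(i)²` is the mean squared
   per-bp height over the region.

Squaring rewards tall concentrated signal over flat background of equal
area. Control heights are multiplied by the ratio of total experiment to
total control fragments before squaring (library-size normalization); pass
`normalize_control=False` / `--no-normalize-control` for the unnormalized
rule. If the control density is exactly 0 and the experiment's is positive
the region passes — a sparse control must not veto strong signal — and the
reported fold enrichment uses 1/size in the denominator to stay finite.
Passed regions are ranked by fold enrichment, ties broken by (chrom, start).

## Parameters

| parameter | unit | default | meaning / choice |
|---|---|---|---|
| `fragment_length` | bp | 200 | mean sonication fragment size; a user input, not estimated from data |
| `min_region`, `max_region` | bp | 100, 2000 | target size range; also the segmentation constraints |
| `cutoff` | coverage | 1 | border shrinking stops below this height; 1 keeps the contiguous covered part |
| `min_supported_reads` | coverage | 10 | gap-skip / candidate support threshold; set it between background and expected peak height |
| `k_fold` | — | 2 | minimum squared-density fold change vs control |

`cutoff = 1` and `k_fold = 2` are the method's stated defaults; the others
have no canonical value and should track the experiment's depth and the
biology being targeted (footprints vs domains).

## Numerical choices

- σ_B² ties are resolved to the **centre of the maximizing plateau**
  (longest run of maximizers, leftmost on equal length, centre element).
  Zero-coverage valleys make σ_B² exactly constant across the valley, and
  the centre is the symmetric, reproducible choice. Plateau membership uses
  a 1e−9 relative tolerance on the maximum.
- The scan resumes at the division point just emitted; trailing signal
  shorter than `min_region` at the chromosome end becomes a final candidate
  and is left to the size filter.
- Summit ties take the leftmost maximum bin.
- "Squared density" is the mean of squared heights; the alternative reading
  (square of the mean height) is available as
  `density_mode="squared_mean"` for sensitivity analysis. The two differ by
  the within-region variance, so the default is the stricter notion of
  concentration.
- Motif scanning counts all overlapping matches on both strands (forward
  pattern plus reverse complement; palindromic patterns scanned once).
  IUPAC degenerate codes in the pattern match their base sets; degenerate
  codes in the *sequence* match nothing.

## The synthetic-data generator

`simulate_reads` draws a uniform background — fragment starts uniform over
the chromosome, random strands, so per-base coverage is Poisson with mean
`n_background_reads · L / chrom_length` — plus, per planted peak, extra
reads whose fragment midpoints are uniform over the peak interval. The
number of extra reads is set so the expected peak-centre coverage is
`fold ×` background (with no background at all, `fold` is read as the
absolute expected coverage). Reads are emitted as the 5'-most `read_length`
bases of their fragment on either strand, so extension at calling time
reconstructs the fragments and the pileup shows the characteristic
strand-offset shape; `strand_aware=False` places peak fragment starts
uniformly instead. The control is background-only with
`control_depth_ratio` times the background read count. `simulate_genome`
draws i.i.d. bases at a given GC fraction and overwrites planted motif
instances (degenerate codes instantiated uniformly). Everything is driven
by one seed; equal configs give byte-identical output.

Deliberately not modelled: chromatin-accessibility or mappability bias,
sequencing error, duplicate reads, diploid copy-number structure. Passing
tests on this generator therefore demonstrate the algorithmic contracts
(segmentation, filtering, calibration against an exchangeable control), not
robustness to the correlated artifacts of real chromatin input.

## Study conditions used by the simulation-based tests

The end-to-end guarantees in the test suite run at one fixed set of
conditions, chosen from Poisson tail bounds at design time: a 1-Mb
chromosome, 10,000 background reads of 36 bp extended to 200 bp fragments
(mean coverage 2), planted peak width 300 bp at fold 10 (expected summit
coverage ≈ 20), control at equal depth. Analysis parameters:
`min_region 100`, `max_region 2000`, `cutoff 4` (twice the background
mean), `min_supported_reads 15`, `k_fold 2`. At threshold 15 the background
produces a qualifying bin with probability ≈ 4·10⁻³ per megabase
(P[Pois(2) ≥ 15] ≈ 3.9·10⁻⁹ per bp), while the peak summit reaches it with
probability ≈ 0.996 — so the null stays clean and recovery is near-certain,
with no tuning margin consumed. The oracle-equivalence checks use ≥ 200
random windows of 50–2000 bins (plus a few of 10⁴ bins) over 100 seeds;
recovery and null calibration use 50 seeds each, the enrichment-score null
20 seeds on 200-kb genomes.

## Known limitations

- The division criterion is positional: with *no* surrounding background
  mass in the window (exact zeros), the argmax for a single isolated block
  falls inside the block rather than after it, because a split beyond all
  mass leaves one class empty (σ_B² = 0). In the method's operating regime
  — nonzero background sharing the window — the valley/edge split dominates
  and isolated peaks are recovered whole; very heavily enriched or broad
  regions can still be emitted as adjacent abutting calls, and signal wider
  than `max_region` is tiled by construction.
- One division point per window, placed greedily left to right; no global
  joint optimization over all thresholds.
- No statistical significance model: ranking is by fold enrichment only,
  and uncertainty is assessed externally (sample swapping).
- Fragment length is a user input; no cross-correlation estimator is
  provided.
- Right-edge clipping of fragments requires a chrom-sizes file; without it
  fragments may overhang the true chromosome end.
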