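# Methods

## The occurrence-distance statistic

For a dinucleotide MN and window W, the positional autocorrelation is the
histogram over integer distances d ∈ [2, W] of start-to-start separations
between MN occurrences. Occurrences may overlap (AA occurs twice in AAA);
distance 1, which only homodinucleotides can produce, is excluded so that
the domain matches the conventional 2–W plotting range. Distances are
differences of 0-based start coordinates; every coordinate in the package
is 0-based, half-open, converted only at format boundaries (BLAST tabular
input is 1-based inclusive with reversed subject coordinates on the minus
strand).

Two boundary rules make the statistic well defined on masked genomes:

1. **Segment confinement.** Counting operates within *analyzable segments*:
   maximal runs of A/C/G/T, where lowercase (soft-masked) bases break
   segments under `mask_mode="masked"` and are kept under `"none"`; N
   breaks segments always, since a hard-masked base carries no dinucleotide
   information. A pair of occurrences is counted only within one segment.
2. **Anchor validity.** An anchor at position i of segment [s, e) is used
   only if the dinucleotide at distance W fits wholly inside the segment:
   i + W + 1 ≤ e − 1. This one condition implements both disruption at
   masked repeats/sequence ends and the exclusion of end-proximal anchors,
   which would otherwise see only short distances and bias the histogram
   left.

The anchor rule looks downstream only. A consequence worth knowing: the
raw histogram of a sequence and of its reverse complement agree exactly for
self-complementary dinucleotides (CG, GC, AT, TA) only when no occurrence
lies within W of a segment boundary; occurrences inside that margin are
anchors in one orientation but partners-only in the other. On
genome-scale input the discrepancy is a vanishing fraction of counts; the
test suite checks the symmetry exactly on sequences padded clear of the
margin.

Normalization divides by the mean raw count over [2, W], pinning the
average at level 1.0; it refuses an all-zero histogram rather than emit
NaNs. Smoothing is a centered running average (default width 3, odd widths
only) applied after normalization; at the two domain edges the average is
truncated to the available neighbors. Normalizing and smoothing commute in
the interior, so the order only affects the edge bins; fixing
normalize-then-smooth makes outputs deterministic. Note the truncated-edge
smoother preserves a constant curve and equals the exact k-window mean at
every interior point, but it does not preserve the curve's mean (the edge
columns of the smoothing matrix sum to less than one).

Multi-record inputs sum raw counts across records before normalizing, the
way a whole-genome curve pools chromosomes; pairs never span records.

## Peak calling and period estimation

A distance d is a local maximum of the smoothed curve iff its value
strictly exceeds both neighbors; the domain edges are ineligible, and a
plateau of exactly tied values flanked by lower neighbors is reported once,
at its leftmost distance. The default height floor of 1.0 requires peaks
to rise above the normalized average level. Exact plateaus are not a
pathological case here: on noise-free planted lattices the flanking counts
are exactly zero and two-bin plateaus are the norm (see "Known behaviors"
below).

Each peak is assigned to the multiple k = round(d / p) of the reference
period p (default 10.4 bases) iff k ≥ 1 and |d − k·p| ≤ 1.5. The 1.5-base
tolerance admits the ≤ 0.5-base rounding of integer peak positions plus a
±1 smoothing shift, while rejecting the ~8-base secondary spacing that
Alu-derived curves carry between the 31/62 peaks. The period is then
re-estimated from assigned peaks by unweighted least squares through the
origin, p̂ = Σk·d_k / Σk², with the residual RMS reported; at least two
assigned peaks are required. Weighting by peak height was considered and
left out: on the synthetic conditions it changes p̂ by less than the
rounding noise, and the unweighted estimator is the simplest one consistent
with reading peaks as "multiples of p".

When ranking peaks by height (e.g. reporting the two dominant peaks),
heights within 1e-9 relative tolerance are treated as tied and ordered by
ascending distance. On planted lattices the k and 2k peaks can be *exactly*
equal in infinite precision, and without the tolerance the ranking would be
decided by last-ulp rounding of the normalization divide.

## Repeat spacing and the run census

Inputs are repeat-match intervals from BLAST tabular or BED. Processing:

- **Dedup** (threshold 250): greedy sweep per chromosome over
  start-sorted matches; a match is dropped iff its start is strictly less
  than 250 beyond the start of the last *retained* match, keeping the most
  upstream copy of a crowded group. Retained start gaps are therefore all
  ≥ 250 and the sweep is idempotent. The comparison is strand-agnostic.
- **Head-to-head spectrum**: counts *all* ordered same-chromosome pairs
  with 0 < Δstart ≤ 1000 into 10-base bins, not only nearest neighbors —
  the second mode near 620 bases arises from first-to-third members of
  trimers, which consecutive-pair distances cannot produce.
- **Run census** (gap threshold 500): consecutive matches belong to one
  run iff their start-to-start gap is ≤ 500, which separates the ~310-base
  tandem spacing from kilobase-scale inter-run spacers. The mean
  tail-to-head spacer (previous run's end to next run's start) is reported;
  negative gaps from overlapping input are excluded with a warning. The
  gap threshold is a package decision exposed as a flag, not a quantity
  with a canonical value.

`scan_consensus` locates approximate copies of a consensus in synthetic
fixtures by sliding the consensus and its reverse complement over every
offset, keeping windows at ≥ 80% identity after greedy non-overlapping
selection (best identity first, ties by position). It is deliberately
ungapped and scoring-matrix-free: a fixture-scale matcher for sequences the
generator built, not a local aligner, and it will miss indel-diverged
copies that a real aligner would find.

## The synthetic generator

All generation is a pure function of the spec (including its seed);
rerunning a spec is byte-identical. Defaults encode the genomic conditions
the analyses presume:

| parameter | default | meaning |
|---|---|---|
| period | 10.4 bases | nucleosome DNA helical repeat |
| stride | 1 or 3 | CG every turn (bulk-genome signal) or every third (Alu-internal) |
| occupancy | 1.0 / 0.8 | per-site retention probability of lattice CGs |
| unit_length | 300 bases | one Alu-scale repeat copy |
| intra_run_start_spacing | 310 bases | tandem head-to-head spacing within a run |
| cluster_proportions | 0.884 / 0.100 / 0.016 | monomer/dimer/trimer mix of the genomic Alu census |
| mean_spacer | 2300 bases | tail-to-head inter-run spacer mean |
| min_spacer | 300 bases | spacer left-truncation (see below) |

Lattice positions are phase + round(period·stride·k), rounded half away
from zero, which reproduces the nearest-integer reading of period multiples
(10.4, 20.8, 31.2 → 10, 21, 31). Planting overwrites the two bases in
place, so sequence length and every other truth coordinate stay stable.
The CG-free background resamples the G of every emergent CG from the
non-G frequencies, iterating because a drawn C can create a new CG with the
following base; with it, planted CpGs are provably the only CpG signal and
the raw histogram has a closed-form oracle (the pair-distance multiset of
the planted positions under the anchor rule).

Inter-run spacers are geometric with the stated mean, left-truncated at
`min_spacer`. Untruncated spacers would occasionally fall inside the
run-clustering gap and merge two planted runs, making the planted census
unrecoverable by construction; truncating at one unit length keeps runs
unambiguous while moving the realized spacer mean by under 1%.

What the generator does *not* emulate: base-composition heterogeneity
(isochores, CpG islands), repeat sequence divergence and indels, subfamily
structure, and any coupling between the CG lattice and repeat placement.
Passing tests therefore demonstrate that the pipeline recovers the signals
it targets under clean conditions with known truth — not that real genomes
contain those signals at any particular strength.

## Problem sizes and determinism

The end-to-end checks run on 1-Mb genomes (~96k planted CGs at stride 1,
~32k at stride 3), a 7-Mb genome with 2000 planted repeat runs for the
census, and ≥ 50 random masked sequences up to 20 kb for exact-count
agreement with a literal brute-force re-implementation of the counting
rules. At these sizes the peak positions, the recovered period (±0.2 of
the planted 10.4) and the census are stable across seeds; every random
draw flows from an explicit integer seed.

## Known behaviors and limitations

- On noise-free lattices the smoothed curve has exact two-bin plateaus
  (flanking counts are exactly zero), and the leftmost-plateau rule can
  report a maximum one base left of the rounded period multiple — e.g. the
  k = 2 peak of the stride-1 lattice appears at 20 rather than 21. Real,
  noisy genomes break these ties. The period estimate absorbs the shift
  (it enters as a ≤ 1-base residual).
- Histogram counts are exact integers; no approximation is made anywhere
  in the counting path, so oracle comparisons are equality, not tolerance.
- The CLI writes TSV/JSON only; figures are derivable from the TSVs.
- Statistical significance of periodicity is out of scope: no null model
  is fitted, and peak heights are descriptive.
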