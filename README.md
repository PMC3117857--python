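# nucperiod

Positional dinucleotide autocorrelation for genomic DNA, with peak calling
against the ~10.4-base nucleosome period and Alu-style repeat spacing/cluster
analysis. For genome sequence analysts studying nucleosome positioning
signals — in particular the CpG periodicity that is the one visible
dinucleotide signature in the human genome — and for anyone who needs a
tested, mask-aware implementation of the occurrence-distance statistic.

## What it computes

**Positional autocorrelation.** For a dinucleotide MN, every occurrence at
position *i* (an *anchor*) contributes the start-to-start distances
*d = j − i* to all downstream occurrences *j* with 2 ≤ *d* ≤ *W*
(window *W* = 80 by default). Counting never crosses a masked repeat
(lowercase or N in the FASTA) or a sequence end, and an anchor is used only
when its whole window fits inside one analyzable segment, which removes the
short-distance bias near segment ends. The histogram over *d* ∈ [2, W] is
normalized by its mean (level 1.0 = average score) and smoothed by a
3-point running average. Peaks of the smoothed curve at integer distances
near multiples of *p* ≈ 10.4 bases — the helical repeat of DNA on the
nucleosome — indicate a nucleosome positioning signal; the period is
re-estimated from the called peaks by a through-origin fit
p̂ = Σk·d_k / Σk².

**Repeat clustering.** From repeat-match coordinates (BLAST outfmt 6 or
BED), the package deduplicates crowded matches (starts < 250 bases apart
keep only the upstream copy), builds the head-to-head start-distance
spectrum whose ~310 and ~620 base modes reveal tandem dimers and trimers,
and counts monomer/dimer/trimer runs with tail-to-head spacer statistics —
the census of candidate "anchor" nucleosome arrays.

**Synthetic genomes.** A generator plants these exact signals with
machine-readable truth: CG-free i.i.d. background, CG on a period-10.4
lattice (stride 3 emulates the 31/32-base CpG spacing internal to Alu
repeats; stride 1 the weak genome-wide CpG periodicity), and repeat units
inserted as monomer/dimer/trimer runs with ~310-base internal spacing.

## Worked example

```sh
nucperiod demo --seed 1 --length 1000000 --outdir demo_out
```

simulates two 1-Mb CG-free genomes, profiles CG, and calls peaks:

```
alu_style: top peaks at d=31 (height 13.2), d=62 (height 13.2)
alu_style: peaks ascending: d=31 (k=3), d=62 (k=6)
alu_style: p_hat=10.3333 from 2 peaks (residual rms 0.000)
genome_style: top peaks at d=41 (height 3.8), d=10 (height 3.8)
genome_style: peaks ascending: d=10 (k=1), d=20 (k=2), d=31 (k=3), d=41 (k=4), d=51 (k=5), d=62 (k=6), d=72 (k=7)
genome_style: p_hat=10.2714 from 7 peaks (residual rms 0.313)
```

The *alu_style* genome (CG planted every three helical turns, as inside Alu
repeats) shows exactly the two dominant peaks at 31 and 62 bases — 10.4×3
and 10.4×6 — rising 13-fold above the average level 1.0. The *genome_style*
genome (CG planted every turn at 80% occupancy) yields the full ladder of
maxima at the nearest integers to multiples of 10.4, and the through-origin
fit over the seven assigned peaks recovers the planted period to within
0.13 bases. Each `*.profile.tsv` carries the raw, normalized and smoothed
curves plus a metadata header (window, mask mode, normalization constant,
anchor count) from which the run is reproducible.

The same pipeline runs on real FASTA:

```sh
nucperiod autocorr --fasta genome_masked.fa --dinuc CG --window 80 \
    --mask-mode masked --out cg_profile.tsv
nucperiod peaks --profile cg_profile.tsv --period 10.4 --tol 1.5
nucperiod repeats --matches alu_hits.tsv --format blast6 --dedup 250 --gap 500
```

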