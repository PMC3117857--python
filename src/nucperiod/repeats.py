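"""Repeat-match post-processing: dedup, spacing spectra, run census.

Works on repeat coordinates (e.g. Alu matches) from BLAST tabular or BED
input.  The pipeline is: deduplicate crowded matches (keep the upstream copy
when starts are < 250 bases apart), build the head-to-head start-distance
spectrum whose ~310 and ~620 base modes reveal tandem dimers and trimers,
and cluster consecutive matches into runs (monomers/dimers/trimers — the
candidate "anchor" nucleosome arrays) with tail-to-head spacer statistics.

A fixture-scale ungapped consensus scanner is provided for synthetic
genomes; it is a simple sliding-identity matcher, not a local aligner.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "RepeatMatch",
    "DistanceSpectrum",
    "RepeatRunSummary",
    "read_matches",
    "write_bed",
    "dedup_matches",
    "distance_spectrum",
    "cluster_runs",
    "scan_consensus",
]


@dataclass(frozen=True, order=True)
class RepeatMatch:
    """One repeat match in 0-based half-open genome coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    identity: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be +, - or ., got {self.strand!r}")
        if self.identity is not None and not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be a percentage in [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_matches(path: str | Path, format: str = "blast6") -> list[RepeatMatch]:
    """Read repeat matches from BLAST tabular (outfmt 6) or BED.

    BLAST subject coordinates are 1-based inclusive and reversed on the
    minus strand; both dialects are converted to 0-based half-open intervals
    with the strand inferred from the sstart/send orientation.  Output is
    sorted by (chrom, start).
    """
    matches: list[RepeatMatch] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if format == "blast6":
                    # qseqid sseqid pident length mismatch gapopen
                    # qstart qend sstart send evalue bitscore
                    chrom = fields[1]
                    identity = float(fields[2])
                    sstart, send = int(fields[8]), int(fields[9])
                    if sstart <= send:
                        start, end, strand = sstart - 1, send, "+"
                    else:
                        start, end, strand = send - 1, sstart, "-"
                    matches.append(RepeatMatch(chrom, start, end, strand, identity))
                elif format == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    strand = fields[5] if len(fields) >= 6 else "."
                    matches.append(RepeatMatch(chrom, start, end, strand))
                else:
                    raise ValueError(f"unknown match format {format!r}")
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ValueError) and "unknown match format" in str(exc):
                    raise
                raise ValueError(f"{path}: unparseable {format} line {lineno}: {exc}")
    matches.sort(key=lambda m: (m.chrom, m.start, m.end))
    return matches


def write_bed(matches: Iterable[RepeatMatch], path: str | Path, name: str = "repeat") -> None:
    """Write matches as BED6; the score column carries percent identity."""
    with open(path, "w") as handle:
        for m in matches:
            score = 0 if m.identity is None else int(round(m.identity * 10))
            handle.write(f"{m.chrom}\t{m.start}\t{m.end}\t{name}\t{score}\t{m.strand}\n")


def dedup_matches(matches: Sequence[RepeatMatch], threshold: int = 250) -> list[RepeatMatch]:
    """Keep only the upstream copy of matches whose starts crowd together.

    Greedy sweep per chromosome over matches sorted by start: keep the first
    match; drop any match whose start is strictly less than ``threshold``
    beyond the start of the last *retained* match.  Retained within-chrom
    start gaps are therefore all >= threshold, and the sweep is idempotent.
    """
    kept: list[RepeatMatch] = []
    last_chrom: str | None = None
    last_start = 0
    for m in sorted(matches, key=lambda m: (m.chrom, m.start, m.end)):
        if m.chrom != last_chrom or m.start - last_start >= threshold:
            kept.append(m)
            last_chrom, last_start = m.chrom, m.start
    return kept


@dataclass(frozen=True)
class DistanceSpectrum:
    """Histogram of head-to-head (start-to-start) distances.

    Bin b covers the half-open-from-the-left interval
    (b*bin_width, (b+1)*bin_width]; bins tile (0, max_distance].
    """

    bin_width: int
    max_distance: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.max_distance % self.bin_width != 0:
            raise ValueError("max_distance must be a multiple of bin_width")
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))

    @property
    def n_bins(self) -> int:
        return self.max_distance // self.bin_width

    def bin_of(self, distance: int) -> int:
        if not 0 < distance <= self.max_distance:
            raise ValueError(f"distance {distance} outside (0, {self.max_distance}]")
        return (distance - 1) // self.bin_width

    def total(self) -> int:
        return int(self.counts.sum())

    def modes(self, n: int = 2) -> list[int]:
        """Centers (upper edges rounded to bin midpoint) of the n fullest bins."""
        order = np.argsort(self.counts)[::-1][:n]
        return sorted(int(b * self.bin_width + self.bin_width // 2) for b in order)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write(f"# bin_width: {self.bin_width}\n")
            handle.write(f"# max_distance: {self.max_distance}\n")
            handle.write("bin_start\tbin_end\tcount\n")
            for b in range(self.n_bins):
                handle.write(
                    f"{b * self.bin_width}\t{(b + 1) * self.bin_width}\t{int(self.counts[b])}\n"
                )


def distance_spectrum(
    matches: Sequence[RepeatMatch], max_distance: int = 1000, bin_width: int = 10
) -> DistanceSpectrum:
    """Head-to-head distance spectrum over *all* same-chromosome pairs.

    Every ordered pair with 0 < start_j - start_i <= max_distance contributes
    (not only consecutive matches): in a tandem trimer the first-to-third
    spacing — twice the intra-run spacing — is exactly the signal that the
    second spectral mode carries.
    """
    if bin_width <= 0 or max_distance <= 0 or max_distance % bin_width != 0:
        raise ValueError("max_distance must be a positive multiple of bin_width")
    counts = np.zeros(max_distance // bin_width, dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for m in matches:
        by_chrom.setdefault(m.chrom, []).append(m.start)
    for starts in by_chrom.values():
        s = np.array(sorted(starts), dtype=np.int64)
        for i in range(len(s)):
            hi = np.searchsorted(s, s[i] + max_distance, side="right")
            lo = np.searchsorted(s, s[i], side="right")
            diffs = s[lo:hi] - s[i]
            diffs = diffs[diffs > 0]
            if diffs.size:
                np.add.at(counts, (diffs - 1) // bin_width, 1)
    return DistanceSpectrum(bin_width, max_distance, counts)


@dataclass(frozen=True)
class RepeatRunSummary:
    """Monomer/dimer/trimer/... census of tandem repeat runs.

    ``runs_by_size[s]`` counts runs of s consecutive matches whose
    start-to-start gaps are all <= gap_threshold; ``mean_spacer`` is the
    average tail-to-head gap (previous run's last end to next run's first
    start) between consecutive runs on a chromosome.
    """

    runs_by_size: dict[int, int]
    gap_threshold: int
    mean_spacer: float
    n_total_matches: int
    n_spacers: int = 0

    def __post_init__(self) -> None:
        total = sum(size * count for size, count in self.runs_by_size.items())
        if total != self.n_total_matches:
            raise ValueError(
                f"run census covers {total} matches but n_total_matches={self.n_total_matches}"
            )

    @property
    def n_runs(self) -> int:
        return sum(self.runs_by_size.values())


def cluster_runs(
    matches: Sequence[RepeatMatch], gap_threshold: int = 500
) -> RepeatRunSummary:
    """Group consecutive same-chromosome matches into tandem runs.

    Two consecutive matches belong to one run iff the start-to-start gap is
    <= gap_threshold.  The default of 500 separates the ~310-base tandem
    spacing of repeat runs from the ~kilobase-scale spacers between runs.
    Negative tail-to-head gaps (overlapping runs) are excluded from the
    spacer mean with a warning.
    """
    ordered = sorted(matches, key=lambda m: (m.chrom, m.start, m.end))
    runs_by_size: Counter[int] = Counter()
    spacers: list[int] = []
    n_clamped = 0

    i = 0
    n = len(ordered)
    while i < n:
        j = i
        while (
            j + 1 < n
            and ordered[j + 1].chrom == ordered[i].chrom
            and ordered[j + 1].start - ordered[j].start <= gap_threshold
        ):
            j += 1
        runs_by_size[j - i + 1] += 1
        if j + 1 < n and ordered[j + 1].chrom == ordered[i].chrom:
            gap = ordered[j + 1].start - ordered[j].end
            if gap >= 0:
                spacers.append(gap)
            else:
                n_clamped += 1
        i = j + 1

    if n_clamped:
        warnings.warn(
            f"{n_clamped} negative tail-to-head gap(s) excluded from spacer mean",
            stacklevel=2,
        )
    mean_spacer = float(np.mean(spacers)) if spacers else 0.0
    return RepeatRunSummary(
        runs_by_size=dict(runs_by_size),
        gap_threshold=gap_threshold,
        mean_spacer=mean_spacer,
        n_total_matches=n,
        n_spacers=len(spacers),
    )


def scan_consensus(
    record: SequenceRecord, consensus: str, min_identity: float = 80.0
) -> list[RepeatMatch]:
    """Locate approximate copies of a consensus by ungapped sliding identity.

    The consensus (and its reverse complement) is slid over every offset of
    the record; windows whose percent identity reaches ``min_identity`` are
    reported after greedy non-overlapping selection, best identity first
    (ties broken by position and then + strand).  Case is ignored (a scan of
    the unmasked sequence); N never matches.  This is a deliberately simple
    fixture-scale matcher: ungapped, no scoring matrix, no e-values.
    """
    if len(consensus) < 50:
        raise ValueError("consensus must be at least 50 bases")
    seq = record.residues.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    m = len(consensus)
    n_offsets = len(seq) - m + 1
    if n_offsets <= 0:
        return []

    candidates: list[tuple[float, int, str]] = []
    for strand, probe in (("+", consensus.upper()), ("-", reverse_complement(consensus).upper())):
        probe_arr = np.frombuffer(probe.encode("ascii"), dtype=np.uint8)
        score = np.zeros(n_offsets, dtype=np.int32)
        for c in range(m):
            score += arr[c : c + n_offsets] == probe_arr[c]
        identity = 100.0 * score / m
        for offset in np.flatnonzero(identity >= min_identity):
            candidates.append((float(identity[offset]), int(offset), strand))

    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    occupied = np.zeros(len(seq), dtype=bool)
    hits: list[RepeatMatch] = []
    for identity, offset, strand in candidates:
        if not occupied[offset : offset + m].any():
            occupied[offset : offset + m] = True
            hits.append(RepeatMatch(record.id, offset, offset + m, strand, identity))
    hits.sort(key=lambda h: h.start)
    return hits
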