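"""FASTA input with repeat-mask awareness.

Genome builds such as those distributed by UCSC mark repeats either by
lowercasing (soft masking) or by substituting N (hard masking).  Dinucleotide
spacing statistics must never pair bases across a masked stretch, so the
reader preserves case verbatim and masking is interpreted lazily, by
:func:`analyzable_segments`, at analysis time.  One file thus serves both the
whole-genome and the repeat-filtered analyses.

Coordinates are 0-based, half-open throughout the package; conversion to
1-based conventions happens only at format boundaries (BLAST tabular input,
see :mod:`nucperiod.repeats`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "SequenceRecord",
    "SegmentSet",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "analyzable_segments",
]

MaskMode = Literal["none", "masked"]

_ALLOWED = frozenset("ACGTNacgtn")

# Maximal runs of analyzable bases.  N/n always break segments: a hard-masked
# base carries no dinucleotide information regardless of mask mode.
_SEGMENT_PATTERNS: dict[str, re.Pattern[str]] = {
    "masked": re.compile(r"[ACGT]+"),
    "none": re.compile(r"[ACGTacgt]+"),
}


class FastaParseError(ValueError):
    """Raised on malformed FASTA input; the message names the line number."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record, with soft/hard masking preserved verbatim.

    Residues are restricted to ``{A,C,G,T,N}`` in either case; anything else
    is rejected on construction.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValueError(
                f"record {self.id!r}: disallowed residue(s) {sorted(bad)!r}; "
                "allowed alphabet is ACGTN in either case"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        """Reverse complement, preserving the soft-mask (case) pattern."""
        return SequenceRecord(self.id, reverse_complement(self.residues))


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; case (soft masking) is preserved."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SegmentSet:
    """Ordered, disjoint half-open intervals of analyzable sequence.

    Under ``mask_mode="masked"`` every base inside a segment is uppercase
    ACGT; under ``mask_mode="none"`` lowercase is analyzable too.  N always
    breaks segments.
    """

    record_id: str
    segments: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.segments:
            if not (0 <= start < end):
                raise ValueError(f"invalid segment [{start}, {end})")
            if start <= prev_end:
                raise ValueError("segments must be sorted and non-overlapping")
            prev_end = end

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def total_length(self) -> int:
        return sum(end - start for start, end in self.segments)

    def to_bed3(self) -> list[str]:
        """Segments as BED3 lines (0-based half-open, as stored)."""
        return [f"{self.record_id}\t{s}\t{e}" for s, e in self.segments]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Residue case is preserved verbatim so that soft masking survives the
    round trip.  Raises :class:`FastaParseError` naming the offending line
    for malformed headers or residues outside ``ACGTN``/``acgtn``.
    """
    records: list[SequenceRecord] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is not None:
            records.append(SequenceRecord(current_id, "".join(chunks)))

    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                bad = set(line) - _ALLOWED
                if bad:
                    raise FastaParseError(
                        f"line {lineno}: disallowed character(s) "
                        f"{''.join(sorted(bad))!r} (alphabet is ACGTN, any case)"
                    )
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (case preserved)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as _bio_write
    from Bio.SeqRecord import SeqRecord as _BioRecord

    bio = [_BioRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        _bio_write(bio, handle, "fasta")
    # Biopython wraps at 60 columns; other widths are not needed here.
    del width


def analyzable_segments(record: SequenceRecord, mask_mode: MaskMode = "none") -> SegmentSet:
    """Maximal runs of analyzable bases of ``record`` under ``mask_mode``.

    ``masked`` treats lowercase (soft-masked) bases as breaks; ``none`` keeps
    them.  Hard-masked N/n always breaks.  A record with no analyzable base
    yields an empty :class:`SegmentSet`.
    """
    try:
        pattern = _SEGMENT_PATTERNS[mask_mode]
    except KeyError:
        raise ValueError(f"unknown mask_mode {mask_mode!r}; use 'none' or 'masked'")
    segments = tuple(m.span() for m in pattern.finditer(record.residues))
    return SegmentSet(record.id, segments)
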