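"""Positional autocorrelation of a dinucleotide.

The central statistic: for every occurrence of a dinucleotide MN (the
*anchor*), count the start-to-start distances to all downstream MN
occurrences within a fixed window W.  Preferred distances show up as peaks
of the resulting occurrence-distance histogram; a ~10.4-base spacing of the
peaks is the classic nucleosome positioning signature.

Two boundary rules make the statistic well defined on masked genomes:

* counting is disrupted at masked repeats and sequence ends — an anchor and
  its partners must lie in one analyzable segment;
* an anchor is *valid* only if the whole window fits inside its segment
  (the dinucleotide at distance W must lie wholly inside), which removes the
  short-distance bias that anchors near segment ends would otherwise
  introduce.

Both rules reduce to a single condition on the anchor position i within a
segment [s, e): ``i + W + 1 <= e - 1``.

The histogram domain is the integer distances 2..W (distance 1, possible
only for homodinucleotides such as AA in AAA, is excluded).  Normalization
divides by the mean raw count over that domain, so level 1.0 is the average
score; smoothing is a centered running average (default width 3) applied
after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import MaskMode, SequenceRecord, analyzable_segments

__all__ = [
    "DistanceHistogram",
    "AutocorrProfile",
    "dinucleotide_positions",
    "distance_histogram",
    "normalize",
    "smooth",
    "autocorr_profile",
]

_VALID_DINUC_CHARS = frozenset("ACGT")


def _check_dinuc(dinuc: str) -> str:
    if len(dinuc) != 2 or not set(dinuc) <= _VALID_DINUC_CHARS:
        raise ValueError(f"dinucleotide must be a 2-mer over ACGT, got {dinuc!r}")
    return dinuc


@dataclass(frozen=True)
class DistanceHistogram:
    """Occurrence-distance histogram of a dinucleotide over distances 2..W.

    ``counts[k]`` holds the score for distance ``k + 2``; ``stage`` is one of
    ``raw`` (integer pair counts), ``normalized`` (mean over the domain is
    1.0) or ``smoothed``.  ``norm_constant`` records the raw mean used as the
    level-1.0 divisor once normalized.
    """

    dinuc: str
    window: int
    counts: np.ndarray
    n_anchors: int = 0
    stage: str = "raw"
    norm_constant: float | None = None
    mask_mode: str = "none"

    def __post_init__(self) -> None:
        _check_dinuc(self.dinuc)
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if len(self.counts) != self.window - 1:
            raise ValueError(
                f"counts must cover distances 2..{self.window} "
                f"({self.window - 1} values), got {len(self.counts)}"
            )
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))

    @property
    def distances(self) -> np.ndarray:
        """Integer distance domain, 2..window inclusive."""
        return np.arange(2, self.window + 1)

    def __getitem__(self, distance: int) -> float:
        if not 2 <= distance <= self.window:
            raise KeyError(f"distance {distance} outside domain [2, {self.window}]")
        return float(self.counts[distance - 2])

    def as_dict(self) -> dict[int, float]:
        return {int(d): float(c) for d, c in zip(self.distances, self.counts)}


def dinucleotide_positions(sequence: str, dinuc: str) -> np.ndarray:
    """0-based start positions of ``dinuc`` in ``sequence``, overlaps included.

    ``sequence`` must be uppercase ACGT only (an analyzable segment).
    """
    _check_dinuc(dinuc)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    if arr.size < 2:
        return np.empty(0, dtype=np.intp)
    first, second = (ord(c) for c in dinuc)
    return np.flatnonzero((arr[:-1] == first) & (arr[1:] == second))


def _occurrence_indicator(segment: str, dinuc: str) -> np.ndarray:
    arr = np.frombuffer(segment.encode("ascii"), dtype=np.uint8)
    if arr.size < 2:
        return np.zeros(0, dtype=bool)
    first, second = (ord(c) for c in dinuc)
    return (arr[:-1] == first) & (arr[1:] == second)


def distance_histogram(
    record: SequenceRecord,
    dinuc: str,
    window: int = 80,
    mask_mode: MaskMode = "none",
) -> DistanceHistogram:
    """Raw occurrence-distance histogram of ``dinuc`` over one record.

    For every analyzable segment [s, e) and every dinucleotide occurrence at
    i with ``i + window + 1 <= e - 1`` (a valid anchor), each downstream
    occurrence at j in the same segment with ``2 <= j - i <= window``
    increments ``counts[j - i]``.  Ordered pairs are counted once.
    """
    _check_dinuc(dinuc)
    if window < 2:
        raise ValueError("window must be >= 2")

    counts = np.zeros(window - 1, dtype=np.int64)
    n_anchors = 0
    for start, end in analyzable_segments(record, mask_mode):
        segment = record.residues[start:end].upper()
        occ = _occurrence_indicator(segment, dinuc)
        if occ.size == 0:
            continue
        seg_len = end - start
        # anchor at relative position i is valid iff i <= seg_len - window - 2
        limit = seg_len - window - 2
        if limit < 0:
            continue
        anchors = occ.copy()
        anchors[limit + 1 :] = False
        n_anchors += int(anchors.sum())
        for d in range(2, window + 1):
            if d >= occ.size:
                break
            counts[d - 2] += int(np.count_nonzero(anchors[:-d] & occ[d:]))
    return DistanceHistogram(
        dinuc=dinuc,
        window=window,
        counts=counts,
        n_anchors=n_anchors,
        stage="raw",
        mask_mode=mask_mode,
    )


def normalize(histogram: DistanceHistogram) -> DistanceHistogram:
    """Divide by the mean count over the domain, fixing level 1.0 at average.

    Raises if the histogram is all-zero (degenerate input is surfaced as an
    explicit error rather than NaNs).
    """
    if histogram.stage != "raw":
        raise ValueError(f"normalize expects a raw histogram, got {histogram.stage!r}")
    mean = float(histogram.counts.mean())
    if mean == 0.0:
        raise ValueError("empty histogram, cannot normalize")
    return replace(
        histogram,
        counts=histogram.counts / mean,
        stage="normalized",
        norm_constant=mean,
    )


def smooth(histogram: DistanceHistogram, k: int = 3) -> DistanceHistogram:
    """Centered running average of odd width ``k``.

    At the domain edges the average is taken over the available neighbors
    only (truncated window), so a constant curve is left unchanged
    everywhere.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"smoothing width must be a positive odd integer, got {k}")
    if k == 1:
        return replace(histogram, stage="smoothed")
    kernel = np.ones(k)
    num = np.convolve(histogram.counts, kernel, mode="same")
    den = np.convolve(np.ones_like(histogram.counts), kernel, mode="same")
    return replace(histogram, counts=num / den, stage="smoothed")


@dataclass(frozen=True)
class AutocorrProfile:
    """All three stages of a (possibly multi-record) autocorrelation curve.

    Raw counts are summed across records before normalization; pairs never
    span records.
    """

    dinuc: str
    window: int
    mask_mode: str
    smooth_k: int
    norm_constant: float
    n_anchors: int
    raw: np.ndarray
    normalized: np.ndarray
    smoothed: np.ndarray

    @property
    def distances(self) -> np.ndarray:
        return np.arange(2, self.window + 1)

    def to_tsv(self, path: str | Path) -> None:
        """Write the profile with a metadata header for full reproducibility."""
        with open(path, "w") as handle:
            handle.write(f"# dinuc: {self.dinuc}\n")
            handle.write(f"# window: {self.window}\n")
            handle.write(f"# mask_mode: {self.mask_mode}\n")
            handle.write(f"# smooth_k: {self.smooth_k}\n")
            handle.write(f"# norm_constant: {self.norm_constant!r}\n")
            handle.write(f"# n_anchors: {self.n_anchors}\n")
            handle.write("distance\traw_count\tnormalized\tsmoothed\n")
            for i, d in enumerate(self.distances):
                handle.write(
                    f"{d}\t{int(self.raw[i])}\t{float(self.normalized[i])!r}"
                    f"\t{float(self.smoothed[i])!r}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AutocorrProfile":
        meta: dict[str, str] = {}
        rows: list[tuple[int, float, float, float]] = []
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, value = line[1:].partition(":")
                    meta[key.strip()] = value.strip()
                elif line and not line.startswith("distance"):
                    d, raw, norm, smo = line.split("\t")
                    rows.append((int(d), float(raw), float(norm), float(smo)))
        if not rows:
            raise ValueError(f"no profile rows in {path}")
        return cls(
            dinuc=meta["dinuc"],
            window=int(meta["window"]),
            mask_mode=meta.get("mask_mode", "none"),
            smooth_k=int(meta.get("smooth_k", 3)),
            norm_constant=float(meta["norm_constant"]),
            n_anchors=int(meta.get("n_anchors", 0)),
            raw=np.array([r[1] for r in rows]),
            normalized=np.array([r[2] for r in rows]),
            smoothed=np.array([r[3] for r in rows]),
        )


def autocorr_profile(
    records: Sequence[SequenceRecord] | Iterable[SequenceRecord],
    dinuc: str,
    window: int = 80,
    mask_mode: MaskMode = "none",
    smooth_k: int = 3,
) -> AutocorrProfile:
    """Raw → normalized → smoothed autocorrelation over one or more records.

    Per-record raw histograms are summed (a whole-genome curve is built from
    all chromosomes), then normalized by the pooled mean and smoothed.
    """
    records = list(records)
    if not records:
        raise ValueError("autocorr_profile needs at least one record")
    total = np.zeros(window - 1, dtype=np.int64)
    n_anchors = 0
    for record in records:
        hist = distance_histogram(record, dinuc, window=window, mask_mode=mask_mode)
        total += hist.counts.astype(np.int64)
        n_anchors += hist.n_anchors
    raw = DistanceHistogram(
        dinuc=dinuc,
        window=window,
        counts=total,
        n_anchors=n_anchors,
        stage="raw",
        mask_mode=mask_mode,
    )
    normalized = normalize(raw)
    smoothed = smooth(normalized, k=smooth_k)
    return AutocorrProfile(
        dinuc=dinuc,
        window=window,
        mask_mode=mask_mode,
        smooth_k=smooth_k,
        norm_constant=float(normalized.norm_constant),
        n_anchors=n_anchors,
        raw=raw.counts.copy(),
        normalized=normalized.counts,
        smoothed=smoothed.counts,
    )
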