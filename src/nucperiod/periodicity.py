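"""Peak calling and helical-period estimation on smoothed profiles.

Local maxima of the smoothed autocorrelation curve are assigned to
nearest-integer multiples of the nucleosome DNA period (default 10.4 bases,
the helical repeat of DNA on the histone octamer), and the period itself is
re-estimated from the assigned peaks by a through-origin least-squares fit
of peak distance on multiple index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .autocorr import AutocorrProfile, DistanceHistogram

__all__ = [
    "Peak",
    "PeakSet",
    "PeriodEstimate",
    "local_maxima",
    "assign_period_multiples",
    "estimate_period",
    "top_peaks",
]

NUCLEOSOME_PERIOD = 10.4  # bases per helical turn of nucleosomal DNA


@dataclass(frozen=True)
class Peak:
    """One called maximum: integer distance, curve height, and (once
    assigned) the period multiple k with its offset d - k*period."""

    distance: int
    height: float
    k: int | None = None
    offset: float | None = None

    @property
    def assigned(self) -> bool:
        return self.k is not None


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...] = field(default_factory=tuple)
    reference_period: float = NUCLEOSOME_PERIOD

    def __post_init__(self) -> None:
        distances = [p.distance for p in self.peaks]
        if distances != sorted(set(distances)):
            raise ValueError("peak distances must be strictly increasing")

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def assigned(self) -> tuple[Peak, ...]:
        return tuple(p for p in self.peaks if p.assigned)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write(f"# reference_period: {self.reference_period}\n")
            handle.write("distance\theight\tk\toffset\n")
            for p in self.peaks:
                k = "." if p.k is None else p.k
                offset = "." if p.offset is None else f"{p.offset:.3f}"
                handle.write(f"{p.distance}\t{p.height!r}\t{k}\t{offset}\n")


@dataclass(frozen=True)
class PeriodEstimate:
    """Period fitted through the origin: p_hat = sum(k*d_k) / sum(k^2)."""

    p_hat: float
    n_peaks_used: int
    residual_rms: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {
                    "p_hat": self.p_hat,
                    "n_peaks_used": self.n_peaks_used,
                    "residual_rms": self.residual_rms,
                },
                handle,
                indent=2,
            )
            handle.write("\n")


def _profile_values(profile) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, AutocorrProfile):
        return profile.distances, profile.smoothed
    if isinstance(profile, DistanceHistogram):
        if profile.stage != "smoothed":
            raise ValueError(
                f"peak calling expects a smoothed curve, got stage {profile.stage!r}"
            )
        return profile.distances, profile.counts
    raise TypeError(f"cannot call peaks on {type(profile).__name__}")


def local_maxima(profile, min_height: float = 1.0) -> PeakSet:
    """Strict local maxima of the smoothed curve, at least ``min_height`` high.

    A distance d is a peak iff value[d] > value[d-1] and value[d] > value[d+1];
    the domain edges are ineligible.  A plateau of tied values flanked by
    strictly lower neighbors is reported once, at its leftmost distance.

    The default ``min_height`` of 1.0 requires peaks to rise above the
    normalized average level.
    """
    distances, values = _profile_values(profile)
    n = len(values)
    peaks: list[Peak] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        is_peak = (
            i > 0
            and j < n - 1
            and values[i - 1] < values[i]
            and values[j + 1] < values[i]
            and values[i] >= min_height
        )
        if is_peak:
            peaks.append(Peak(distance=int(distances[i]), height=float(values[i])))
        i = j + 1
    return PeakSet(peaks=tuple(peaks))


def assign_period_multiples(
    peaks: PeakSet, period: float = NUCLEOSOME_PERIOD, tol: float = 1.5
) -> PeakSet:
    """Assign each peak to its nearest period multiple k = round(d / period).

    A peak is assigned iff k >= 1 and |d - k*period| <= tol; otherwise it is
    left unassigned.  The default tolerance of 1.5 bases admits the <=0.5
    rounding of lattice positions plus smoothing-induced +-1 shifts, while
    rejecting off-lattice harmonics (e.g. the ~8-base secondary spacing of
    Alu sequences).  Idempotent and independent of peak order.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    assigned = []
    for peak in peaks:
        k = int(np.floor(peak.distance / period + 0.5))
        offset = peak.distance - k * period
        if k >= 1 and abs(offset) <= tol:
            assigned.append(replace(peak, k=k, offset=offset))
        else:
            assigned.append(replace(peak, k=None, offset=None))
    return PeakSet(peaks=tuple(assigned), reference_period=period)


def estimate_period(peaks: PeakSet) -> PeriodEstimate:
    """Least-squares period through the origin from the assigned peaks.

    With peak distances d_k at multiples k, minimizes sum_k (d_k - p*k)^2,
    giving p_hat = sum(k*d_k) / sum(k^2).  Requires at least two assigned
    peaks.
    """
    used = peaks.assigned
    if len(used) < 2:
        raise ValueError(
            f"period estimation needs >= 2 assigned peaks, got {len(used)}"
        )
    k = np.array([p.k for p in used], dtype=float)
    d = np.array([p.distance for p in used], dtype=float)
    p_hat = float(np.sum(k * d) / np.sum(k * k))
    residual_rms = float(np.sqrt(np.mean((d - p_hat * k) ** 2)))
    return PeriodEstimate(p_hat=p_hat, n_peaks_used=len(used), residual_rms=residual_rms)


def top_peaks(peaks: PeakSet, n: int = 2, height_tol: float = 1e-9) -> list[Peak]:
    """The ``n`` highest peaks, tallest first.

    Heights within ``height_tol`` (relative) of each other are treated as
    tied and ordered by ascending distance, so that exact symmetries of
    noise-free inputs do not leave the ranking at the mercy of last-ulp
    rounding.
    """
    if not peaks.peaks:
        return []
    scale = max(abs(p.height) for p in peaks) or 1.0

    def key(p: Peak):
        return (-round(p.height / (scale * height_tol)), p.distance)

    return sorted(peaks, key=key)[:n]
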