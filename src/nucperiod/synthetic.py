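"""Synthetic genomes with planted periodicity and repeat clusters.

Generates sequences carrying exactly the statistical structure the analysis
modules look for, together with machine-readable truth:

* an i.i.d. background, optionally scrubbed of CG dinucleotides so that
  planted CpGs are the only signal;
* CG planted on a period-10.4 lattice — stride 1 emulates the weak
  genome-wide CpG periodicity of non-repetitive DNA, stride 3 the 31/32-base
  CpG spacing internal to Alu repeats;
* repeat units inserted as monomer/dimer/trimer runs with a fixed ~310-base
  intra-run start spacing and geometric inter-run spacers (default mean
  2300 bases, the tail-to-head scale of genomic Alu spacers), optionally
  lowercased to emulate soft masking.

All generation is a pure function of (spec, seed): rerunning a spec yields
byte-identical sequences.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .repeats import RepeatMatch
from .seqio import SequenceRecord

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "PlantedRepeat",
    "random_genome",
    "lattice_positions",
    "plant_dinucleotide",
    "make_unit",
    "insert_repeat_clusters",
    "make_periodic_genome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _G = ord("C"), ord("G")

# Run-size mix of the genomic Alu census (~1.02M monomers, 116k dimers,
# 18k trimers of ~1.15M runs), used as the default cluster composition.
_DEFAULT_PROPORTIONS = {1: 1_020_000 / 1_154_000, 2: 116_000 / 1_154_000, 3: 18_000 / 1_154_000}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic genome.

    ``period`` (bases) and ``stride`` define the CG planting lattice at
    positions round(period * stride * k); ``occupancy`` is the independent
    retention probability of each lattice site.  ``cluster_proportions``,
    ``intra_run_start_spacing`` (310 bases, the tandem Alu head-to-head
    spacing), ``unit_length`` (300 bases, one Alu) and ``mean_spacer``
    (2300 bases tail-to-head) drive repeat-cluster insertion.
    """

    length: int
    seed: int = 0
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    period: float = 10.4
    stride: int = 1
    occupancy: float = 1.0
    cg_free_background: bool = False
    cluster_proportions: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    intra_run_start_spacing: int = 310
    unit_length: int = 300
    mean_spacer: int = 2300
    min_spacer: int = 300

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-9:
            raise ValueError("base_frequencies must sum to 1")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")
        if self.period <= 2:
            raise ValueError("period must exceed 2 (planted dinucleotides must not overlap)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        total = sum(self.cluster_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")


@dataclass(frozen=True)
class PlantedRepeat:
    """Truth annotation for one inserted repeat copy."""

    match: RepeatMatch
    run_id: int
    run_size: int


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a synthetic genome: planted lattice positions and/or
    inserted repeat copies, plus the generating spec."""

    record_id: str
    spec: SyntheticSpec
    planted_positions: tuple[int, ...] = ()
    repeat_annotations: tuple[PlantedRepeat, ...] = ()

    @property
    def repeat_matches(self) -> list[RepeatMatch]:
        return [a.match for a in self.repeat_annotations]

    @property
    def runs_by_size(self) -> dict[int, int]:
        seen: dict[int, int] = {}
        sizes: dict[int, int] = {}
        for a in self.repeat_annotations:
            seen[a.run_id] = a.run_size
        for size in seen.values():
            sizes[size] = sizes.get(size, 0) + 1
        return sizes

    def to_json(self, path: str | Path) -> None:
        payload = {
            "record_id": self.record_id,
            "spec": asdict(self.spec),
            "planted_positions": list(self.planted_positions),
            "repeat_annotations": [
                {
                    "chrom": a.match.chrom,
                    "start": a.match.start,
                    "end": a.match.end,
                    "strand": a.match.strand,
                    "run_id": a.run_id,
                    "run_size": a.run_size,
                }
                for a in self.repeat_annotations
            ],
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)
            handle.write("\n")

    def repeats_to_bed(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for a in self.repeat_annotations:
                handle.write(
                    f"{a.match.chrom}\t{a.match.start}\t{a.match.end}"
                    f"\trun{a.run_id}_size{a.run_size}\t0\t{a.match.strand}\n"
                )


def _scrub_cg(arr: np.ndarray, rng: np.random.Generator, freqs: Sequence[float]) -> None:
    """Resample the G of every CG in place until none remain.

    Replacement bases are drawn from the non-G frequencies; a replacement C
    can create a new CG with the following base, hence the loop (it
    terminates quickly: each pass removes a constant fraction).
    """
    non_g = np.frombuffer(b"ACT", dtype=np.uint8)
    p = np.array([freqs[0], freqs[1], freqs[3]], dtype=float)
    p /= p.sum()
    while True:
        hits = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
        if hits.size == 0:
            return
        arr[hits + 1] = non_g[rng.choice(3, size=hits.size, p=p)]


def random_genome(spec: SyntheticSpec, record_id: str | None = None) -> SequenceRecord:
    """I.i.d. background genome from the spec's seed and base frequencies.

    With ``cg_free_background`` every emergent C-followed-by-G has its G
    resampled, so the output contains zero CG dinucleotides and planted CpGs
    are later the only CpG signal.
    """
    rng = np.random.default_rng(spec.seed)
    arr = _BASES[rng.choice(4, size=spec.length, p=np.asarray(spec.base_frequencies))]
    if spec.cg_free_background and spec.length >= 2:
        _scrub_cg(arr, rng, spec.base_frequencies)
    return SequenceRecord(record_id or f"synthetic_seed{spec.seed}", arr.tobytes().decode("ascii"))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # positive lattice coordinates only
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def lattice_positions(period: float, stride: int, n: int, phase: int = 0) -> np.ndarray:
    """Positions phase + round(period * stride * k), k = 0..n-1.

    Rounding is half away from zero, reproducing the nearest-integer reading
    of period multiples (10.4, 20.8, 31.2 -> 10, 21, 31).
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    k = np.arange(max(0, n), dtype=float)
    return phase + _round_half_away(period * stride * k)


def plant_dinucleotide(
    record: SequenceRecord,
    dinuc: str,
    positions: Sequence[int] | np.ndarray,
    occupancy: float = 1.0,
    seed: int = 0,
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Overwrite ``dinuc`` at each retained lattice position.

    Each listed position is retained independently with probability
    ``occupancy``; retained positions are overwritten in place (sequence
    length, and hence all other coordinates, are preserved).  The returned
    truth lists exactly the retained positions.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size and (positions.min() < 0 or positions.max() > record.length - 2):
        raise ValueError("plant positions must fit within the sequence (p <= length - 2)")
    if positions.size > 1:
        if np.any(np.diff(positions) < 2):
            raise ValueError("plant positions overlap (start gaps must be >= 2)")
    rng = np.random.default_rng(seed)
    keep = rng.random(positions.size) < occupancy
    retained = positions[keep]
    arr = np.frombuffer(record.residues.encode("ascii"), dtype=np.uint8).copy()
    arr[retained] = ord(dinuc[0])
    arr[retained + 1] = ord(dinuc[1])
    planted = SequenceRecord(record.id, arr.tobytes().decode("ascii"))
    spec = SyntheticSpec(length=record.length, seed=seed, occupancy=occupancy)
    truth = SyntheticTruth(
        record_id=record.id, spec=spec, planted_positions=tuple(int(p) for p in retained)
    )
    return planted, truth


def make_unit(
    unit_length: int = 300,
    period: float = 10.4,
    cg_stride: int = 3,
    seed: int = 0,
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> str:
    """A CG-free random repeat unit with CG planted on an internal lattice.

    With the defaults (300 bases, stride 3) the unit carries CGs starting at
    0, 31, 62, 94, ... — consecutive gaps of 31 or 32 bases, the Alu-internal
    CpG spacing at three helical turns.  The unit contains no CG other than
    the planted ones.
    """
    spec = SyntheticSpec(
        length=unit_length,
        seed=seed,
        base_frequencies=base_frequencies,
        cg_free_background=True,
    )
    background = random_genome(spec, record_id="unit")
    n = int(unit_length // (period * cg_stride)) + 1
    positions = lattice_positions(period, cg_stride, n)
    positions = positions[positions <= unit_length - 2]
    planted, _ = plant_dinucleotide(background, "CG", positions, occupancy=1.0, seed=seed)
    return planted.residues


def _draw_spacer(rng: np.random.Generator, spec: SyntheticSpec) -> int:
    return int(max(spec.min_spacer, rng.geometric(1.0 / spec.mean_spacer)))


def insert_repeat_clusters(
    record: SequenceRecord,
    unit: str,
    spec: SyntheticSpec,
    n_runs: int,
    seed: int | None = None,
    soft_mask: bool = True,
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Insert ``n_runs`` repeat runs (monomers/dimers/trimers) into a genome.

    Run sizes are drawn from ``spec.cluster_proportions``; within a run,
    copies start ``spec.intra_run_start_spacing`` apart; runs are separated
    by tail-to-head spacers drawn geometric with mean ``spec.mean_spacer``,
    left-truncated at ``spec.min_spacer`` (default one unit length) so that
    distinct runs never crowd into the intra-run spacing scale and the
    planted census stays unambiguous.  Copies replace background in place,
    so genome length and truth coordinates are stable; with ``soft_mask``
    the copies are lowercased, emulating a repeat-masked genome build.
    """
    if n_runs < 0:
        raise ValueError("n_runs must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sizes_avail = sorted(spec.cluster_proportions)
    probs = np.array([spec.cluster_proportions[s] for s in sizes_avail], dtype=float)
    probs /= probs.sum()
    sizes = rng.choice(sizes_avail, size=n_runs, p=probs)

    unit_bytes = np.frombuffer(
        (unit.lower() if soft_mask else unit).encode("ascii"), dtype=np.uint8
    )
    unit_len = len(unit)
    spacing = spec.intra_run_start_spacing
    if spacing < unit_len:
        raise ValueError("intra_run_start_spacing must be >= unit length (no overlap)")

    arr = np.frombuffer(record.residues.encode("ascii"), dtype=np.uint8).copy()
    annotations: list[PlantedRepeat] = []
    pos = _draw_spacer(rng, spec)
    for run_id, size in enumerate(sizes):
        size = int(size)
        run_end = pos + (size - 1) * spacing + unit_len
        if run_end > record.length:
            raise ValueError(
                f"genome too short for requested content: run {run_id} would end at "
                f"{run_end} > {record.length}"
            )
        for c in range(size):
            start = pos + c * spacing
            arr[start : start + unit_len] = unit_bytes
            annotations.append(
                PlantedRepeat(
                    match=RepeatMatch(record.id, start, start + unit_len, "+"),
                    run_id=run_id,
                    run_size=size,
                )
            )
        pos = run_end + _draw_spacer(rng, spec)

    genome = SequenceRecord(record.id, arr.tobytes().decode("ascii"))
    truth = SyntheticTruth(
        record_id=record.id, spec=spec, repeat_annotations=tuple(annotations)
    )
    return genome, truth


def make_periodic_genome(
    spec: SyntheticSpec, dinuc: str = "CG", record_id: str | None = None, phase: int = 0
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Background genome with ``dinuc`` planted on the spec's full lattice.

    Composes :func:`random_genome`, :func:`lattice_positions` spanning the
    whole sequence, and :func:`plant_dinucleotide` at the spec's occupancy.
    Deterministic given the spec (planting uses a seed derived from it).
    """
    record = random_genome(spec, record_id=record_id)
    step = spec.period * spec.stride
    n = int((max(0, spec.length - 2) - phase) // step) + 1 if spec.length >= 2 else 0
    positions = lattice_positions(spec.period, spec.stride, n, phase=phase)
    positions = positions[(positions >= 0) & (positions <= spec.length - 2)]
    planted, plant_truth = plant_dinucleotide(
        record, dinuc, positions, occupancy=spec.occupancy, seed=spec.seed + 1
    )
    truth = SyntheticTruth(
        record_id=planted.id,
        spec=spec,
        planted_positions=plant_truth.planted_positions,
    )
    return planted, truth
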