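"""Synthetic-genome generation: determinism, planting, cluster insertion."""

import numpy as np
import pytest

from nucperiod import (
    SequenceRecord,
    SyntheticSpec,
    cluster_runs,
    dinucleotide_positions,
    distance_histogram,
    distance_spectrum,
    insert_repeat_clusters,
    lattice_positions,
    make_periodic_genome,
    make_unit,
    plant_dinucleotide,
    random_genome,
)


class TestRandomGenome:
    def test_zero_length_gives_empty_record(self):
        assert random_genome(SyntheticSpec(length=0)).length == 0

    def test_generation_is_deterministic(self):
        spec = SyntheticSpec(length=5000, seed=42, cg_free_background=True)
        assert random_genome(spec).residues == random_genome(spec).residues

    def test_cg_free_background_has_no_cg(self):
        record = random_genome(SyntheticSpec(length=200_000, seed=7, cg_free_background=True))
        assert dinucleotide_positions(record.residues, "CG").size == 0

    def test_uniform_base_frequencies_at_scale(self):
        record = random_genome(SyntheticSpec(length=1_000_000, seed=11))
        for base in "ACGT":
            assert record.residues.count(base) / 1e6 == pytest.approx(0.25, abs=0.002)

    def test_skewed_frequencies_respected(self):
        spec = SyntheticSpec(length=500_000, seed=13, base_frequencies=(0.4, 0.1, 0.1, 0.4))
        record = random_genome(spec)
        assert record.residues.count("A") / 5e5 == pytest.approx(0.4, abs=0.005)
        assert record.residues.count("C") / 5e5 == pytest.approx(0.1, abs=0.005)


class TestLatticePositions:
    def test_stride_one_matches_nearest_integer_multiples(self):
        assert lattice_positions(10.4, 1, 5).tolist() == [0, 10, 21, 31, 42]

    def test_stride_three_matches_alu_spacing(self):
        assert lattice_positions(10.4, 3, 4).tolist() == [0, 31, 62, 94]

    def test_consecutive_gaps_bracket_the_real_period(self):
        positions = lattice_positions(7.3, 2, 200, phase=5)
        gaps = set(np.diff(positions).tolist())
        assert gaps <= {14, 15}  # floor and ceil of 14.6


class TestPlantDinucleotide:
    def test_full_occupancy_plants_every_position(self):
        record = random_genome(SyntheticSpec(length=10_000, seed=3, cg_free_background=True))
        positions = lattice_positions(10.4, 1, 900)
        planted, truth = plant_dinucleotide(record, "CG", positions, occupancy=1.0, seed=5)
        assert truth.planted_positions == tuple(positions.tolist())
        found = set(dinucleotide_positions(planted.residues, "CG").tolist())
        assert set(positions.tolist()) <= found

    def test_partial_occupancy_is_binomial(self):
        record = random_genome(SyntheticSpec(length=50_000, seed=3))
        positions = np.arange(0, 10_000, 10)  # 1000 sites
        _, truth = plant_dinucleotide(record, "CG", positions, occupancy=0.5, seed=6)
        assert 450 <= len(truth.planted_positions) <= 550  # 500 +- ~3 sigma

    def test_replanting_identical_spec_is_byte_identical(self):
        record = random_genome(SyntheticSpec(length=5_000, seed=3))
        positions = np.arange(0, 4000, 13)
        a, _ = plant_dinucleotide(record, "CG", positions, occupancy=0.7, seed=9)
        b, _ = plant_dinucleotide(record, "CG", positions, occupancy=0.7, seed=9)
        assert a.residues == b.residues

    def test_overlapping_positions_rejected(self):
        record = random_genome(SyntheticSpec(length=100, seed=1))
        with pytest.raises(ValueError, match="overlap"):
            plant_dinucleotide(record, "CG", [10, 11])

    def test_positions_must_fit(self):
        record = random_genome(SyntheticSpec(length=100, seed=1))
        with pytest.raises(ValueError, match="fit"):
            plant_dinucleotide(record, "CG", [99])


class TestMakeUnit:
    def test_default_unit_carries_alu_style_cg_lattice(self):
        unit = make_unit(300, 10.4, 3, seed=1)
        positions = dinucleotide_positions(unit, "CG").tolist()
        assert positions == [0, 31, 62, 94, 125, 156, 187, 218, 250, 281]

    def test_consecutive_cg_gaps_are_31_or_32(self):
        unit = make_unit(300, 10.4, 3, seed=2)
        gaps = set(np.diff(dinucleotide_positions(unit, "CG")).tolist())
        assert gaps <= {31, 32}

    def test_no_cg_other_than_planted(self):
        # forced by construction: planting is the only CG source
        unit = make_unit(250, 10.4, 3, seed=3)
        expected = lattice_positions(10.4, 3, 250 // 31 + 1)
        expected = expected[expected <= 248]
        assert dinucleotide_positions(unit, "CG").tolist() == expected.tolist()


class TestInsertRepeatClusters:
    def make_background(self, length, seed=21):
        return random_genome(SyntheticSpec(length=length, seed=seed))

    def test_all_monomers(self):
        spec = SyntheticSpec(length=300_000, seed=4, cluster_proportions={1: 1.0})
        genome, truth = insert_repeat_clusters(
            self.make_background(300_000), make_unit(seed=4), spec, n_runs=10
        )
        assert truth.runs_by_size == {1: 10}
        assert len(truth.repeat_annotations) == 10

    def test_dimer_spacing_gives_single_spectrum_mode(self):
        spec = SyntheticSpec(length=400_000, seed=5, cluster_proportions={2: 1.0})
        genome, truth = insert_repeat_clusters(
            self.make_background(400_000), make_unit(seed=5), spec, n_runs=50
        )
        gaps = [
            b.match.start - a.match.start
            for a, b in zip(truth.repeat_annotations, truth.repeat_annotations[1:])
            if a.run_id == b.run_id
        ]
        assert gaps == [310] * 50
        spectrum = distance_spectrum(truth.repeat_matches, max_distance=1000, bin_width=10)
        # within-run pairs all land in the 310 bin; everything else is
        # inter-run distance, far beyond 1000 with overwhelming probability
        assert spectrum.counts[spectrum.bin_of(310)] == 50

    def test_mixed_proportions_recovered_by_cluster_runs(self):
        spec = SyntheticSpec(length=1_200_000, seed=6, mean_spacer=1500)
        genome, truth = insert_repeat_clusters(
            self.make_background(1_200_000), make_unit(seed=6), spec, n_runs=300
        )
        summary = cluster_runs(truth.repeat_matches, gap_threshold=500)
        assert summary.runs_by_size == truth.runs_by_size
        assert summary.n_total_matches == len(truth.repeat_annotations)

    def test_soft_masked_copies_are_removed_by_masked_profile(self):
        spec = SyntheticSpec(length=200_000, seed=8, cluster_proportions={2: 1.0})
        background = random_genome(
            SyntheticSpec(length=200_000, seed=8, cg_free_background=True)
        )
        genome, truth = insert_repeat_clusters(
            background, make_unit(seed=8), spec, n_runs=20, soft_mask=True
        )
        unmasked = distance_histogram(genome, "CG", window=80, mask_mode="none")
        masked = distance_histogram(genome, "CG", window=80, mask_mode="masked")
        assert unmasked.counts.sum() > 0  # Alu-internal CG pairs visible
        assert masked.counts.sum() == 0  # all CG lives in soft-masked copies
        assert np.all(masked.counts <= unmasked.counts)

    def test_genome_too_short_is_an_error(self):
        spec = SyntheticSpec(length=2_000, seed=9)
        with pytest.raises(ValueError, match="too short"):
            insert_repeat_clusters(self.make_background(2_000), make_unit(seed=9), spec, n_runs=50)


class TestMakePeriodicGenome:
    def test_histogram_equals_closed_form_pair_multiset(self):
        """With a CG-free background, the raw CG histogram must equal the
        pair-distance multiset of the planted positions under the anchor
        rule — a closed-form oracle requiring no sequence scan."""
        spec = SyntheticSpec(
            length=50_000, seed=12, stride=1, occupancy=0.7, cg_free_background=True
        )
        record, truth = make_periodic_genome(spec)
        window = 80
        hist = distance_histogram(record, "CG", window=window)
        planted = set(truth.planted_positions)
        limit = spec.length - window - 2
        expected = {d: 0 for d in range(2, window + 1)}
        for p in truth.planted_positions:
            if p > limit:
                continue
            for d in range(2, window + 1):
                if p + d in planted:
                    expected[d] += 1
        assert hist.as_dict() == expected

    def test_determinism_across_calls(self):
        spec = SyntheticSpec(length=30_000, seed=15, stride=3, cg_free_background=True)
        a, ta = make_periodic_genome(spec)
        b, tb = make_periodic_genome(spec)
        assert a.residues == b.residues
        assert ta.planted_positions == tb.planted_positions
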