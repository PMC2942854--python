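import numpy as np
import pytest

from ilsom import analysis
from ilsom.analysis import (
    COMPOSITION_MIXED,
    COMPOSITION_TRANSCRIPTS,
    GRAY,
    GREEN,
    WHITE,
    all_cohesions,
    chromosome_subset,
    classify_composition,
    cohesion,
    global_compactness,
    neuron_report,
    pseudo_zero_neurons,
    search,
    symmetry_report,
    three_color_map,
    units_within,
)
from ilsom.datatypes import (
    KIND_METABOLITE,
    KIND_TRANSCRIPT,
    SIGN_INVERTED,
    SIGN_ORIGINAL,
)
from ilsom.som import Assignment, SomConfig, SomMap

from conftest import make_dataset


def _fixed_assignment(bmus):
    bmu = np.asarray(bmus)
    return Assignment(bmu=bmu, distance=np.zeros(len(bmu)))


class TestSearch:
    def test_finds_both_signs_of_an_entity(self, trained):
        dataset, _, _, assignment = trained
        name = dataset.patterns[0].entity_id
        hits = search(name, assignment, dataset)
        assert {sign for _, sign in hits} == {SIGN_ORIGINAL, SIGN_INVERTED}
        assert hits[0][0] == int(assignment.bmu[0])

    def test_unknown_name_returns_empty(self, trained):
        dataset, _, _, assignment = trained
        assert search("nosuchthing", assignment, dataset) == []

    def test_case_insensitive_substring_fallback(self):
        ds = make_dataset(
            [[0.6, 0.8]], kinds=[KIND_METABOLITE],
            entity_ids=["L-aspartic acid"],
        )
        assignment = _fixed_assignment([3, 5])
        hits = search("aspartic", assignment, ds)
        assert hits == [(3, SIGN_ORIGINAL), (5, SIGN_INVERTED)]


class TestComposition:
    def _setup(self):
        # two transcripts in unit 1; one metabolite in unit 2 (adjacent)
        ds = make_dataset(
            [[1.0, 0.0], [0.9, 0.1], [0.0, 1.0]],
            kinds=[KIND_TRANSCRIPT, KIND_TRANSCRIPT, KIND_METABOLITE],
            augment=False,
        )
        som = SomMap(SomConfig(rows=2, cols=2), np.zeros((4, 2)))
        assignment = _fixed_assignment([1, 1, 2])
        return ds, som, assignment

    def test_vn0_counts_only_the_unit_itself(self):
        ds, som, assignment = self._setup()
        assert classify_composition(1, assignment, ds, som, vn=0) == (
            COMPOSITION_TRANSCRIPTS
        )

    def test_vn1_pools_the_adjacent_metabolite(self):
        ds, som, assignment = self._setup()
        assert classify_composition(1, assignment, ds, som, vn=1) == (
            COMPOSITION_MIXED
        )

    def test_vn_beyond_map_diameter_gives_global_composition(self):
        ds, som, assignment = self._setup()
        for unit in (1, 2, 3, 4):
            assert classify_composition(unit, assignment, ds, som, vn=99) == (
                COMPOSITION_MIXED
            )

    def test_pooling_is_monotone_mixed_stays_mixed(self, trained):
        dataset, _, som, assignment = trained
        for unit in assignment.nonempty_units():
            prev = classify_composition(int(unit), assignment, dataset, som, 0)
            for vn in (1, 2):
                cur = classify_composition(int(unit), assignment, dataset, som, vn)
                if prev == COMPOSITION_MIXED:
                    assert cur == COMPOSITION_MIXED
                prev = cur

    def test_chebyshev_neighborhood_on_the_grid(self):
        som = SomMap(SomConfig(rows=4, cols=4), np.zeros((16, 2)))
        center = som.unit_at(2, 2)
        ring = units_within(som, center, 1)
        assert len(ring) == 9
        assert som.unit_at(1, 1) in ring and som.unit_at(3, 3) in ring


class TestCohesion:
    def test_hand_example(self):
        ds = make_dataset([[0.0, 0.0], [2.0, 0.0]], augment=False)
        codebook = np.array([[1.0, 0.0], [9.0, 9.0]])
        som = SomMap(SomConfig(rows=2, cols=1), codebook)
        assignment = _fixed_assignment([1, 1])
        assert cohesion(1, assignment, ds, som) == pytest.approx(1.0)

    def test_members_equal_to_codebook_have_zero_cohesion(self):
        ds = make_dataset([[0.5, -0.5]], augment=False)
        som = SomMap(SomConfig(rows=2, cols=1), np.array([[0.5, -0.5], [0, 0]]))
        assert cohesion(1, _fixed_assignment([1]), ds, som) == 0.0

    def test_empty_unit_is_undefined_not_zero(self):
        ds = make_dataset([[1.0, 1.0]], augment=False)
        som = SomMap(SomConfig(rows=2, cols=1), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="empty"):
            cohesion(2, _fixed_assignment([1]), ds, som)

    def test_matches_brute_force_on_random_assignments(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n, p, k = rng.integers(2, 15), rng.integers(2, 8), rng.integers(2, 6)
            values = rng.normal(size=(int(n), int(p)))
            ds = make_dataset(values, augment=False)
            codebook = rng.normal(size=(int(k), int(p)))
            som = SomMap(SomConfig(rows=int(k), cols=1), codebook)
            bmus = rng.integers(1, int(k) + 1, size=int(n))
            assignment = _fixed_assignment(bmus)
            for unit in np.unique(bmus):
                members = values[bmus == unit]
                expected = float(
                    np.mean(
                        [np.sum((x - codebook[unit - 1]) ** 2) for x in members]
                    )
                )
                got = cohesion(int(unit), assignment, ds, som)
                assert got == pytest.approx(expected, rel=1e-12)

    def test_masked_cohesion_rescales_to_full_dimension(self):
        # member missing one of two components: squared distance on the
        # valid half is scaled by P / n_valid = 2
        ds = make_dataset([[3.0, np.nan]], augment=False)
        som = SomMap(SomConfig(rows=2, cols=1), np.array([[1.0, 5.0], [0, 0]]))
        got = cohesion(1, _fixed_assignment([1]), ds, som)
        assert got == pytest.approx((3.0 - 1.0) ** 2 * 2.0)

    def test_global_compactness_is_the_mean(self):
        assert global_compactness({3: 1.0, 7: 3.0}) == 2.0
        assert global_compactness({12: 1.0, 2: 3.0}) == 2.0  # label-invariant

    def test_all_cohesions_covers_exactly_nonempty_units(self, trained):
        dataset, _, som, assignment = trained
        cohesions = all_cohesions(assignment, dataset, som)
        assert set(cohesions) == {int(u) for u in assignment.nonempty_units()}
        assert all(c >= 0 for c in cohesions.values())


class TestThreeColor:
    def _one_unit(self, member_values):
        values = np.asarray(member_values, dtype=float)
        ds = make_dataset(values, augment=False)
        som = SomMap(SomConfig(rows=2, cols=1), np.zeros((2, values.shape[1])))
        assignment = _fixed_assignment([1] * len(values))
        return three_color_map(assignment, ds, som)

    def test_outlier_above_mean_plus_sd_is_green(self):
        tcm = self._one_unit([[0.0], [0.0], [10.0]])
        assert tcm.color(0, 1) == GREEN

    def test_outlier_below_mean_minus_sd_is_gray(self):
        # {0, 0, -10}: min is below mean - sd and nothing exceeds mean + sd
        tcm = self._one_unit([[0.0], [0.0], [-10.0]])
        assert tcm.color(0, 1) == GRAY

    def test_identical_members_are_white(self):
        tcm = self._one_unit([[2.0], [2.0], [2.0]])
        assert tcm.color(0, 1) == WHITE

    def test_single_member_unit_is_white(self):
        tcm = self._one_unit([[5.0]])
        assert tcm.color(0, 1) == WHITE

    def test_empty_units_are_white(self):
        tcm = self._one_unit([[0.0], [0.0], [10.0]])
        assert tcm.color(0, 2) == WHITE

    def test_domain_is_green_gray_white(self, trained):
        dataset, _, som, assignment = trained
        tcm = three_color_map(assignment, dataset, som)
        assert set(np.unique(tcm.colors)) <= {GREEN, GRAY, WHITE}

    def test_scale_equivariance_per_genotype(self, trained):
        dataset, _, som, assignment = trained
        tcm = three_color_map(assignment, dataset, som)
        scaled = make_dataset(
            dataset.matrix() * np.array([3.0] + [1.0] * (dataset.n_genotypes - 1)),
            kinds=[p.kind for p in dataset.patterns],
            entity_ids=[p.label for p in dataset.patterns],
            genotypes=dataset.genotypes,
            augment=False,
        )
        tcm_scaled = three_color_map(assignment, scaled, som)
        assert np.array_equal(tcm.colors, tcm_scaled.colors)


class TestPseudoZeros:
    def test_fully_valid_dataset_has_none(self):
        ds = make_dataset([[1.0, 2.0]], augment=False)
        assert pseudo_zero_neurons(_fixed_assignment([1]), ds) == {}

    def test_partially_missing_metabolite_is_flagged_with_genotype(self):
        ds = make_dataset(
            [[1.0, np.nan, 2.0]],
            kinds=[KIND_METABOLITE],
            genotypes=["12-1", "12-2", "12-3"],
            entity_ids=["met_x"],
            augment=False,
        )
        found = pseudo_zero_neurons(_fixed_assignment([4]), ds)
        assert found == {4: [("met_x", SIGN_ORIGINAL, ["12-2"])]}


class TestChromosomeSubset:
    PANEL = [
        "1-1", "1-2", "1-3", "2-1", "2-2", "3-1", "3-2", "5-1", "5-2",
        "5-3", "8-1", "8-2", "10-1", "10-2", "11-1", "11-2", "11-3",
        "12-1-1", "12-1", "12-2", "12-3",
    ]

    def _panel_dataset(self):
        rng = np.random.default_rng(2)
        return make_dataset(
            rng.normal(size=(3, 21)), genotypes=self.PANEL, augment=False
        )

    def test_chromosome_12_has_its_four_ils(self):
        sub = chromosome_subset(self._panel_dataset(), "12")
        assert sub.genotypes == ["12-1-1", "12-1", "12-2", "12-3"]
        assert sub.n_patterns == 3

    def test_union_over_chromosomes_recovers_the_panel(self):
        ds = self._panel_dataset()
        total = sum(
            chromosome_subset(ds, c).n_genotypes for c in ds.chromosomes()
        )
        assert total == 21
        assert ds.chromosomes() == ["1", "2", "3", "5", "8", "10", "11", "12"]

    def test_single_il_chromosome(self):
        ds = make_dataset([[1.0, 2.0]], genotypes=["4-1", "7-1"], augment=False)
        assert chromosome_subset(ds, "4").genotypes == ["4-1"]

    def test_unknown_chromosome_lists_available(self):
        with pytest.raises(KeyError, match="12"):
            chromosome_subset(self._panel_dataset(), "99")


class TestSymmetry:
    def test_trained_map_is_mirror_symmetric(self, trained):
        dataset, _, som, assignment = trained
        report = symmetry_report(assignment, dataset, som)
        assert report.fraction >= 0.95
        perfect = sum(1 for d in report.displacements.values() if d == (0, 0))
        assert perfect / len(report.displacements) == report.fraction

    def test_requires_inversion_closed_data(self):
        ds = make_dataset([[1.0, 2.0]], augment=False)
        som = SomMap(SomConfig(rows=2, cols=1), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="inversion-closed"):
            symmetry_report(_fixed_assignment([1]), ds, som)

    def test_invariant_under_global_negation(self, trained):
        from dataclasses import replace

        from ilsom.datatypes import ProfileDataset
        from ilsom.som import assign

        dataset, _, som, assignment = trained
        negated = ProfileDataset(
            genotypes=list(dataset.genotypes),
            patterns=[
                replace(p, values=-p.values, raw_values=None)
                for p in dataset.patterns
            ],
        )
        report = symmetry_report(assign(negated, som), negated, som)
        assert report.fraction == pytest.approx(
            symmetry_report(assignment, dataset, som).fraction
        )

    def test_random_codebook_is_near_chance(self):
        rng = np.random.default_rng(33)
        ds = make_dataset(rng.normal(size=(40, 6)))
        som = SomMap(SomConfig(rows=5, cols=5), rng.normal(size=(25, 6)))
        from ilsom.som import assign

        report = symmetry_report(assign(ds, som), ds, som)
        assert report.fraction < 0.3


class TestNeuronReport:
    def test_report_counts_and_cohesion(self, trained):
        dataset, _, som, assignment = trained
        unit = int(assignment.nonempty_units()[0])
        rep = neuron_report(unit, assignment, dataset, som)
        members = assignment.members_of(unit)
        assert sorted(rep.members) == sorted(int(i) for i in members)
        assert rep.n_transcripts + rep.n_metabolites == len(members)
        assert rep.cohesion == pytest.approx(
            cohesion(unit, assignment, dataset, som)
        )
        assert (rep.composition == COMPOSITION_MIXED) == (
            rep.n_transcripts > 0 and rep.n_metabolites > 0
        )
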