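"""Polymer sequences, full-factorial design generation and featurization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palkit import (
    FEATURE_NAMES,
    MONOMER_TYPES,
    Composition,
    PolymerSequence,
    backtrace_sequence,
    cluster_statistics,
    featurize,
    full_factorial_design,
    invertible_components,
    random_sequence,
    relative_sequence_entropy,
    standardize_features,
)
from palkit.features import apply_standardization, invert_standardization

seq = PolymerSequence.from_string

compositions = st.builds(
    Composition,
    st.tuples(*[st.integers(0, 6)] * 4).filter(lambda c: sum(c) >= 1),
)


class TestSequences:
    def test_bracket_round_trip(self):
        s = seq("[W][R][Ta][Tr]")
        assert s.id == "[W][R][Ta][Tr]"
        assert PolymerSequence.from_string(s.id) == s

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            seq("[W][X]")

    def test_composition_consistency(self):
        s = seq("[W][W][R][Ta]")
        assert s.composition.as_dict() == {"W": 2, "R": 1, "Ta": 1, "Tr": 0}
        assert len(s) == s.composition.total == 4

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            Composition((0, 0, 0, 0))


class TestRandomSequence:
    def test_homopolymer_unique_arrangement(self):
        s = random_sequence(Composition((2, 0, 0, 0)), seed=0)
        assert s.id == "[W][W]"

    def test_outputs_are_permutations(self):
        comp = Composition((1, 1, 0, 0))
        for s in (random_sequence(comp, 1), random_sequence(comp, 2)):
            assert sorted(s.beads) == ["R", "W"]

    def test_counts_preserved(self):
        comp = Composition((4, 4, 4, 4))
        s = random_sequence(comp, seed=5)
        assert len(s) == 16
        assert s.composition == comp

    def test_deterministic(self):
        comp = Composition((3, 2, 1, 0))
        assert random_sequence(comp, 9) == random_sequence(comp, 9)


class TestFullFactorial:
    def test_paper_scale_cardinality_small(self, small_design):
        # 2 levels ^ 2 factors x 3 arrangements
        assert len(small_design) == 2**2 * 3

    def test_single_level_single_sequence(self):
        ds = full_factorial_design([4], n_factors=4, sequences_per_point=1, seed=0)
        assert len(ds) == 1
        assert len(ds.sequences[0]) == 16

    def test_cardinality_formula(self):
        ds = full_factorial_design([4, 6, 8], n_factors=2, sequences_per_point=2, seed=1)
        assert len(ds) == 3**2 * 2

    def test_ids_unique_and_deterministic(self):
        a = full_factorial_design([4, 6], 2, 3, seed=3)
        b = full_factorial_design([4, 6], 2, 3, seed=3)
        assert a.ids == b.ids
        assert len(set(a.ids)) == len(a.ids)

    def test_duplicate_collision_reported(self):
        # a homopolymer composition has one arrangement; asking for two
        # distinct sequences must fail naming the composition
        with pytest.raises(RuntimeError, match="composition"):
            full_factorial_design([4], n_factors=1, sequences_per_point=2, seed=0)

    def test_feature_rows_align_with_sequences(self, small_design):
        i = 5
        np.testing.assert_allclose(
            small_design.features[i], featurize(small_design.sequences[i])
        )


class TestEntropy:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("[W][W][W][W]", 0.0),
            ("[W][R][Ta][Tr]", 1.0),
            ("[W][W][R][R][R][R]", (-(1 / 3) * math.log(1 / 3) - (2 / 3) * math.log(2 / 3)) / math.log(4)),
        ],
    )
    def test_examples(self, text, expected):
        assert relative_sequence_entropy(seq(text)) == pytest.approx(expected)

    @settings(deadline=None, max_examples=100)
    @given(compositions, st.integers(0, 2**31 - 1))
    def test_bounds_and_extremes(self, comp, s):
        poly = random_sequence(comp, s)
        h = relative_sequence_entropy(poly)
        assert 0.0 <= h <= 1.0
        n_types = sum(1 for c in comp.counts if c > 0)
        if n_types == 1:
            assert h == 0.0
        counts = [c for c in comp.counts if c > 0]
        if n_types == 4 and len(set(counts)) == 1:
            assert h == pytest.approx(1.0)


class TestClusterStatistics:
    def test_single_run(self):
        stats = cluster_statistics(seq("[W][W][W]"))
        assert stats["n_runs_total"] == 1
        assert stats["max_run_total"] == 3

    def test_alternating(self):
        stats = cluster_statistics(seq("[W][R][W][R]"))
        assert stats["n_runs_total"] == 4
        assert stats["max_run_total"] == 1

    def test_mixed_runs(self):
        stats = cluster_statistics(seq("[W][W][R][R][R][Ta]"))
        assert stats["n_runs_total"] == 3
        assert stats["n_runs_W"] == 1 and stats["max_run_W"] == 2
        assert stats["n_runs_R"] == 1 and stats["max_run_R"] == 3
        assert stats["n_runs_Tr"] == 0 and stats["mean_run_Tr"] == 0.0


class TestFeaturize:
    def test_homopolymer(self):
        v = dict(zip(FEATURE_NAMES, featurize(seq("[W]" * 8), {"W": 1, "R": 0, "Ta": 0, "Tr": 0})))
        assert v["degree_of_polymerization"] == 8
        assert v["sum_interaction"] == 8
        assert v["rel_entropy"] == 0.0

    def test_end_groups_one_hot(self):
        v = dict(zip(FEATURE_NAMES, featurize(seq("[R][W][Ta]"))))
        assert v["head_R"] == 1.0 and v["tail_Ta"] == 1.0
        assert v["head_W"] == v["head_Ta"] == v["head_Tr"] == 0.0

    def test_summed_interaction(self):
        v = dict(zip(FEATURE_NAMES, featurize(seq("[W][R]"), {"W": 0.5, "R": 1.5, "Ta": 0, "Tr": 0})))
        assert v["sum_interaction"] == pytest.approx(2.0)

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="interaction"):
            featurize(seq("[W]"), {"W": 1.0})

    def test_pure_function(self):
        s = seq("[W][R][R][Ta]")
        np.testing.assert_array_equal(featurize(s), featurize(s))

    @settings(deadline=None, max_examples=60)
    @given(compositions, st.integers(0, 2**31 - 1))
    def test_counts_sum_to_length(self, comp, s):
        poly = random_sequence(comp, s)
        v = dict(zip(FEATURE_NAMES, featurize(poly)))
        total = sum(v[f"count_{t}"] for t in MONOMER_TYPES)
        assert total == v["degree_of_polymerization"] == len(poly)


class TestStandardize:
    def test_population_sd_two_points(self):
        x = np.array([[1.0], [3.0]])
        xs, mean, sd = standardize_features(x, [0, 1])
        np.testing.assert_allclose(xs.ravel(), [-1.0, 1.0])
        assert mean[0] == 2.0 and sd[0] == 1.0

    def test_constant_column_maps_to_zero(self):
        x = np.array([[5.0, 1.0], [5.0, 2.0]])
        xs, _, _ = standardize_features(x, [0, 1])
        np.testing.assert_allclose(xs[:, 0], 0.0)

    def test_heldout_row_at_train_mean_is_zero(self):
        x = np.array([[0.0, 2.0], [4.0, 6.0], [2.0, 4.0]])
        xs, _, _ = standardize_features(x, [0, 1])
        np.testing.assert_allclose(xs[2], 0.0, atol=1e-12)

    def test_affine_inverse_recovers_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 4))
        xs, mean, sd = standardize_features(x, range(10))
        np.testing.assert_allclose(invert_standardization(xs, mean, sd), x, atol=1e-12)
        np.testing.assert_allclose(apply_standardization(x, mean, sd), xs)

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValueError):
            standardize_features(np.ones((3, 2)), [])


class TestBacktrace:
    def test_forced_homopolymer(self):
        vec = np.array([4, 0, 0, 0] + [1, 0, 0, 0] + [1, 0, 0, 0] + [1, 0, 0, 0], dtype=float)
        s = backtrace_sequence(vec, seed=0)
        assert s is not None and s.id == "[W][W][W][W]"

    def test_end_group_contradicting_counts_invalid(self):
        # head one-hot says R but there are no R beads
        vec = np.array([1, 0, 0, 0] + [0, 1, 0, 0] + [1, 0, 0, 0] + [1, 0, 0, 0], dtype=float)
        assert backtrace_sequence(vec, seed=0) is None

    def test_non_integer_counts_invalid(self):
        vec = invertible_components(seq("[W][R]")).astype(float)
        vec[0] = 1.5
        assert backtrace_sequence(vec, seed=0) is None

    def test_infeasible_run_counts_invalid(self):
        # 3 W runs but only 1 other run cannot alternate
        vec = np.array([6, 1, 0, 0] + [1, 0, 0, 0] + [1, 0, 0, 0] + [3, 1, 0, 0], dtype=float)
        assert backtrace_sequence(vec, seed=0) is None

    @settings(deadline=None, max_examples=60)
    @given(compositions, st.integers(0, 2**31 - 1))
    def test_round_trip_on_random_sequences(self, comp, s):
        poly = random_sequence(comp, s)
        vec = invertible_components(poly)
        decoded = backtrace_sequence(vec, max_tries=400, seed=11)
        assert decoded is not None
        np.testing.assert_array_equal(invertible_components(decoded), vec)
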