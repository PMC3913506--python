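"""Landscape data model: loading, statistics, optimal regions, round trips."""

import io

import numpy as np
import pytest

from edopt import CombinatorialLandscape, CompoundKey, load_landscape
from edopt.synthetic import random_landscape


def brute_force_region(landscape, alpha):
    """Independent recomputation: sort the raw values, threshold, collect."""
    y = np.array(sorted(landscape.responses.values()))
    threshold = np.quantile(y, 1.0 - alpha)
    return {k for k, v in landscape.responses.items() if v >= threshold}


class TestLoad:
    def test_tiny_grid_round_numbers(self):
        csv = "reagent_a,reagent_b,activity\nA1,B1,1\nA1,B2,2\nA2,B1,3\nA2,B2,4\n"
        ls = load_landscape(io.StringIO(csv), l_a=2, l_b=2)
        assert ls.n_cells == 4
        assert ls.describe().y_max == 4.0

    def test_duplicate_cell_is_an_error_naming_the_cell(self):
        csv = "reagent_a,reagent_b,activity\nA1,B1,1\nA1,B1,2\n"
        with pytest.raises(ValueError, match="duplicate cell.*A1.*B1"):
            load_landscape(io.StringIO(csv), l_a=2, l_b=2)

    def test_too_many_levels_rejected(self):
        csv = "reagent_a,reagent_b,activity\nA1,B1,1\nA2,B1,2\nA3,B1,3\n"
        with pytest.raises(ValueError, match="exceed declared"):
            load_landscape(io.StringIO(csv), l_a=2, l_b=2)

    def test_non_numeric_activity_rejected(self):
        csv = "reagent_a,reagent_b,activity\nA1,B1,high\n"
        with pytest.raises(ValueError, match="non-numeric"):
            load_landscape(io.StringIO(csv), l_a=1, l_b=1)

    def test_na_marks_missing(self):
        csv = "reagent_a,reagent_b,activity\nA1,B1,1.5\nA1,B2,NA\nA2,B1,\nA2,B2,4\n"
        ls = load_landscape(io.StringIO(csv), l_a=2, l_b=2)
        assert ls.n_available == 2
        assert ls.evaluate(CompoundKey(1, 2)) is None
        assert ls.is_missing(CompoundKey(2, 1))

    def test_label_mapping_is_lexicographic_and_retrievable(self):
        csv = "reagent_a,reagent_b,activity\nA2,B1,1\nA1,B2,2\nA1,B1,3\nA2,B2,4\n"
        ls = load_landscape(io.StringIO(csv), l_a=2, l_b=2)
        assert ls.a_labels == ["A1", "A2"]
        assert ls.evaluate(CompoundKey(2, 1)) == 1.0


class TestDescribe:
    def test_symmetric_set(self):
        ls = CombinatorialLandscape(
            1, 5, {CompoundKey(1, b): float(b) for b in range(1, 6)}
        )
        stats = ls.describe()
        assert stats.y_min == 1 and stats.y_max == 5
        assert stats.mean == 3 and stats.median == 3

    def test_against_brute_force_on_random_values(self, rng):
        values = rng.gamma(2.0, 2.0, size=1000)
        ls = CombinatorialLandscape(
            40, 25,
            {CompoundKey(i // 25 + 1, i % 25 + 1): v for i, v in enumerate(values)},
        )
        stats = ls.describe()
        assert stats.mean == pytest.approx(values.mean())
        assert stats.median == pytest.approx(np.quantile(values, 0.5))
        assert stats.q1 == pytest.approx(np.quantile(values, 0.25))
        assert stats.q3 == pytest.approx(np.quantile(values, 0.75))

    def test_all_missing_is_an_error(self):
        ls = CombinatorialLandscape(2, 2, {})
        with pytest.raises(ValueError, match="missing"):
            ls.describe()


class TestEvaluate:
    def test_lookup_and_missing(self, tiny_landscape):
        assert tiny_landscape.evaluate(CompoundKey(2, 3)) == 9.0
        sparse = CombinatorialLandscape(2, 2, {CompoundKey(1, 1): 8.0})
        assert sparse.evaluate(CompoundKey(1, 1)) == 8.0
        assert sparse.evaluate(CompoundKey(2, 2)) is None

    def test_out_of_range_is_an_error(self, tiny_landscape):
        with pytest.raises(ValueError, match="outside"):
            tiny_landscape.evaluate(CompoundKey(0, 1))
        with pytest.raises(ValueError, match="outside"):
            tiny_landscape.evaluate(CompoundKey(1, 4))

    def test_write_then_load_round_trip(self, tiny_landscape, tmp_path):
        path = tmp_path / "ls.csv"
        tiny_landscape.to_csv(path)
        back = load_landscape(path, l_a=3, l_b=3)
        for key in tiny_landscape.all_keys():
            assert back.evaluate(key) == tiny_landscape.evaluate(key)

    def test_round_trip_preserves_missing_cells(self, tmp_path):
        ls = CombinatorialLandscape(
            3, 3, {CompoundKey(a, b): float(a * b) for a in (1, 3) for b in (1, 2)}
        )
        path = tmp_path / "sparse.csv"
        ls.to_csv(path)
        back = load_landscape(path, l_a=3, l_b=3)
        for key in ls.all_keys():
            assert back.evaluate(key) == ls.evaluate(key)


class TestOptimalRegion:
    def test_hundred_cell_toy_against_brute_force(self):
        ls = CombinatorialLandscape(
            10, 10,
            {CompoundKey(i // 10 + 1, i % 10 + 1): float(i + 1) for i in range(100)},
        )
        region = ls.optimal_region(0.05)
        assert region == brute_force_region(ls, 0.05)
        assert {v for v in (ls.evaluate(k) for k in region)} == {96.0, 97.0, 98.0, 99.0, 100.0}

    def test_alpha_near_one_returns_everything(self, tiny_landscape):
        # generic landscape: everything except possibly the unique minimum
        region = tiny_landscape.optimal_region(1 - 1e-12)
        assert len(region) >= tiny_landscape.n_available - 1
        # tied minimum: the interpolated threshold equals y_min exactly, so
        # the limit region is the whole available space
        tied = CombinatorialLandscape(
            2, 2,
            {CompoundKey(1, 1): 1.0, CompoundKey(1, 2): 1.0,
             CompoundKey(2, 1): 2.0, CompoundKey(2, 2): 3.0},
        )
        assert tied.optimal_region(1 - 1e-12) == set(tied.responses)

    def test_degenerate_equal_responses_returns_all(self):
        ls = CombinatorialLandscape(2, 2, {k: 5.0 for k in
                                           (CompoundKey(1, 1), CompoundKey(1, 2),
                                            CompoundKey(2, 1), CompoundKey(2, 2))})
        assert ls.optimal_region(0.05) == set(ls.responses)

    def test_region_monotone_in_alpha(self, rng):
        for _ in range(5):
            ls = random_landscape(12, 9, seed=int(rng.integers(2**31)))
            alphas = [0.01, 0.05, 0.1, 0.5, 0.9]
            regions = [ls.optimal_region(a) for a in alphas]
            for small, big in zip(regions, regions[1:]):
                assert small <= big

    def test_matches_brute_force_on_random_landscapes(self, rng):
        for _ in range(10):
            ls = random_landscape(50, 50, seed=int(rng.integers(2**31)))
            for alpha in (0.01, 0.05):
                assert ls.optimal_region(alpha) == brute_force_region(ls, alpha)


class TestGlobalOptimum:
    def test_unique_max(self, tiny_landscape):
        keys, value = tiny_landscape.global_optimum()
        assert keys == {CompoundKey(2, 3)} and value == 9.0

    def test_tied_maxima_both_returned(self):
        ls = CombinatorialLandscape(
            2, 2,
            {CompoundKey(1, 1): 8.0, CompoundKey(1, 2): 3.4,
             CompoundKey(2, 1): 5.0, CompoundKey(2, 2): 8.0},
        )
        keys, value = ls.global_optimum()
        assert keys == {CompoundKey(1, 1), CompoundKey(2, 2)} and value == 8.0

    def test_matches_exhaustive_scan(self, rng):
        ls = random_landscape(20, 20, seed=99)
        keys, value = ls.global_optimum()
        best = max(ls.responses.values())
        assert value == best
        assert keys == {k for k, v in ls.responses.items() if v == best}


def test_matrix_export_shape_and_values(tiny_landscape):
    mat = tiny_landscape.to_matrix()
    assert mat.shape == (3, 3)
    assert mat.loc["A2", "B3"] == 9.0
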