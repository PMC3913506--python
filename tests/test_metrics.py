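"""Goodness criteria: DGO closed form, region coverage, enrichment, z-test."""

import numpy as np
import pytest
from scipy import stats as sps

from edopt import (
    CombinatorialLandscape,
    CompoundKey,
    EvaluatedDesign,
    build_goodness_report,
    dgo,
    dgo_alpha,
    enrichment_curve,
    one_tailed_two_proportion_test,
    response_frequency_table,
)
from edopt.design import RunResult
from edopt.synthetic import random_landscape


class TestDGO:
    def test_optimum_found_gives_one(self):
        assert dgo(8.00, 8.00, 3.40) == 1.00

    def test_worst_case_gives_zero(self):
        assert dgo(3.40, 8.00, 3.40) == 0.0

    def test_near_miss_value_by_hand(self):
        # 1 - 0.40 / 4.60 = 0.91304...
        assert dgo(7.60, 8.00, 3.40) == pytest.approx(0.913, abs=5e-4)

    def test_affine_and_strictly_increasing_in_y_hat(self):
        ys = np.linspace(3.40, 8.00, 47)
        vals = np.array([dgo(y, 8.00, 3.40) for y in ys])
        assert np.all(np.diff(vals) > 0)
        second_diff = np.diff(vals, n=2)
        assert np.allclose(second_diff, 0.0, atol=1e-12)
        assert vals[-1] == 1.0 and vals[0] == 0.0

    def test_degenerate_range_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            dgo(5.0, 5.0, 5.0)
        with pytest.raises(ValueError, match="between"):
            dgo(9.0, 8.0, 3.4)


def _hundred_cell_landscape():
    return CombinatorialLandscape(
        10, 10,
        {CompoundKey(i // 10 + 1, i % 10 + 1): float(i + 1) for i in range(100)},
    )


class TestDGOAlpha:
    def test_disjoint_tested_set_gives_zero(self):
        ls = _hundred_cell_landscape()
        tested = [CompoundKey(1, b) for b in range(1, 6)]  # values 1..5
        assert dgo_alpha(tested, ls, 0.05) == 0.0

    def test_full_region_gives_one(self):
        ls = _hundred_cell_landscape()
        region = ls.optimal_region(0.05)
        assert dgo_alpha(region, ls, 0.05) == 1.0

    def test_partial_coverage_brute_force(self):
        ls = _hundred_cell_landscape()
        region = sorted(ls.optimal_region(0.05))  # 5 cells: values 96..100
        assert len(region) == 5
        tested = region[:2] + [CompoundKey(1, 1)]
        assert dgo_alpha(tested, ls, 0.05) == pytest.approx(0.40)

    def test_accepts_evaluated_design(self):
        ls = _hundred_cell_landscape()
        design = EvaluatedDesign()
        for key in sorted(ls.optimal_region(0.05)):
            design.add(key, ls.evaluate(key), 1)
        assert dgo_alpha(design, ls, 0.05) == 1.0

    def test_matches_brute_force_on_random_landscape(self, rng):
        ls = random_landscape(50, 50, seed=31)
        keys = list(ls.responses)
        tested = [keys[i] for i in rng.choice(len(keys), size=140, replace=False)]
        for alpha in (0.01, 0.05):
            threshold = np.quantile(list(ls.responses.values()), 1 - alpha)
            num = sum(ls.responses[k] >= threshold for k in tested)
            den = sum(v >= threshold for v in ls.responses.values())
            assert dgo_alpha(tested, ls, alpha) == pytest.approx(num / den)


def _planted_run(landscape, per_generation_keys):
    design = EvaluatedDesign()
    for gen, keys in enumerate(per_generation_keys, start=1):
        for k in keys:
            design.add(k, landscape.evaluate(k), gen)
    best_key, best_value = design.best()
    return RunResult(
        method="EDO", design=design, landscape=landscape, best_key=best_key,
        best_value=best_value,
        generation_found=next(
            r.generation for r in design.records if r.activity == best_value
        ),
        per_generation_best=design.best_by_generation(),
        n_generations=design.last_generation, truncated=False,
        reached_known_optimum=False, seed=0, config=None,
    )


class TestEnrichmentCurve:
    def test_flat_then_rising_for_a_planted_run(self):
        ls = _hundred_cell_landscape()
        region = sorted(ls.optimal_region(0.05))
        low = [CompoundKey(1, b) for b in range(1, 10)]
        run = _planted_run(ls, [low[:4], low[4:8], [region[0], region[1]]])
        curve = enrichment_curve(run, ls, 0.05)
        assert curve == [0.0, 0.0, pytest.approx(0.4)]

    def test_non_decreasing_and_ends_at_final_coverage(self, mmp12_like_run, mmp12_like):
        for alpha in (0.01, 0.05):
            curve = enrichment_curve(mmp12_like_run, mmp12_like, alpha)
            assert all(x <= y for x, y in zip(curve, curve[1:]))
            assert curve[-1] == pytest.approx(
                dgo_alpha(mmp12_like_run.design, mmp12_like, alpha)
            )


class TestTwoProportionTest:
    def test_equal_proportions_give_half(self):
        assert one_tailed_two_proportion_test(3, 10, 6, 20) == pytest.approx(0.5)

    def test_hand_computed_z(self):
        # x1/n1 = 7/24 vs x2/n2 = 4/24, pooled 11/48
        p1, p2, pooled = 7 / 24, 4 / 24, 11 / 48
        z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (2 / 24))
        assert one_tailed_two_proportion_test(7, 24, 4, 24) == pytest.approx(
            sps.norm.sf(z)
        )

    def test_extreme_separation(self):
        assert one_tailed_two_proportion_test(50, 50, 0, 50) < 1e-10

    def test_antisymmetry_without_continuity_correction(self):
        p_fwd = one_tailed_two_proportion_test(7, 24, 4, 24)
        p_rev = one_tailed_two_proportion_test(4, 24, 7, 24)
        assert p_fwd + p_rev == pytest.approx(1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            one_tailed_two_proportion_test(1, 0, 1, 2)
        with pytest.raises(ValueError):
            one_tailed_two_proportion_test(3, 2, 1, 2)


class TestFrequencyTable:
    def _run_with_values(self, values):
        ls = CombinatorialLandscape(
            1, len(values),
            {CompoundKey(1, b): v for b, v in enumerate(values, start=1)},
        )
        return _planted_run(ls, [list(ls.responses)])

    def test_no_qualifying_responses(self):
        run = self._run_with_values([1.0, 2.0])
        assert response_frequency_table(run, 6.0, 1.0) == {}

    def test_hand_counted_bins(self):
        run = self._run_with_values([6.1, 6.1, 7.9, 2.0])
        table = response_frequency_table(run, 6.0, 1.0)
        assert table == {(6.0, 7.0): 2, (7.0, 8.0): 1}

    def test_total_matches_brute_force_count(self, mmp12_like_run):
        table = response_frequency_table(mmp12_like_run, 6.0, 0.25)
        qualifying = [
            r.activity for r in mmp12_like_run.design.records
            if r.activity is not None and r.activity > 6.0
        ]
        assert sum(table.values()) == len(qualifying)

    def test_non_positive_width_rejected(self, mmp12_like_run):
        with pytest.raises(ValueError, match="positive"):
            response_frequency_table(mmp12_like_run, 6.0, 0.0)


class TestGoodnessReport:
    def test_report_consistency(self, mmp12_like_run, mmp12_like):
        report = build_goodness_report(mmp12_like_run, mmp12_like)
        assert 0.0 <= report.dgo <= 1.0
        assert report.m == mmp12_like_run.n_evaluations
        assert report.n_space == 2500
        recomputed = dgo(report.y_hat_max, report.y_max, report.y_min)
        assert report.dgo == pytest.approx(recomputed)
        for alpha, curve in report.enrichment_curves.items():
            assert curve[-1] == pytest.approx(report.dgo_alpha[alpha])
        assert "dgo" in report.to_json()
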