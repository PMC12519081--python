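"""Tuple scans, frequency maps, minimal sets, and stabilization detection."""

import numpy as np
import pytest

from hoinfo import (DataMatrix, ScanConfig, ValidationError,
                    detect_stabilization, estimate_covariance,
                    minimal_synergistic_set, scan, top_fraction_frequency)
from hoinfo.synthetic import gen_independent, gen_redundant, gen_synergistic
from hoinfo.tuple_scan import InfoCurve, OrderResult


@pytest.fixture(scope="module")
def small_data():
    return gen_independent(400, 6, seed=0).data


class TestScan:
    def test_exhaustive_when_budget_allows(self):
        data = gen_independent(300, 4, seed=1).data
        curve = scan(data, ScanConfig(orders=[3], budget=10, seed=0))
        res = curve.per_order[3]
        assert res.n_evaluated == 4  # C(4,3)
        assert res.exhaustive

    def test_sampled_equals_exhaustive_at_budget_boundary(self, small_data):
        cov = estimate_covariance(small_data)
        # C(6,3) = 20: budget 20 enumerates, budget 1000 also enumerates
        a = scan(cov, ScanConfig(orders=[3], budget=20, seed=0))
        b = scan(cov, ScanConfig(orders=[3], budget=1000, seed=99))
        assert a.per_order[3].tuples == b.per_order[3].tuples
        np.testing.assert_array_equal(a.per_order[3].values,
                                      b.per_order[3].values)

    def test_sampling_draws_distinct_tuples(self, small_data):
        curve = scan(small_data, ScanConfig(orders=[3], budget=10, seed=3))
        res = curve.per_order[3]
        assert not res.exhaustive
        assert len(set(res.tuples)) == 10

    def test_seeded_rerun_bit_identical(self, small_data):
        c = ScanConfig(orders=[3, 4], budget=8, seed=11)
        a = scan(small_data, c)
        b = scan(small_data, c)
        for k in (3, 4):
            assert a.per_order[k].tuples == b.per_order[k].tuples
            np.testing.assert_array_equal(a.per_order[k].values,
                                          b.per_order[k].values)

    def test_singular_tuples_skipped_and_tallied(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((200, 3))
        data = DataMatrix(np.column_stack([x, x[:, 0]]),
                          ["a", "b", "c", "a_dup"])
        curve = scan(data, ScanConfig(orders=[3], budget=10, seed=0))
        # tuples containing both a and a_dup are singular: C(2,1) = 2 skipped
        assert curve.skipped_total == 2
        assert curve.per_order[3].n_evaluated == 2

    def test_rsi_scan_excludes_target(self):
        data = gen_independent(400, 5, seed=5).data
        c = ScanConfig(orders=[1, 2], budget=100, seed=0, measure="rsi",
                       target="x03")
        curve = scan(data, c)
        for res in curve.per_order.values():
            assert all("x03" not in t for t in res.tuples)

    def test_order_exceeding_variables_rejected(self, small_data):
        with pytest.raises(ValidationError):
            scan(small_data, ScanConfig(orders=[7], budget=10))

    def test_oinfo_needs_order_three(self):
        with pytest.raises(ValidationError):
            ScanConfig(orders=[2], budget=10, measure="oinfo")

    def test_redundant_ensemble_mean_nondecreasing(self):
        """With one shared latent factor the per-order mean O-info grows
        with tuple size."""
        data = gen_redundant(5000, p=8, seed=6).data
        curve = scan(data, ScanConfig(orders=range(3, 8), budget=150, seed=0))
        means = curve.statistic("mean")
        assert np.all(np.diff(means) > -1e-6)
        assert np.all(means > 0)


class TestFrequencyMap:
    def test_single_selected_tuple_scores_members_one(self, small_data):
        curve = scan(small_data, ScanConfig(orders=[3], budget=1000, seed=0))
        fm = top_fraction_frequency(curve, fraction=1e-9, side="min")
        col = fm.frequencies[3]
        assert fm.n_selected[3] == 1
        assert sorted(col[col > 0].index) == sorted(
            curve.per_order[3].tuples[np.argmin(curve.per_order[3].values)])
        assert set(col.unique()) <= {0.0, 1.0}

    def test_column_sums_equal_order(self, small_data):
        """Each selected tuple contributes `order` memberships, so the
        frequency column sums to the order."""
        curve = scan(small_data, ScanConfig(orders=[3, 4], budget=1000, seed=0))
        fm = top_fraction_frequency(curve, fraction=0.25)
        for order in (3, 4):
            assert fm.frequencies[order].sum() == pytest.approx(order)

    def test_planted_constrained_trio_ranks_highest(self):
        """A constraint-conditioned trio among independents dominates the
        top-synergy tuples at every order."""
        ds = gen_synergistic(4000, p=3, seed=7, tau=0.3, n_background=5)
        planted = set(ds.truth["constrained"])
        curve = scan(ds.data, ScanConfig(orders=range(3, 6), budget=5000,
                                         seed=0))
        fm = top_fraction_frequency(curve, fraction=0.05, side="min")
        top3 = set(fm.mean_frequency().index[:3])
        assert top3 == planted

    def test_redundant_block_dominates_max_side(self):
        """With side='max' on a planted latent-factor block, the block
        variables lead the frequency ranking."""
        rng = np.random.default_rng(8)
        n = 4000
        z = rng.standard_normal(n)
        block = np.column_stack([z + 0.7 * rng.standard_normal(n)
                                 for _ in range(3)])
        noise = rng.standard_normal((n, 5))
        data = DataMatrix(np.column_stack([block, noise]),
                          ["b1", "b2", "b3", "n1", "n2", "n3", "n4", "n5"])
        curve = scan(data, ScanConfig(orders=range(3, 6), budget=5000, seed=0))
        fm = top_fraction_frequency(curve, fraction=0.05, side="max")
        assert set(fm.mean_frequency().index[:3]) == {"b1", "b2", "b3"}

    def test_invalid_fraction_rejected(self, small_data):
        curve = scan(small_data, ScanConfig(orders=[3], budget=10, seed=0))
        with pytest.raises(ValidationError):
            top_fraction_frequency(curve, fraction=0.0)


def _curve_from_series(values_per_order: dict[int, list[float]]) -> InfoCurve:
    per_order = {}
    for k, vals in values_per_order.items():
        tuples = [tuple(f"v{i + j}" for j in range(k))
                  for i in range(len(vals))]
        per_order[k] = OrderResult(k, tuples, np.array(vals, dtype=float),
                                   exhaustive=True)
    return InfoCurve("rsi", per_order)


class TestMinimalSet:
    def test_infinite_tolerance_returns_smallest_order(self):
        curve = _curve_from_series({2: [-0.1], 3: [-0.5], 4: [-0.9]})
        ms = minimal_synergistic_set(curve, tolerance=np.inf)
        assert ms.order == 2

    def test_strictly_decreasing_returns_largest_order(self):
        curve = _curve_from_series({2: [-0.1], 3: [-0.5], 4: [-0.9]})
        ms = minimal_synergistic_set(curve)
        assert ms.order == 4
        assert ms.value_nats == pytest.approx(-0.9)

    def test_plateau_returns_first_order_on_it(self):
        curve = _curve_from_series({2: [-0.35], 3: [-0.35], 4: [-0.351]})
        ms = minimal_synergistic_set(curve)
        assert ms.order == 2

    def test_non_contiguous_orders_rejected(self):
        curve = _curve_from_series({2: [-0.1], 4: [-0.9]})
        with pytest.raises(ValidationError):
            minimal_synergistic_set(curve)

    def test_tie_breaks_lexicographically(self):
        per_order = {2: OrderResult(2, [("b", "c"), ("a", "b")],
                                    np.array([-1.0, -1.0]), True)}
        ms = minimal_synergistic_set(InfoCurve("rsi", per_order))
        assert ms.tuple == ("a", "b")


class TestStabilization:
    def test_worked_example(self):
        """s = [0, -3, -4.5, -5, -5, -5]: interior second differences are
        [1.5, 1.0, 0.5, 0.0]; the minimum sits at index 4."""
        assert detect_stabilization([0, -3, -4.5, -5, -5, -5]) == 4

    def test_linear_series_ties_to_first_interior(self):
        assert detect_stabilization([5, 4, 3, 2, 1]) == 1

    def test_plateau_extension_stable_under_first_min_convention(self):
        base = [0, -3, -4.5, -5, -5, -5]
        extended = base + [-5, -5]
        assert detect_stabilization(base) == 4
        assert detect_stabilization(extended) == 4

    def test_alternative_knee_rule(self):
        s = [0, -3, -4.5, -5, -5, -5]
        assert detect_stabilization(s, rule="max_abs_d2") == 1

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            detect_stabilization([1.0, 2.0])
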