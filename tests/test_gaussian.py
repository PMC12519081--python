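"""Closed-form Gaussian information measures: hand values, identities,
invariances, and agreement with plug-in estimates from simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import random_pd_cov
from hoinfo import (CovarianceModel, DataMatrix, SingularCovarianceError,
                    ValidationError, conditional_covariance,
                    conditional_variance, dual_total_correlation,
                    estimate_covariance, gaussian_entropy, gaussian_mi,
                    o_info, rsi, total_correlation)

LN_2PIE = math.log(2 * math.pi * math.e)


def equicorrelated(rho, k=3, var=1.0):
    return CovarianceModel(var * (np.eye(k) * (1 - rho) + rho),
                           [f"v{i}" for i in range(k)], 100)


@pytest.fixture
def sum_cov():
    # X3 = X1 + X2 + unit noise: Sigma = [[1,0,1],[0,1,1],[1,1,3]]
    return CovarianceModel(np.array([[1, 0, 1], [0, 1, 1], [1, 1, 3.0]]),
                           ["x1", "x2", "y"], 100)


class TestEntropyAndMI:
    def test_entropy_hand_values(self):
        cov = CovarianceModel(np.diag([1.0, 4.0]), ["a", "b"], 10)
        assert gaussian_entropy(cov, ["a"]) == pytest.approx(0.5 * LN_2PIE)
        assert gaussian_entropy(cov, ["b"]) == pytest.approx(
            0.5 * LN_2PIE + 0.5 * math.log(4))
        # additivity under independence
        assert gaussian_entropy(cov, ["a", "b"]) == pytest.approx(
            gaussian_entropy(cov, ["a"]) + gaussian_entropy(cov, ["b"]))

    @pytest.mark.parametrize("rho,expected", [
        (0.0, 0.0), (0.5, -0.5 * math.log(0.75)),
    ])
    def test_mi_closed_form(self, rho, expected):
        assert gaussian_mi(equicorrelated(rho, 2), "v0", "v1") == \
            pytest.approx(expected, abs=1e-12)

    def test_mi_is_entropy_combination(self):
        rng = np.random.default_rng(3)
        cov = random_pd_cov(rng, 4)
        expected = (gaussian_entropy(cov, ["v0"]) + gaussian_entropy(cov, ["v2"])
                    - gaussian_entropy(cov, ["v0", "v2"]))
        assert gaussian_mi(cov, "v0", "v2") == pytest.approx(expected, abs=1e-12)

    def test_mi_errors_on_perfect_correlation(self):
        cov = CovarianceModel(np.array([[1.0, 1.0], [1.0, 1.0]]),
                              ["a", "b"], 10)
        with pytest.raises(SingularCovarianceError):
            gaussian_mi(cov, "a", "b")


class TestOInfo:
    @pytest.mark.parametrize("sigma,expected", [
        # X3 = X1 + X2 + noise: |S|=1, prod var = 3, prod minors = 4
        (np.array([[1, 0, 1], [0, 1, 1], [1, 1, 3.0]]),
         0.5 * math.log(3 / 4)),
        # common latent factor: diag 2, off-diag 1
        (np.eye(3) + 1.0, 0.5 * math.log(32 / 27)),
    ])
    def test_hand_evaluated(self, sigma, expected):
        cov = CovarianceModel(sigma, ["a", "b", "c"], 100)
        assert o_info(cov, ["a", "b", "c"]).value == \
            pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("rho,expected_printed", [
        (0.45, 0.0625), (-0.45, -0.4403),
    ])
    def test_equicorrelated_closed_form(self, rho, expected_printed):
        closed = 0.5 * math.log(
            (1 - rho) ** 2 * (1 + 2 * rho) / (1 - rho ** 2) ** 3)
        got = o_info(equicorrelated(rho), ["v0", "v1", "v2"]).value
        assert got == pytest.approx(closed, abs=1e-12)
        assert got == pytest.approx(expected_printed, abs=5e-5)

    def test_independent_triple_is_zero(self):
        got = o_info(equicorrelated(0.0), ["v0", "v1", "v2"]).value
        assert abs(got) < 1e-10

    def test_requires_at_least_three(self, sum_cov):
        with pytest.raises(ValidationError):
            o_info(sum_cov, ["x1", "x2"])

    def test_equals_tc_minus_dtc(self, sum_cov):
        sub = ["x1", "x2", "y"]
        tc = total_correlation(sum_cov, sub)
        dtc = dual_total_correlation(sum_cov, sub)
        assert tc >= 0 and dtc >= 0
        assert o_info(sum_cov, sub).value == pytest.approx(tc - dtc, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(3, 7))
    def test_invariances(self, seed, k):
        """O-info is invariant to subset permutation and per-variable
        rescaling, and equals TC - DTC, on random PD matrices."""
        rng = np.random.default_rng(seed)
        cov = random_pd_cov(rng, k)
        names = cov.variable_names
        base = o_info(cov, names).value
        assert base == pytest.approx(
            total_correlation(cov, names) - dual_total_correlation(cov, names),
            abs=1e-9)
        perm = [names[i] for i in rng.permutation(k)]
        assert o_info(cov, perm).value == pytest.approx(base, abs=1e-9)
        scales = rng.uniform(0.2, 5.0, size=k)
        scaled = CovarianceModel(cov.sigma * np.outer(scales, scales),
                                 names, cov.n_samples)
        assert o_info(scaled, names).value == pytest.approx(base, abs=1e-9)

    def test_block_additivity(self):
        """O-info of a union of independent blocks is the sum of per-block
        O-info values."""
        rng = np.random.default_rng(42)
        a = random_pd_cov(rng, 3, names=["a0", "a1", "a2"])
        b = random_pd_cov(rng, 4, names=["b0", "b1", "b2", "b3"])
        sigma = np.block([
            [a.sigma, np.zeros((3, 4))],
            [np.zeros((4, 3)), b.sigma],
        ])
        joint = CovarianceModel(sigma, a.variable_names + b.variable_names, 100)
        expected = (o_info(a, a.variable_names).value
                    + o_info(b, b.variable_names).value)
        assert o_info(joint, joint.variable_names).value == \
            pytest.approx(expected, abs=1e-9)

    def test_singular_minor_names_variable(self):
        sigma = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1.0]])
        cov = CovarianceModel(sigma, ["a", "a_dup", "b"], 10)
        with pytest.raises(SingularCovarianceError):
            o_info(cov, ["a", "a_dup", "b"])


class TestConditional:
    def test_independent_target_leaves_covariance(self):
        cov = equicorrelated(0.0, 4)
        cond = conditional_covariance(cov, ["v0", "v1"], "v3")
        np.testing.assert_allclose(cond.sigma, np.eye(2), atol=1e-12)

    def test_conditional_variance_closed_form(self):
        cov = equicorrelated(0.5, 2)
        assert conditional_variance(cov, "v0", "v1") == pytest.approx(0.75)

    def test_conditional_never_exceeds_marginal(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            cov = random_pd_cov(rng, 5)
            for x in ["v0", "v1", "v2"]:
                assert conditional_variance(cov, x, "v4") <= cov.variance(x) + 1e-12

    def test_target_in_subset_rejected(self):
        with pytest.raises(ValidationError):
            conditional_covariance(equicorrelated(0.2), ["v0", "v1"], "v1")


class TestRSI:
    def test_sum_construction_closed_form(self, sum_cov):
        """Y = X1 + X2 + noise: printed = ln 2 - 1/2 ln 3, results negated."""
        expected = math.log(2) - 0.5 * math.log(3)
        printed = rsi(sum_cov, ["x1", "x2"], "y", convention="printed")
        results = rsi(sum_cov, ["x1", "x2"], "y")
        assert printed.value == pytest.approx(expected, abs=1e-12)
        assert results.value == pytest.approx(-expected, abs=1e-12)
        assert results.convention == "results"

    def test_single_predictor_is_zero(self, sum_cov):
        for conv in ("printed", "results"):
            assert rsi(sum_cov, ["x1"], "y", convention=conv).value == \
                pytest.approx(0.0, abs=1e-12)

    def test_conventions_negate_exactly(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            cov = random_pd_cov(rng, 5)
            p = rsi(cov, ["v0", "v1", "v2"], "v4", convention="printed").value
            r = rsi(cov, ["v0", "v1", "v2"], "v4", convention="results").value
            assert p + r == 0.0

    def test_near_duplicate_predictors_read_redundant(self):
        """Two highly correlated predictors each informative about Y:
        printed negative, results positive (redundancy)."""
        rho = 0.95
        sigma = np.array([
            [1.0, rho, 0.6],
            [rho, 1.0, 0.6],
            [0.6, 0.6, 1.0],
        ])
        cov = CovarianceModel(sigma, ["x1", "x2", "y"], 100)
        assert rsi(cov, ["x1", "x2"], "y", convention="printed").value < 0
        assert rsi(cov, ["x1", "x2"], "y").value > 0

    def test_target_among_predictors_rejected(self, sum_cov):
        with pytest.raises(ValidationError):
            rsi(sum_cov, ["x1", "y"], "y")


class TestEstimateCovariance:
    def test_independent_columns_near_identity(self):
        rng = np.random.default_rng(2024)
        data = DataMatrix(rng.standard_normal((100_000, 5)),
                          [f"v{i}" for i in range(5)])
        cov = estimate_covariance(data)
        assert np.max(np.abs(cov.sigma - np.eye(5))) < 0.02

    def test_ridge_adds_trace_scaled_diagonal(self):
        rng = np.random.default_rng(1)
        data = DataMatrix(rng.standard_normal((50, 4)),
                          [f"v{i}" for i in range(4)])
        plain = estimate_covariance(data, ridge=0.0)
        ridged = estimate_covariance(data, ridge=1e-9)
        expected = 1e-9 * np.trace(plain.sigma) / 4
        diff = ridged.sigma - plain.sigma
        np.testing.assert_allclose(np.diag(diff), expected, rtol=1e-6)
        off = diff - np.diag(np.diag(diff))
        assert np.abs(off).max() == 0.0

    def test_duplicated_column_breaks_determinant_ops(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(200)
        data = DataMatrix(np.column_stack([x, x, rng.standard_normal(200)]),
                          ["a", "a_copy", "b"])
        cov = estimate_covariance(data)
        assert cov.sigma[0, 1] == pytest.approx(cov.sigma[0, 0])
        with pytest.raises(SingularCovarianceError):
            o_info(cov, ["a", "a_copy", "b"])

    def test_zero_variance_column_named(self):
        data = DataMatrix(np.column_stack([np.ones(10),
                                           np.arange(10.0)]), ["flat", "ok"])
        with pytest.raises(ValidationError, match="flat"):
            estimate_covariance(data)

    def test_too_few_samples(self):
        data = DataMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]), ["a", "b"])
        with pytest.raises(ValidationError):
            estimate_covariance(data)


class TestPlugInAgreement:
    def test_measures_match_large_sample_plug_in(self):
        """Plug-in estimates from n=1e5 simulated Gaussian samples agree
        with the closed forms evaluated on the population covariance."""
        rng = np.random.default_rng(77)
        pop = random_pd_cov(rng, 4)
        chol = np.linalg.cholesky(pop.sigma)
        x = rng.standard_normal((100_000, 4)) @ chol.T
        est = estimate_covariance(DataMatrix(x, pop.variable_names))
        names = pop.variable_names
        assert o_info(est, names).value == pytest.approx(
            o_info(pop, names).value, abs=0.01)
        assert total_correlation(est, names) == pytest.approx(
            total_correlation(pop, names), abs=0.01)
        assert rsi(est, names[:2], names[3]).value == pytest.approx(
            rsi(pop, names[:2], names[3]).value, abs=0.01)
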