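"""Sequential conditional samplers: exactness, equivalence, failure modes."""

import numpy as np
import pytest

from bahadur import (InvalidDistributionError, OpCounter, Order2Spec,
                     conditional_success_prob, enumerate_pmf, pmf_order2,
                     prefix_conditional_prob, rb_dplr, rb_unstr)
from bahadur.order2 import _outcomes
from bahadur.randomspecs import random_valid_dplr_spec, random_valid_full_spec


def oracle_conditional(table, prefix):
    """P(X_{n+1}=1 | prefix) as a ratio of enumerated marginal sums."""
    n = len(prefix)
    X = table.outcomes
    p = table.probabilities
    mask = np.all(X[:, :n] == np.asarray(prefix), axis=1)
    joint = p[mask & (X[:, n] == 1)].sum()
    marginal = p[mask].sum()
    return joint / marginal


class TestConditionalProbability:
    def test_first_draw_is_marginal(self):
        assert conditional_success_prob(0.3, 0.0, 0.0) == pytest.approx(0.3)

    def test_independence_always_marginal(self, rng):
        S = rng.normal(size=10) * 0.1
        p = conditional_success_prob(0.42, np.zeros(10), S)
        np.testing.assert_allclose(p, 0.42, atol=1e-15)

    def test_two_variable_ratio(self):
        # mu=(0.5,0.5), r=0.5, prefix x1=1: P(X2=1|X1=1) = 0.375/0.5
        spec = Order2Spec.from_correlation([0.5, 0.5], [[1, 0.5], [0.5, 1]])
        assert prefix_conditional_prob(spec, [1]) == pytest.approx(0.75)
        assert prefix_conditional_prob(spec, [0]) == pytest.approx(0.25)

    def test_success_and_failure_probabilities_are_complementary(self, rng):
        mu_n, t, S = 0.37, 0.4, 0.25
        p1 = conditional_success_prob(mu_n, t, S)
        z0 = -np.sqrt(mu_n / (1 - mu_n))
        p0 = (1 - mu_n) * (1 + S + z0 * t) / (1 + S)
        assert p1 + p0 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("m, c", [(4, None), (6, None), (5, 1), (6, 2)])
    def test_matches_enumerated_marginal_ratios(self, m, c, rng):
        spec = (random_valid_full_spec(m, rng) if c is None
                else random_valid_dplr_spec(m, c, rng))
        table = enumerate_pmf(spec)
        for n in range(m):
            for prefix in _outcomes(n) if n else [np.empty(0, dtype=int)]:
                mass = table.probabilities[
                    np.all(table.outcomes[:, :n] == prefix, axis=1)].sum()
                if mass < 1e-10:
                    continue
                assert prefix_conditional_prob(spec, prefix) == pytest.approx(
                    oracle_conditional(table, prefix), abs=1e-10)

    def test_near_zero_prefix_mass_aborts(self):
        with pytest.raises(InvalidDistributionError, match="prefix"):
            conditional_success_prob(0.5, 0.0, -1.0 + 1e-14, step=3)


class TestChainRule:
    @pytest.mark.parametrize("kind", ["full", "dplr"])
    def test_path_probability_equals_pmf(self, kind, rng):
        m = 8 if kind == "dplr" else 6
        spec = (random_valid_full_spec(m, rng) if kind == "full"
                else random_valid_dplr_spec(m, 2, rng))
        if kind == "full":
            X, P = rb_unstr(spec, 200, rng, return_probs=True)
        else:
            X, P = rb_dplr(spec.mu, spec.structure.U, 200, rng,
                           return_probs=True)
        realized = np.where(X == 1, P, 1.0 - P).prod(axis=1)
        for row, prob in zip(X, realized):
            assert prob == pytest.approx(pmf_order2(spec, row),
                                         abs=1e-10, rel=1e-8)


class TestSamplingDistribution:
    def test_identity_matrix_gives_independent_draws(self, rng):
        m, n = 6, 40_000
        spec = Order2Spec.from_correlation(np.full(m, 0.5), np.eye(m))
        X = rb_unstr(spec, n, rng).astype(float)
        C = np.corrcoef(X.T)
        off = ~np.eye(m, dtype=bool)
        assert np.abs(C[off]).max() < 3.5 / np.sqrt(n) + 0.005

    def test_perfectly_correlated_pair_is_always_concordant(self, rng):
        spec = Order2Spec.from_correlation([0.5, 0.5], [[1, 1], [1, 1]])
        X = rb_unstr(spec, 2000, rng)
        np.testing.assert_array_equal(X[:, 0], X[:, 1])

    @pytest.mark.parametrize("maker, label", [
        (lambda rng: random_valid_full_spec(4, rng), "full-m4"),
        (lambda rng: random_valid_dplr_spec(5, 1, rng), "dplr-m5"),
    ])
    def test_total_variation_against_enumeration(self, maker, label, rng):
        spec = maker(rng)
        table = enumerate_pmf(spec)
        n = 50_000
        X = (rb_dplr(spec.mu, spec.structure.U, n, rng)
             if hasattr(spec.structure, "U") else rb_unstr(spec, n, rng))
        idx = X.astype(np.int64) @ (1 << np.arange(spec.m - 1, -1, -1))
        emp = np.bincount(idx, minlength=2**spec.m) / n
        tv = 0.5 * np.abs(emp - table.probabilities).sum()
        assert tv < 0.02

    def test_moment_recovery_within_monte_carlo_error(self, rng):
        spec = random_valid_dplr_spec(6, 2, rng)
        n = 200_000
        X = rb_dplr(spec.mu, spec.structure.U, n, rng).astype(float)
        se_mu = np.sqrt(spec.mu * (1 - spec.mu) / n)
        assert np.all(np.abs(X.mean(0) - spec.mu) < 4 * se_mu)
        Z = (X - spec.mu) / np.sqrt(spec.mu * (1 - spec.mu))
        emp_R = Z.T @ Z / n
        off = ~np.eye(6, dtype=bool)
        # correlation MC standard error is ~1/sqrt(n) for weak dependence
        assert np.abs((emp_R - spec.correlation_matrix())[off]).max() < 4.5 / np.sqrt(n)


class TestDplrUnstrEquivalence:
    def test_identical_streams_and_probabilities(self, rng):
        spec = random_valid_dplr_spec(8, 1, rng)
        expanded = Order2Spec.from_correlation(spec.mu, spec.correlation_matrix())
        seed = 991
        Xd, Pd = rb_dplr(spec.mu, spec.structure.U, 5000,
                         np.random.default_rng(seed), return_probs=True)
        Xu, Pu = rb_unstr(expanded, 5000, np.random.default_rng(seed),
                          return_probs=True)
        np.testing.assert_array_equal(Xd, Xu)
        assert np.abs(Pd - Pu).max() < 1e-10

    def test_prefix_probabilities_agree_between_structures(self, rng):
        spec = random_valid_dplr_spec(7, 3, rng)
        expanded = Order2Spec.from_correlation(spec.mu, spec.correlation_matrix())
        for _ in range(30):
            n = rng.integers(0, 7)
            prefix = rng.integers(0, 2, n)
            assert prefix_conditional_prob(spec, prefix) == pytest.approx(
                prefix_conditional_prob(expanded, prefix), abs=1e-10)


class TestTransparentFailure:
    def test_invalid_spec_raises_with_step_context(self, infeasible_spec, rng):
        with pytest.raises(InvalidDistributionError) as err:
            rb_unstr(infeasible_spec, 500, rng)
        assert err.value.step == 1
        assert err.value.value is not None
        assert "step 1" in str(err.value)

    def test_dplr_invalid_spec_raises(self, rng):
        # rank-1 factor implying the same infeasible correlation 0.9
        U = np.array([[np.sqrt(0.9)], [np.sqrt(0.9)]])
        with pytest.raises(InvalidDistributionError):
            rb_dplr(np.array([0.05, 0.95]), U, 500, rng)

    def test_row_norm_violation_is_a_domain_error(self, rng):
        with pytest.raises(ValueError, match="U"):
            rb_dplr(np.array([0.5, 0.5]), np.array([[1.1], [0.0]]), 10, rng)


class TestWorkScaling:
    def test_op_count_growth_rates(self, rng):
        ratios_d, ratios_u = [], []
        prev_d = prev_u = None
        for m in (200, 400, 800):
            mu = np.full(m, 0.3)
            ops_d = OpCounter()
            rb_dplr(mu, np.zeros((m, 1)), 2, rng, ops=ops_d)
            ops_u = OpCounter()
            rb_unstr(Order2Spec.from_correlation(mu, np.eye(m)), 2, rng,
                     ops=ops_u)
            if prev_d is not None:
                ratios_d.append(ops_d.total / prev_d)
                ratios_u.append(ops_u.total / prev_u)
            prev_d, prev_u = ops_d.total, ops_u.total
        assert all(abs(r - 2.0) < 0.2 for r in ratios_d)
        assert all(abs(r - 4.0) < 0.4 for r in ratios_u)
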