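"""Ergodic HMM: emissions, decoding vs enumeration, EM, distance kernel."""

import numpy as np
import pytest

import allelescan as al
from allelescan.data import HET, HOM, MISSING, DataError
from allelescan.ergodic import (
    TransitionKernel,
    _scaled_emissions,
    emission_loglik,
)
from allelescan._hmmcore import forward_backward_kernel, viterbi_kernel

from conftest import enumerate_paths, normal_histogram, random_stochastic_matrix


class TestEmissions:
    def test_hom_site_shares_value_across_expressed_states(self, fixture_model):
        L = emission_loglik(
            fixture_model,
            np.array([2.0]),
            np.array([np.nan]),
            np.array([HOM]),
        )
        assert np.allclose(L[0, 1:], L[0, 1])
        # non-expressed state differs (different E histogram)
        assert L[0, 0] != pytest.approx(L[0, 1])

    def test_het_site_at_balanced_mean_favours_balanced_state(
        self, fixture_model
    ):
        L = emission_loglik(
            fixture_model,
            np.array([2.5]),
            np.array([0.0]),  # R at the balanced state's mean
            np.array([HET]),
        )
        expressed = L[0, 1:]
        assert np.argmax(expressed) == 3  # B is the middle expressed state

    def test_low_expression_favours_nonexpressed_by_histogram_ratio(self):
        h_expr = normal_histogram(3.0, 0.5)
        h_non = normal_histogram(0.0, 0.5)
        model = al.make_initial_model(3, h_expr, h_non, D=1000.0)
        E = np.array([0.0])
        L = emission_loglik(model, E, np.array([np.nan]), np.array([HOM]))
        expected = h_non.logpdf(E)[0] - h_expr.logpdf(E)[0]
        assert L[0, 0] - L[0, 1] == pytest.approx(expected)

    def test_missing_genotype_contributes_nothing(self, fixture_model):
        L = emission_loglik(
            fixture_model,
            np.array([np.nan]),
            np.array([np.nan]),
            np.array([MISSING]),
        )
        assert np.all(L == 0.0)


class TestDecodingOracles:
    def _random_instance(self, rng, n, S):
        pi = rng.dirichlet(np.ones(S))
        A = np.stack(
            [random_stochastic_matrix(rng, S, 1.0) for _ in range(n - 1)]
        )
        L = rng.normal(0.0, 2.0, size=(n, S))
        return pi, A, L

    @pytest.mark.parametrize("seed", range(10))
    def test_forward_backward_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        S = int(rng.integers(2, 5))
        pi, A, L = self._random_instance(rng, n, S)
        B, off = _scaled_emissions(L)
        gap_idx = np.arange(n - 1, dtype=np.int64)
        gamma, xi, log_c = forward_backward_kernel(pi, A, gap_idx, B)
        g0, x0, ll0, _, _ = enumerate_paths(pi, list(A), L)
        np.testing.assert_allclose(gamma, g0, atol=1e-9)
        np.testing.assert_allclose(xi, x0, atol=1e-9)
        assert log_c + off == pytest.approx(ll0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_viterbi_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 7))
        S = int(rng.integers(2, 5))
        pi, A, L = self._random_instance(rng, n, S)
        path, best = viterbi_kernel(
            np.log(pi), np.log(A), np.arange(n - 1, dtype=np.int64), L
        )
        _, _, _, path0, best0 = enumerate_paths(pi, list(A), L)
        assert best == pytest.approx(best0, abs=1e-9)
        np.testing.assert_array_equal(path, path0)

    def test_xi_marginals_consistent_with_gamma(self):
        rng = np.random.default_rng(4)
        pi, A, L = self._random_instance(rng, 6, 4)
        B, _ = _scaled_emissions(L)
        gamma, xi, _ = forward_backward_kernel(
            pi, A, np.arange(5, dtype=np.int64), B
        )
        np.testing.assert_allclose(xi.sum(axis=2), gamma[:-1], atol=1e-10)
        np.testing.assert_allclose(xi.sum(axis=1), gamma[1:], atol=1e-10)

    def test_single_site_posterior_is_pi_times_emission(self, fixture_model):
        E = np.array([2.5])
        R = np.array([0.4])
        geno = np.array([HET])
        gamma, _, ll = al.forward_backward(fixture_model, E, R, geno)
        L = emission_loglik(fixture_model, E, R, geno)
        expected = fixture_model.pi * np.exp(L[0])
        np.testing.assert_allclose(
            gamma[0], expected / expected.sum(), atol=1e-12
        )
        assert ll == pytest.approx(np.log(expected.sum()))

    def test_uniform_emissions_give_markov_marginals(self, fixture_model):
        # missing genotypes: every state equally likely per site, so the
        # posterior reduces to the prior chain marginals pi @ T^t
        n = 5
        geno = np.full(n, MISSING)
        gamma, _, _ = al.forward_backward(
            fixture_model,
            np.full(n, np.nan),
            np.full(n, np.nan),
            geno,
        )
        marg = fixture_model.pi.copy()
        for t in range(n):
            np.testing.assert_allclose(gamma[t], marg, atol=1e-9)
            marg = marg @ fixture_model.T

    def test_viterbi_tie_breaks_to_lower_state(self):
        # two symmetric states, symmetric emissions: path of 0s wins
        pi = np.array([0.5, 0.5])
        A = np.array([[[0.5, 0.5], [0.5, 0.5]]])
        L = np.zeros((4, 2))
        path, _ = viterbi_kernel(
            np.log(pi), np.log(A), np.zeros(3, dtype=np.int64), L
        )
        np.testing.assert_array_equal(path, np.zeros(4, dtype=np.int64))

    def test_overwhelming_emissions_give_constant_path(self, fixture_model):
        n = 6
        E = np.full(n, 2.5)
        R = np.full(n, fixture_model.mu[7])  # strong positive imbalance
        geno = np.full(n, HET)
        path = al.viterbi(fixture_model, E, R, geno)
        assert (path == 7).all()


class TestTransitionKernel:
    def test_identity_root_is_identity(self):
        T1 = al.unit_transition(np.eye(4), 100.0)
        np.testing.assert_allclose(T1, np.eye(4), atol=1e-12)

    def test_distance_one_returns_t(self):
        rng = np.random.default_rng(1)
        T = random_stochastic_matrix(rng, 4)
        np.testing.assert_allclose(al.unit_transition(T, 1.0), T, atol=1e-10)

    def test_root_power_inverse(self):
        rng = np.random.default_rng(2)
        T = random_stochastic_matrix(rng, 3)
        T1 = al.unit_transition(T, 1000.0)
        np.testing.assert_allclose(
            np.linalg.matrix_power(T1, 1000), T, atol=1e-6
        )

    def test_zero_distance_is_identity(self):
        rng = np.random.default_rng(3)
        k = TransitionKernel(random_stochastic_matrix(rng, 4), 500.0)
        np.testing.assert_allclose(k.at_distance(0), np.eye(4))

    def test_distance_d_recovers_t(self):
        rng = np.random.default_rng(4)
        T = random_stochastic_matrix(rng, 5)
        k = TransitionKernel(T, 750.0)
        np.testing.assert_allclose(k.at_distance(750.0), T, atol=1e-6)

    def test_semigroup_property_pre_projection(self):
        rng = np.random.default_rng(5)
        T = random_stochastic_matrix(rng, 4)
        k = TransitionKernel(T, 1000.0)
        d1, d2 = 333.0, 808.0
        lhs = k.power_raw((d1 + d2) / k.D)
        rhs = k.power_raw(d1 / k.D) @ k.power_raw(d2 / k.D)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_rows_stochastic_at_any_distance(self):
        rng = np.random.default_rng(6)
        k = TransitionKernel(random_stochastic_matrix(rng, 4), 1234.0)
        for d in [1, 17, 500, 1234, 99999]:
            M = k.at_distance(d)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-9)
            assert (M >= 0).all()


class TestBaumWelch:
    def _sim_sequences(self, model, n, rng, het_prob=0.6):
        S = model.n_states
        states = np.empty(n, dtype=np.int64)
        states[0] = rng.choice(S, p=model.pi)
        for t in range(1, n):
            states[t] = rng.choice(S, p=model.T[states[t - 1]])
        # E from each state's histogram (shared expressed/non-expressed)
        def draw_hist(h, size):
            bins = rng.choice(h.n_bins, p=h.mass, size=size)
            return rng.uniform(h.edges[bins], h.edges[bins + 1])

        E = np.empty(n)
        non = states == 0
        E[non] = draw_hist(model.hist_nonexpressed, int(non.sum()))
        E[~non] = draw_hist(model.hist_expressed, int((~non).sum()))
        geno = np.where(rng.random(n) < het_prob, HET, HOM).astype(np.int8)
        R = np.where(
            geno == HET,
            rng.normal(model.mu[states], model.sigma[states]),
            np.nan,
        )
        return E, R, geno, states

    def test_loglik_nondecreasing_and_converges(self, fixture_model):
        rng = np.random.default_rng(10)
        E, R, geno, _ = self._sim_sequences(fixture_model, 2000, rng)
        init = al.make_initial_model(
            3,
            fixture_model.hist_expressed,
            fixture_model.hist_nonexpressed,
            D=4000.0,
        )
        trained = al.baum_welch_train([(E, R, geno)], init, max_iter=30)
        ll = np.array(trained.loglik_history)
        assert np.all(np.diff(ll) >= -1e-6)

    def test_fixed_point_after_convergence(self, fixture_model):
        rng = np.random.default_rng(11)
        E, R, geno, _ = self._sim_sequences(fixture_model, 1500, rng)
        init = al.make_initial_model(
            3,
            fixture_model.hist_expressed,
            fixture_model.hist_nonexpressed,
            D=4000.0,
        )
        trained = al.baum_welch_train([(E, R, geno)], init, max_iter=150)
        again = al.baum_welch_train([(E, R, geno)], trained, max_iter=1)
        np.testing.assert_allclose(again.mu, trained.mu, atol=5e-3)
        np.testing.assert_allclose(again.T, trained.T, atol=5e-3)

    def test_training_is_reproducible(self, fixture_model):
        rng = np.random.default_rng(12)
        E, R, geno, _ = self._sim_sequences(fixture_model, 800, rng)
        init = al.make_initial_model(
            3,
            fixture_model.hist_expressed,
            fixture_model.hist_nonexpressed,
            D=4000.0,
        )
        a = al.baum_welch_train([(E, R, geno)], init, max_iter=10)
        b = al.baum_welch_train([(E, R, geno)], init, max_iter=10)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.T, b.T)

    def test_mu_ordering_enforced(self, fixture_model):
        rng = np.random.default_rng(13)
        E, R, geno, _ = self._sim_sequences(fixture_model, 1000, rng)
        init = al.make_initial_model(
            3,
            fixture_model.hist_expressed,
            fixture_model.hist_nonexpressed,
            D=4000.0,
        )
        trained = al.baum_welch_train([(E, R, geno)], init, max_iter=20)
        assert np.all(np.diff(trained.mu[1:]) >= 0)


class TestPosteriorScore:
    def test_point_mass_examples(self, fixture_model):
        S = fixture_model.n_states
        g = np.zeros((3, S))
        g[0, 7] = 1.0  # mu = 2
        g[1, 0] = 1.0  # N: convention mu = 0
        g[2, 1] = 0.5  # mu = -2
        g[2, 7] = 0.5  # mu = +2
        s = al.posterior_expected_logratio(g, fixture_model)
        np.testing.assert_allclose(s, [2.0, 0.0, 0.0], atol=1e-12)

    def test_score_bounded_by_state_means(self, small_dataset, fixture_model):
        _, sites, matrix, _ = small_dataset
        track = al.score_ergodic(sites, matrix, fixture_model)
        mu = fixture_model.score_mu()
        assert np.nanmin(track.scores) >= mu.min() - 1e-9
        assert np.nanmax(track.scores) <= mu.max() + 1e-9


def test_model_json_round_trip(fixture_model, tmp_path):
    path = tmp_path / "model.json"
    fixture_model.to_json(path)
    back = al.ErgodicModel.from_json(path)
    np.testing.assert_allclose(back.mu, fixture_model.mu)
    np.testing.assert_allclose(back.T, fixture_model.T)
    np.testing.assert_allclose(
        back.hist_expressed.mass, fixture_model.hist_expressed.mass
    )
    assert back.D == fixture_model.D
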