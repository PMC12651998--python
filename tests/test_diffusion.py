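"""Exactness of the discrete edge-diffusion machinery.

The closed-form cumulative transition is checked against the iterated
matrix product, and the reverse posterior against Bayes' rule computed
by exhaustive enumeration of the 2-state chain's joint outcomes.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import planet
from planet.diffusion import bridge_matrix, sample_stationary


def iterated_product(schedule, t):
    """Brute-force product of single-step transition matrices."""
    m = np.eye(2)
    for i in range(1, t + 1):
        m = m @ planet.transition_matrix(schedule, i)
    return m


def enumeration_posterior(schedule, t_prev, t, e_t, p_e0_edge):
    """Bayes by exhaustive enumeration over (e0, e_prev) outcomes."""
    mbar_prev = planet.cumulative_transition(schedule, t_prev)
    bridge = bridge_matrix(schedule, t_prev, t)
    post = np.zeros(2)
    for e0 in (0, 1):
        w_e0 = p_e0_edge if e0 == 1 else 1.0 - p_e0_edge
        joint = np.array([mbar_prev[e0, p] * bridge[p, e_t] for p in (0, 1)])
        if joint.sum() > 0:
            post += w_e0 * joint / joint.sum()
    return post / post.sum()


class TestSchedule:
    def test_limits_and_validity(self):
        sch = planet.cosine_schedule(50, 0.9)
        assert np.all((sch.alpha >= 0) & (sch.alpha <= 1))
        assert np.all(np.diff(sch.gamma_bar) >= -1e-12)
        assert sch.gamma_bar[0] == 0.0
        assert sch.gamma_bar[-1] >= 1 - 1e-5
        # step 0: no corruption
        assert np.allclose(planet.cumulative_transition(sch, 0), np.eye(2))
        # step T: both rows equal the stationary distribution (delta, 1-delta)
        mT = planet.cumulative_transition(sch, 50)
        assert np.allclose(mT, [[0.9, 0.1], [0.9, 0.1]], atol=2e-5)

    def test_alpha_product_reconstructs_retention(self):
        sch = planet.cosine_schedule(200, 0.8)
        prod = np.cumprod(1.0 - sch.alpha)
        assert np.allclose(prod, 1.0 - sch.gamma_bar[1:], atol=1e-10)

    def test_transition_matrix_hand_example(self):
        # alpha=0.5, delta=0.9: M = 0.5*S + 0.5*I
        sch = planet.cosine_schedule(10, 0.9)
        sch.alpha = sch.alpha.copy()
        sch.alpha[2] = 0.5
        m = planet.transition_matrix(sch, 3)
        assert np.allclose(m, [[0.95, 0.05], [0.45, 0.55]])

    def test_endpoint_alphas(self):
        sch = planet.cosine_schedule(10, 0.7)
        sch.alpha = sch.alpha.copy()
        sch.alpha[0] = 0.0
        assert np.allclose(planet.transition_matrix(sch, 1), np.eye(2))
        sch.alpha[1] = 1.0
        assert np.allclose(planet.transition_matrix(sch, 2), sch.S)

    @pytest.mark.parametrize("T,delta", [(50, 0.9), (100, 0.5), (17, 0.99)])
    def test_closed_form_equals_iterated_product(self, T, delta):
        sch = planet.cosine_schedule(T, delta)
        for t in range(T + 1):
            assert np.allclose(planet.cumulative_transition(sch, t),
                               iterated_product(sch, t), atol=1e-10)

    def test_row_stochastic_everywhere(self):
        sch = planet.cosine_schedule(60, 0.85)
        for t in range(1, 61):
            for mat in (planet.transition_matrix(sch, t),
                        planet.cumulative_transition(sch, t),
                        bridge_matrix(sch, t - 1, t)):
                assert np.all(mat >= -1e-15)
                assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)

    def test_bridge_composition(self):
        sch = planet.cosine_schedule(40, 0.9)
        for t_prev in range(0, 40, 7):
            for t in range(t_prev, 41, 5):
                lhs = planet.cumulative_transition(sch, t_prev) @ \
                    bridge_matrix(sch, t_prev, t)
                assert np.allclose(lhs, planet.cumulative_transition(sch, t),
                                   atol=1e-10)

    def test_invalid_configs(self):
        with pytest.raises(planet.ConfigurationError):
            planet.cosine_schedule(0, 0.9)
        with pytest.raises(planet.ConfigurationError):
            planet.cosine_schedule(10, 1.0)
        sch = planet.cosine_schedule(10, 0.9)
        with pytest.raises(ValueError):
            planet.transition_matrix(sch, 11)
        with pytest.raises(ValueError):
            planet.cumulative_transition(sch, -1)

    def test_yaml_roundtrip(self, tmp_path):
        sch = planet.cosine_schedule(30, 0.875)
        sch.to_yaml(tmp_path / "sch.yaml")
        back = planet.NoiseSchedule.from_yaml(tmp_path / "sch.yaml")
        assert back.T == 30 and back.delta == 0.875
        assert np.array_equal(back.alpha, sch.alpha)


class TestForwardSampling:
    def test_t0_is_identity_and_seeded(self, schedule):
        rng = np.random.default_rng(0)
        e0 = (rng.random((12, 12)) < 0.2).astype(int)
        np.fill_diagonal(e0, 0)
        assert np.array_equal(planet.forward_sample(e0, 0, schedule, 5), e0)
        a = planet.forward_sample(e0, 40, schedule, 5)
        b = planet.forward_sample(e0, 40, schedule, 5)
        assert np.array_equal(a, b)

    def test_stationary_marginal_independent_of_e0(self, schedule):
        n = 100_000
        ones = np.ones((1, n), dtype=int)
        zeros = np.zeros((1, n), dtype=int)
        f1 = planet.forward_sample(ones, schedule.T, schedule, 1).mean()
        f0 = planet.forward_sample(zeros, schedule.T, schedule, 2).mean()
        # both match the stationary edge frequency 1-delta = 0.1
        se = 3 * np.sqrt(0.1 * 0.9 / n)
        assert abs(f1 - 0.1) < se and abs(f0 - 0.1) < se
        assert abs(f1 - f0) < 0.01  # total-variation bound at 1e5 samples

    def test_midway_marginal_matches_closed_form(self, schedule):
        t = 60
        mbar = planet.cumulative_transition(schedule, t)
        n = 100_000
        stay = planet.forward_sample(np.ones((1, n), dtype=int), t,
                                     schedule, 3).mean()
        p = mbar[1, 1]
        assert abs(stay - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_mask_is_respected(self, schedule):
        e0 = np.ones((6, 6), dtype=int)
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, :3] = True
        et = planet.forward_sample(e0, 30, schedule, 4, mask=mask)
        assert et[~mask].sum() == 0


class TestSubsequence:
    def test_even_spacing(self):
        tau = planet.make_subsequence(1000, 10)
        assert np.array_equal(tau, np.arange(0, 1001, 100))

    def test_full_ladder(self):
        assert np.array_equal(planet.make_subsequence(7, 7), np.arange(8))

    def test_half_ladder_spacing(self):
        tau = planet.make_subsequence(1000, 500)
        assert len(tau) == 501
        assert set(np.diff(tau)) == {2}

    @given(T=st.integers(1, 300), k=st.integers(1, 300))
    @settings(max_examples=60, deadline=None)
    def test_ladder_properties(self, T, k):
        if k > T:
            with pytest.raises(ValueError):
                planet.make_subsequence(T, k)
            return
        tau = planet.make_subsequence(T, k)
        assert tau[0] == 0 and tau[-1] == T
        assert np.all(np.diff(tau) > 0)
        assert len(tau) == k + 1


class TestPosterior:
    def test_rows_normalized(self, schedule):
        rng = np.random.default_rng(0)
        e_t = (rng.random((10, 10)) < 0.3).astype(int)
        p0 = rng.random((10, 10))
        post = planet.posterior(e_t, p0, 50, 20, schedule)
        assert np.allclose(post.sum(axis=-1), 1.0, atol=1e-10)
        assert np.all(post >= 0)

    def test_matches_enumeration_oracle(self):
        """1000 random (schedule, t_prev, t, e_t, p0) draws vs brute force."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            T = int(rng.integers(2, 60))
            delta = float(rng.uniform(0.05, 0.99))
            sch = planet.cosine_schedule(T, delta)
            t = int(rng.integers(1, T + 1))
            t_prev = int(rng.integers(0, t))
            e_t = int(rng.integers(0, 2))
            p0 = float(rng.random())
            expected = enumeration_posterior(sch, t_prev, t, e_t, p0)
            got = planet.posterior(np.array([[0, e_t], [0, 0]]),
                                   np.full((2, 2), p0), t, t_prev, sch)[0, 1]
            assert np.allclose(got, expected, atol=1e-8)

    def test_one_hot_e0_lands_on_clean_state(self, schedule):
        """t_prev=0 with a certain E_0 forces the chain onto that state."""
        e0 = np.array([[0, 1], [0, 0]])
        e_t = np.array([[1, 0], [0, 1]])
        post = planet.posterior(e_t, e0.astype(float), 60, 0, schedule)
        assert np.allclose(post[..., 1], e0, atol=1e-9)

    def test_reverse_step_deterministic_and_seeded(self, schedule):
        rng = np.random.default_rng(5)
        e_t = (rng.random((8, 8)) < 0.3).astype(int)
        p0 = rng.random((8, 8))
        a = planet.reverse_step(e_t, p0, 40, 10, schedule, seed=9)
        b = planet.reverse_step(e_t, p0, 40, 10, schedule, seed=9)
        assert np.array_equal(a, b)
        e0 = (rng.random((8, 8)) < 0.3).astype(float)
        exact = planet.reverse_step(e_t, e0, 40, 0, schedule, seed=1)
        assert np.array_equal(exact, e0.astype(int))

    def test_single_step_matches_ancestral_marginal(self):
        """Skip-step posterior at adjacent steps = classic ancestral step."""
        sch = planet.cosine_schedule(20, 0.9)
        rng = np.random.default_rng(7)
        n = 100_000
        t = 10
        e_t = np.ones((1, n), dtype=int)
        p0 = np.full((1, n), 0.7)
        post = planet.posterior(e_t, p0, t, t - 1, sch)
        # oracle: mixture of enumeration posteriors
        expected = enumeration_posterior(sch, t - 1, t, 1, 0.7)
        assert np.allclose(post[0, 0], expected, atol=1e-10)
        draws = planet.reverse_step(e_t, p0, t, t - 1, sch, seed=2).mean()
        p = expected[1]
        assert abs(draws - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_stationary_sampler_frequency(self, schedule):
        e = sample_stationary((300, 300), schedule, seed=0)
        freq = e.mean()
        assert abs(freq - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 300 ** 2)

    def test_delta_from_suite(self, toy_pair):
        grn, _ = toy_pair
        d = planet.delta_from_suite([grn])
        dens = grn.n_edges / grn.candidate_mask().sum()
        assert d == pytest.approx(1 - dens)
        # clamped at 0.999 for an (almost) empty network
        empty = planet.GRN(genes=["a", "b"], tf_mask=[True, False],
                           adjacency=np.zeros((2, 2), dtype=int))
        assert planet.delta_from_suite([empty]) == 0.999
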