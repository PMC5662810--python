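"""Fusion-cycle checks: mixing identities, degeneracies, mode
identifiability and probability conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heartimm.filtering import GaussianBelief, kf_predict, kf_update
from heartimm.imm import (
    ImmPredictor,
    ModeSet,
    combine_output,
    mix_gaussians,
    mixing_probabilities,
    mix_states,
    sojourn_transition_matrix,
)
from heartimm.uim import ArCoefficients, companion_from_coeffs


def ar_mode(a, name="AR", q=0.01, r=1e-4, order=None):
    """Fixed-coefficient AR KF mode (no RLS adaptation) for controlled tests."""
    coeffs = np.atleast_1d(a)
    spec = companion_from_coeffs(
        ArCoefficients(coeffs, q), measurement_noise_var=r
    ).as_linear_spec()

    class FixedArMode:
        family = "uim"

        def __init__(self):
            self.name = name
            self.spec = spec
            self.belief = GaussianBelief(
                np.zeros(len(coeffs)), 0.1 * np.eye(len(coeffs))
            )

        def predicted_measurement(self):
            H = self.spec.observation
            z = float((H @ self.belief.mean)[0])
            v = float((H @ self.belief.covariance @ H.T)[0, 0])
            return z, v

        def forecast(self, horizon):
            from heartimm.filtering import multi_step_predict

            return multi_step_predict(self.belief, self.spec, horizon)

        def update(self, z):
            prior = kf_predict(self.belief, self.spec)
            zp = float((self.spec.observation @ prior.mean)[0])
            post, innov = kf_update(prior, z, self.spec, mode_name=self.name)
            self.belief = post
            return zp, float(innov.covariance[0, 0]), innov

        def apply_anchor(self, delta, extra_var):
            self.belief.mean[0] += delta
            self.belief.covariance[0, 0] += extra_var

    return FixedArMode()


class TestSojourn:
    def test_formula_values(self):
        np.testing.assert_allclose(
            sojourn_transition_matrix([100.0, 100.0]),
            [[0.99, 0.01], [0.01, 0.99]],
        )
        np.testing.assert_allclose(
            sojourn_transition_matrix([2.0, 2.0]),
            [[0.5, 0.5], [0.5, 0.5]],
        )

    def test_rows_sum_to_one(self, rng):
        tau = rng.uniform(1.5, 500.0, size=4)
        P = sojourn_transition_matrix(tau)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-15)

    def test_sojourn_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            sojourn_transition_matrix([1.0, 10.0])


class TestMixingProbabilities:
    def test_identity_transition_no_mixing(self):
        ms = ModeSet([ar_mode(0.5), ar_mode(-0.5)], np.eye(2), [0.3, 0.7])
        mix, mu_pred = mixing_probabilities(ms)
        np.testing.assert_allclose(mix, np.eye(2))
        np.testing.assert_allclose(mu_pred, [0.3, 0.7])

    def test_uniform_transition_hand_values(self):
        ms = ModeSet(
            [ar_mode(0.5), ar_mode(-0.5)], np.full((2, 2), 0.5), [0.3, 0.7]
        )
        mix, mu_pred = mixing_probabilities(ms)
        np.testing.assert_allclose(mu_pred, [0.5, 0.5])
        np.testing.assert_allclose(mix, [[0.3, 0.3], [0.7, 0.7]])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_columns_always_normalized(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.dirichlet(np.ones(3), size=3)
        mu = rng.dirichlet(np.ones(3))
        ms = ModeSet([ar_mode(0.1), ar_mode(0.2), ar_mode(0.3)], P, mu)
        mix, _ = mixing_probabilities(ms)
        np.testing.assert_allclose(mix.sum(axis=0), 1.0, atol=1e-12)


class TestMixStates:
    def test_single_mode_untouched(self):
        mode = ar_mode(0.7)
        mode.belief = GaussianBelief([1.0], [[0.5]])
        ms = ModeSet([mode], [[1.0]], [1.0])
        mix, _ = mixing_probabilities(ms)
        mix_states(ms, mix)
        assert mode.belief.mean[0] == 1.0
        assert mode.belief.covariance[0, 0] == 0.5

    def test_identical_state_space_hand_mixing(self):
        """Equal-weight mix of two same-family beliefs reproduces the
        hand-expanded probability-weighted mean + spread covariance."""
        m1 = np.array([1.0, 0.0])
        m2 = np.array([3.0, 2.0])
        P = np.eye(2)
        mixed = mix_gaussians(
            [GaussianBelief(m1, P), GaussianBelief(m2, P)],
            np.array([0.5, 0.5]),
        )
        np.testing.assert_allclose(mixed.mean, [2.0, 1.0])
        d1 = m1 - mixed.mean
        expected = P + 0.5 * (np.outer(d1, d1) + np.outer(-d1, -d1))
        np.testing.assert_allclose(mixed.covariance, expected)

    def test_degenerate_weights_select_single_mode(self):
        b1 = GaussianBelief([1.0, 2.0], np.diag([0.1, 0.2]))
        b2 = GaussianBelief([5.0, -1.0], np.diag([0.3, 0.4]))
        mixed = mix_gaussians([b1, b2], np.array([1.0, 0.0]))
        np.testing.assert_allclose(mixed.mean, b1.mean)
        np.testing.assert_allclose(mixed.covariance, b1.covariance)


class TestCombineOutput:
    def test_degenerate_probability(self):
        assert combine_output([1.0, 99.0], [0.5, 7.0], [1.0, 0.0]) == (1.0, 0.5)

    def test_hand_spread_term(self):
        mean, var = combine_output([1.0, 3.0], [1.0, 1.0], [0.5, 0.5])
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(2.0)  # 1 + spread 1

    def test_agreeing_modes_have_no_spread(self, rng):
        z = 1.234
        variances = rng.uniform(0.1, 2.0, 3)
        mu = rng.dirichlet(np.ones(3))
        mean, var = combine_output([z, z, z], variances, mu)
        assert mean == pytest.approx(z)
        assert var == pytest.approx(float(mu @ variances))


class TestImmStep:
    def test_single_mode_bank_equals_bare_filter(self, rng):
        z_seq = rng.standard_normal(200) * 0.3
        bare = ar_mode(0.8, "bare")
        banked = ar_mode(0.8, "banked")
        imm = ImmPredictor([banked], [[1.0]], [1.0], name="IMM1")
        for z in z_seq:
            zp_bare, var_bare, _ = bare.update(z)
            zp_imm, var_imm, _ = imm.update(z)
            assert abs(zp_bare - zp_imm) < 1e-12
            assert abs(var_bare - var_imm) < 1e-12

    def test_identical_two_mode_bank_equals_single_mode(self, rng):
        z_seq = rng.standard_normal(300) * 0.3
        single = ar_mode(0.8, "single")
        twins = [ar_mode(0.8, "twin1"), ar_mode(0.8, "twin2")]
        imm = ImmPredictor(
            twins, sojourn_transition_matrix([50.0, 50.0]), [0.6, 0.4],
            mixing="full",
        )
        for z in z_seq:
            zp_s, _, _ = single.update(z)
            zp_i, _, _ = imm.update(z)
            assert abs(zp_s - zp_i) < 1e-10

    def test_absorbing_mode_stays_absorbed(self, rng):
        z_seq = rng.standard_normal(200)
        imm = ImmPredictor(
            [ar_mode(0.9, "a"), ar_mode(-0.9, "b")], np.eye(2), [1.0, 0.0]
        )
        for z in z_seq:
            imm.update(z)
            np.testing.assert_allclose(imm.mode_probs, [1.0, 0.0], atol=1e-300)

    def test_identifies_generating_ar_mode(self, rng):
        # data from AR(1) with a = +0.99; the matched mode should dominate
        y = np.zeros(1000)
        for k in range(1, 1000):
            y[k] = 0.99 * y[k - 1] + 0.1 * rng.standard_normal()
        imm = ImmPredictor(
            [ar_mode(0.99, "match", q=0.01, r=1e-4),
             ar_mode(-0.99, "anti", q=0.01, r=1e-4)],
            sojourn_transition_matrix([20.0, 20.0]),
            [0.5, 0.5],
        )
        mu_hist = []
        for z in y:
            imm.update(z)
            mu_hist.append(imm.mode_probs[0])
        assert np.mean(mu_hist[100:]) > 0.9

    def test_mode_probs_remain_normalized_long_run(self, rng):
        imm = ImmPredictor(
            [ar_mode(0.5, "a"), ar_mode(-0.5, "b")],
            sojourn_transition_matrix([100.0, 100.0]),
            [0.9, 0.1],
        )
        for z in rng.standard_normal(5000):
            _, _, res = imm.update(z)
            s = res.mode_probs.sum()
            assert abs(s - 1.0) < 1e-10
            assert np.all(res.mode_probs >= 0)


class TestModeSetValidation:
    def test_full_mixing_rejects_heterogeneous_bank(self):
        with pytest.raises(ValueError, match="converter"):
            ModeSet(
                [ar_mode(0.5, order=1), ar_mode([0.5, 0.1], "AR2")],
                np.eye(2), [0.5, 0.5], mixing="full",
            )

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ModeSet([ar_mode(0.5), ar_mode(0.4)], [[0.9, 0.2], [0.1, 0.9]],
                    [0.5, 0.5])

    def test_bad_mode_probs_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            ModeSet([ar_mode(0.5), ar_mode(0.4)], np.eye(2), [0.7, 0.7])


class TestSqiHook:
    def test_disabled_by_default(self, rng):
        imm = ImmPredictor([ar_mode(0.5), ar_mode(-0.5)],
                           sojourn_transition_matrix([100.0, 100.0]),
                           [0.5, 0.5])
        base = imm.mode_set.transition_matrix.copy()
        for z in rng.standard_normal(50):
            imm.update(z)
        np.testing.assert_array_equal(imm.mode_set.transition_matrix, base)

    def test_scales_off_diagonal_switch_rates(self, rng):
        imm = ImmPredictor(
            [ar_mode(0.5), ar_mode(-0.5)],
            sojourn_transition_matrix([100.0, 100.0]),
            [0.5, 0.5],
            sqi_hook=lambda window: 0.5,
        )
        for z in rng.standard_normal(10):
            imm.update(z)
        P = imm.mode_set.transition_matrix
        np.testing.assert_allclose(P, [[0.995, 0.005], [0.005, 0.995]])
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
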