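"""Harmonic-model checks: Jacobians vs finite differences, EKF tracking,
spectral initialization."""

import numpy as np
import pytest

from heartimm.filtering import GaussianBelief
from heartimm.nam import (
    FREQ_FLOOR_HZ,
    HarmonicConfig,
    InitializationError,
    NamNoise,
    NamPredictor,
    NamState,
    nam_ekf_step,
    nam_init_from_signal,
    nam_measure,
    nam_measurement_jacobian,
    nam_transition,
    wrap_phase,
)
from heartimm.synthetic import NormalParams, simulate_normal

CFG = HarmonicConfig(n_cardiac=2, n_resp=1, n_mod_cardiac=1, n_mod_resp=1,
                     dt=0.01)


def random_state(rng, config):
    x = rng.standard_normal(config.dim)
    x[config.idx_fc] = rng.uniform(0.8, 2.0)
    x[config.idx_fr] = rng.uniform(0.1, 0.5)
    return x


class TestTransition:
    def test_zero_dt_is_identity(self, rng):
        cfg = HarmonicConfig(n_cardiac=2, n_resp=1, dt=0.0)
        x = random_state(rng, cfg)
        out, A = nam_transition(x, cfg)
        np.testing.assert_allclose(out, x)
        np.testing.assert_allclose(A, np.eye(cfg.dim))

    def test_fundamental_phase_advance(self):
        cfg = HarmonicConfig(n_cardiac=1, n_resp=0, n_mod_cardiac=0,
                             n_mod_resp=0, dt=0.25)
        x = np.zeros(cfg.dim)
        x[cfg.idx_fc] = 1.0
        out, _ = nam_transition(x, cfg)
        assert out[cfg.sl_phase_c][0] == pytest.approx(np.pi / 2)

    def test_harmonic_multipliers_scale_phase_rate(self, rng):
        x = random_state(rng, CFG)
        out, _ = nam_transition(x, CFG)
        d_theta = out[CFG.sl_phase_c] - x[CFG.sl_phase_c]
        fc = x[CFG.idx_fc]
        np.testing.assert_allclose(
            d_theta, 2 * np.pi * np.array([1, 2]) * fc * CFG.dt, rtol=1e-12
        )

    def test_jacobian_matches_finite_differences(self, rng):
        eps = 1e-6
        for _ in range(100):
            x = random_state(rng, CFG)
            _, A = nam_transition(x, CFG)
            fd = np.empty_like(A)
            for j in range(CFG.dim):
                dx = np.zeros(CFG.dim)
                dx[j] = eps
                fp, _ = nam_transition(x + dx, CFG)
                fm, _ = nam_transition(x - dx, CFG)
                fd[:, j] = (fp - fm) / (2 * eps)
            assert np.max(np.abs(A - fd)) / max(np.max(np.abs(A)), 1.0) < 1e-6


class TestMeasurement:
    def test_offset_only(self):
        x = np.zeros(CFG.dim)
        x[CFG.idx_offset] = 1.7
        assert nam_measure(x, CFG) == pytest.approx(1.7)

    def test_single_cosine_at_zero_phase(self):
        cfg = HarmonicConfig(n_cardiac=1, n_resp=0, n_mod_cardiac=0,
                             n_mod_resp=0, dt=0.01)
        x = np.zeros(cfg.dim)
        x[cfg.sl_amp_c] = 2.0
        assert nam_measure(x, cfg) == pytest.approx(2.0)

    def test_equals_term_by_term_summation(self, rng):
        x = random_state(rng, CFG)
        s = NamState(x, CFG)
        expected = s.offset
        for a, th in zip(s.cardiac_amplitudes, s.cardiac_phases):
            expected += a * np.cos(th)
        for a, th in zip(s.resp_amplitudes, s.resp_phases):
            expected += a * np.cos(th)
        for a, th in zip(s.mod_amplitudes, s.mod_phases):
            expected += a * np.cos(th)
        assert nam_measure(x, CFG) == pytest.approx(expected, rel=1e-12)

    def test_jacobian_entries_at_zero_phase(self):
        cfg = HarmonicConfig(n_cardiac=1, n_resp=0, n_mod_cardiac=0,
                             n_mod_resp=0, dt=0.01)
        x = np.zeros(cfg.dim)
        x[cfg.sl_amp_c] = 3.0
        H = nam_measurement_jacobian(x, cfg)
        assert H[cfg.idx_offset] == 1.0
        assert H[cfg.sl_amp_c][0] == pytest.approx(1.0)  # cos 0
        assert H[cfg.sl_phase_c][0] == pytest.approx(0.0)  # -a sin 0
        # at θ = π/2 the roles flip
        x[cfg.sl_phase_c] = np.pi / 2
        H = nam_measurement_jacobian(x, cfg)
        assert H[cfg.sl_amp_c][0] == pytest.approx(0.0, abs=1e-12)
        assert H[cfg.sl_phase_c][0] == pytest.approx(-3.0)

    def test_jacobian_matches_finite_differences(self, rng):
        eps = 1e-6
        for _ in range(100):
            x = random_state(rng, CFG)
            H = nam_measurement_jacobian(x, CFG)
            fd = np.empty(CFG.dim)
            for j in range(CFG.dim):
                dx = np.zeros(CFG.dim)
                dx[j] = eps
                fd[j] = (nam_measure(x + dx, CFG) - nam_measure(x - dx, CFG)) / (
                    2 * eps
                )
            scale = max(np.max(np.abs(H)), 1.0)
            assert np.max(np.abs(H - fd)) / scale < 1e-6

    def test_phase_wrap_does_not_change_measurement(self, rng):
        x = random_state(rng, CFG)
        x[CFG.sl_phases] = rng.uniform(-50, 50, x[CFG.sl_phases].shape)
        y_raw = nam_measure(x, CFG)
        x[CFG.sl_phases] = wrap_phase(x[CFG.sl_phases])
        assert abs(nam_measure(x, CFG) - y_raw) < 1e-12
        assert np.all(x[CFG.sl_phases] > -np.pi)
        assert np.all(x[CFG.sl_phases] <= np.pi)


class TestEkf:
    def test_zero_innovation_keeps_mean(self):
        cfg = HarmonicConfig(n_cardiac=1, n_resp=1, n_mod_cardiac=0,
                             n_mod_resp=0, dt=0.01)
        noise = NamNoise(q_amp=0.0, q_freq=0.0, q_phase=0.0, r_meas=1e-4)
        mean = np.zeros(cfg.dim)
        mean[cfg.sl_amp_c] = 1.0
        mean[cfg.idx_fc] = 1.2
        mean[cfg.idx_fr] = 0.25
        belief = GaussianBelief(mean, 1e-3 * np.eye(cfg.dim))
        prior_mean, _ = nam_transition(mean, cfg)
        z = nam_measure(prior_mean, cfg)
        post, innov = nam_ekf_step(belief, z, cfg, noise)
        assert innov.residual[0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(post.mean, prior_mean, atol=1e-12)

    def test_tracks_noise_free_cosine(self):
        fs, f, dur = 100.0, 1.0, 10.0
        t = np.arange(int(dur * fs)) / fs
        y = np.cos(2 * np.pi * f * t)
        cfg = HarmonicConfig(n_cardiac=1, n_resp=0, n_mod_cardiac=0,
                             n_mod_resp=0, dt=1 / fs)
        noise = NamNoise(q_amp=1e-10, q_freq=1e-12, q_phase=1e-10, r_meas=1e-8)
        mean = np.zeros(cfg.dim)
        mean[cfg.sl_amp_c] = 1.0
        mean[cfg.idx_fc] = f
        belief = GaussianBelief(mean, 1e-6 * np.eye(cfg.dim))
        pred = NamPredictor(cfg, noise, belief)
        errs = []
        for k in range(1, 1000):
            zp, _, _ = pred.update(y[k])
            if k >= 200:
                errs.append(zp - y[k])
        assert np.sqrt(np.mean(np.square(errs))) < 1e-6

    def test_tracks_drifting_amplitude(self):
        fs = 100.0
        t = np.arange(int(60 * fs)) / fs
        amp = 1.0 + 0.1 * np.sin(2 * np.pi * 0.05 * t)
        y = amp * np.cos(2 * np.pi * 1.0 * t)
        cfg = HarmonicConfig(n_cardiac=1, n_resp=0, n_mod_cardiac=0,
                             n_mod_resp=0, dt=1 / fs)
        noise = NamNoise(q_amp=1e-5, q_freq=1e-10, q_phase=1e-6, r_meas=1e-4)
        mean = np.zeros(cfg.dim)
        mean[cfg.sl_amp_c] = 1.0
        mean[cfg.idx_fc] = 1.0
        pred = NamPredictor(cfg, noise, GaussianBelief(mean, 1e-3 * np.eye(cfg.dim)))
        amp_err = []
        for k in range(1, len(t)):
            pred.update(y[k])
            if k > 2000:
                amp_err.append(pred.belief.mean[cfg.sl_amp_c][0] - amp[k])
        assert np.sqrt(np.mean(np.square(amp_err))) < 0.05

    def test_frequency_floor_enforced(self):
        cfg = HarmonicConfig(n_cardiac=1, n_resp=0, n_mod_cardiac=0,
                             n_mod_resp=0, dt=0.01)
        mean = np.zeros(cfg.dim)
        mean[cfg.idx_fc] = 0.011
        belief = GaussianBelief(mean, np.eye(cfg.dim))
        post, _ = nam_ekf_step(belief, -5.0, cfg, NamNoise())
        assert post.mean[cfg.idx_fc] >= FREQ_FLOOR_HZ


class TestInitialization:
    def test_recovers_two_tone_parameters(self):
        fs = 100.0
        t = np.arange(int(30 * fs)) / fs
        y = 1.0 * np.cos(2 * np.pi * 1.2 * t) + 0.5 * np.cos(2 * np.pi * 0.25 * t)
        cfg = HarmonicConfig(n_cardiac=1, n_resp=1, n_mod_cardiac=0,
                             n_mod_resp=0, dt=1 / fs)
        belief = nam_init_from_signal(y, cfg, sample_rate=fs)
        assert belief.mean[cfg.idx_fc] == pytest.approx(1.2, abs=0.02)
        assert belief.mean[cfg.idx_fr] == pytest.approx(0.25, abs=0.02)
        assert belief.mean[cfg.sl_amp_c][0] == pytest.approx(1.0, abs=0.05)
        assert belief.mean[cfg.sl_amp_r][0] == pytest.approx(0.5, abs=0.05)

    def test_absent_respiration_gives_near_zero_amplitude(self):
        fs = 100.0
        t = np.arange(int(30 * fs)) / fs
        y = np.cos(2 * np.pi * 1.2 * t)
        cfg = HarmonicConfig(n_cardiac=1, n_resp=1, n_mod_cardiac=0,
                             n_mod_resp=0, dt=1 / fs)
        belief = nam_init_from_signal(y, cfg, sample_rate=fs)
        assert abs(belief.mean[cfg.sl_amp_r][0]) < 0.05

    def test_constant_signal_raises(self):
        cfg = HarmonicConfig(dt=0.01)
        with pytest.raises(InitializationError, match="cardiac"):
            nam_init_from_signal(np.ones(2000), cfg, sample_rate=100.0)

    def test_initialized_phases_continue_signal(self):
        trace = simulate_normal(
            20.0, 100.0,
            params=NormalParams(amp_drift=0.0, freq_drift=0.0, noise_sd=0.0,
                                mod_depth=0.0,
                                cardiac_amps=(1.0,), resp_amps=(0.5,)),
            seed=0,
        )
        cfg = HarmonicConfig(n_cardiac=1, n_resp=1, n_mod_cardiac=0,
                             n_mod_resp=0, dt=0.01)
        belief = nam_init_from_signal(trace.slice(0, 10), cfg)
        # one transition step predicts the sample right after the window
        mean, _ = nam_transition(belief.mean, cfg)
        z_next = trace.channel(0)[int(10 * 100)]
        assert nam_measure(mean, cfg) == pytest.approx(z_next, abs=0.02)


def test_without_modulation_matches_plain_ekf_oracle(rng):
    """With no modulation states the tracker is a sum-of-oscillators EKF;
    compare against a directly coded EKF using explicit matrix formulas."""
    fs = 100.0
    cfg = HarmonicConfig(n_cardiac=2, n_resp=1, n_mod_cardiac=0, n_mod_resp=0,
                         dt=1 / fs)
    noise = NamNoise(q_amp=1e-6, q_freq=1e-8, q_phase=1e-5, r_meas=1e-3)
    mean = np.zeros(cfg.dim)
    mean[cfg.sl_amp_c] = [1.0, 0.3]
    mean[cfg.sl_amp_r] = 0.5
    mean[cfg.idx_fc] = 1.2
    mean[cfg.idx_fr] = 0.25
    diag = rng.uniform(0.01, 0.1, cfg.dim)
    diag[[cfg.idx_fc, cfg.idx_fr]] = 1e-4  # keep frequencies off the floor
    P0 = np.diag(diag)
    pred = NamPredictor(cfg, noise, GaussianBelief(mean.copy(), P0.copy()))

    # independent oracle: textbook EKF with explicit inverse, no wrapping
    x = mean.copy()
    P = P0.copy()
    Q = np.diag(noise.diagonal(cfg))
    # measurements consistent with the harmonic model so the frequency
    # states stay well inside the positivity floor
    t_seq = (np.arange(1, 51)) / fs
    z_seq = (
        1.0 * np.cos(2 * np.pi * 1.2 * t_seq)
        + 0.3 * np.cos(2 * np.pi * 2.4 * t_seq)
        + 0.5 * np.cos(2 * np.pi * 0.25 * t_seq)
        + 0.05 * rng.standard_normal(50)
    )
    oracle_preds = []
    dt = cfg.dt
    for z in z_seq:
        # transition: phases advance by 2π k f dt
        A = np.eye(cfg.dim)
        xn = x.copy()
        th0 = cfg.sl_phases.start
        rates = [1 * x[cfg.idx_fc], 2 * x[cfg.idx_fc], 1 * x[cfg.idx_fr]]
        mults = [(cfg.idx_fc, 1), (cfg.idx_fc, 2), (cfg.idx_fr, 1)]
        for i, rate in enumerate(rates):
            xn[th0 + i] = x[th0 + i] + 2 * np.pi * rate * dt
            A[th0 + i, mults[i][0]] = 2 * np.pi * mults[i][1] * dt
        P = A @ P @ A.T + Q
        x = xn
        amps = x[cfg.sl_amplitudes]
        ths = x[cfg.sl_phases]
        h = x[0] + np.sum(amps * np.cos(ths))
        oracle_preds.append(h)
        H = np.zeros((1, cfg.dim))
        H[0, 0] = 1.0
        H[0, cfg.sl_amplitudes] = np.cos(ths)
        H[0, cfg.sl_phases] = -amps * np.sin(ths)
        S = H @ P @ H.T + noise.r_meas
        K = P @ H.T / S
        x = x + (K * (z - h)).ravel()
        P = P - K @ H @ P

    pred_preds = [pred.update(z)[0] for z in z_seq]
    np.testing.assert_allclose(pred_preds, oracle_preds, atol=1e-9)
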