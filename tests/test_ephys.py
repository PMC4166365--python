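"""Ephys chain: PSTH, sharp events, gamma filtering, phases, circular stats."""

import numpy as np
import pytest

from gammasnap.ephys import (
    SharpEvent,
    analyze_session,
    bandpass_gamma,
    bootstrap_population_phase,
    circular_mean_Z,
    detect_sharp_events,
    instantaneous_phase,
    make_synthetic_session,
    psth,
    read_session,
    sharp_event_onset,
    write_session,
)


class TestPsth:
    def test_homogeneous_poisson_recovers_rate(self):
        rng = np.random.default_rng(0)
        trials = [np.sort(rng.uniform(-2, 2, rng.poisson(80)))
                  for _ in range(100)]
        _, rates = psth(trials)
        assert rates.mean() == pytest.approx(20.0, rel=0.05)

    def test_no_spikes_gives_zero_psth(self):
        _, rates = psth([np.array([])] * 3)
        assert not rates.any()

    def test_single_spike_single_trial_bin_value(self):
        centers, rates = psth([np.array([0.105])])
        k = np.argmin(np.abs(centers - 0.105))
        assert rates[k] == pytest.approx(100.0)  # 1 spike / 10 ms bin

    def test_empty_trial_list_rejected(self):
        with pytest.raises(ValueError):
            psth([])


class TestDetectSharpEvents:
    def _flat_psth(self, peak_height=None, peak_at=0.5):
        centers = np.arange(-2.0, 2.0, 0.01) + 0.005
        rng = np.random.default_rng(1)
        rates = 10.0 + rng.normal(0, 1.0, centers.size)
        if peak_height is not None:
            rates[np.argmin(np.abs(centers - peak_at))] += peak_height
        return centers, rates

    def test_flat_psth_has_no_events(self):
        centers, rates = self._flat_psth()
        assert detect_sharp_events(centers, rates) == []

    def test_six_sigma_burst_detected_once_at_burst_bin(self):
        centers, rates = self._flat_psth(peak_height=None)
        sd = np.std(rates[centers < 0])
        mu = np.mean(rates[centers < 0])
        k = np.argmin(np.abs(centers - 0.5))
        rates[k] = mu + 6.0 * sd
        events = detect_sharp_events(centers, rates)
        assert len(events) == 1
        assert events[0].peak_time == pytest.approx(centers[k])

    def test_four_sigma_burst_rejected(self):
        centers, rates = self._flat_psth()
        sd = np.std(rates[centers < 0])
        mu = np.mean(rates[centers < 0])
        rates[np.argmin(np.abs(centers - 0.5))] = mu + 4.0 * sd
        assert detect_sharp_events(centers, rates) == []

    def test_silent_baseline_uses_sd_floor(self):
        centers = np.arange(-2.0, 2.0, 0.01) + 0.005
        rates = np.zeros(centers.size)
        rates[centers > 0.5] = 0.2  # just under floor * 4.5
        assert detect_sharp_events(centers, rates) == []
        rates[np.argmin(np.abs(centers - 0.5))] = 10.0
        assert len(detect_sharp_events(centers, rates)) == 1


class TestSharpEventOnset:
    def test_derived_window_and_threshold(self):
        ev = SharpEvent(peak_time=1.0, max_fr=200.0)
        assert ev.isi_threshold == pytest.approx(0.0075)
        assert ev.search_window == (pytest.approx(0.99), pytest.approx(1.02))

    def test_single_spike_yields_none(self):
        ev = SharpEvent(peak_time=1.0, max_fr=200.0)
        assert sharp_event_onset(np.array([1.0]), ev) is None

    def test_first_subthreshold_isi_marks_onset(self):
        # ISIs of 12, 6, 5 ms against a 7.5 ms threshold: onset precedes 6 ms
        ev = SharpEvent(peak_time=0.02, max_fr=200.0)
        spikes = np.array([0.010, 0.022, 0.028, 0.033])
        assert sharp_event_onset(spikes, ev) == pytest.approx(0.022)


class TestBandpassGamma:
    fs = 1000.0

    def test_passband_sinusoid_preserved_with_zero_lag(self):
        t = np.arange(0, 2, 1 / self.fs)
        x = np.cos(2 * np.pi * 60 * t)
        y = bandpass_gamma(x, self.fs)
        core = slice(200, -200)
        gain = np.dot(y[core], x[core]) / np.dot(x[core], x[core])
        assert gain == pytest.approx(1.0, abs=0.05)
        lags = np.arange(-5, 6)
        xc = [np.dot(y[core], np.roll(x, k)[core]) for k in lags]
        assert lags[np.argmax(xc)] == 0

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(0, 2, 1 / self.fs)
        x = np.cos(2 * np.pi * 10 * t)
        y = bandpass_gamma(x, self.fs)
        atten = 20 * np.log10(np.std(y[500:-500]) / np.std(x[500:-500]))
        assert atten < -20.0

    def test_zero_phase_symmetry_under_time_reversal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2048)
        fwd = bandpass_gamma(x, self.fs)
        rev = bandpass_gamma(x[::-1], self.fs)[::-1]
        # identical away from the boundary padding
        assert np.allclose(fwd[200:-200], rev[200:-200], atol=1e-6)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_gamma(np.zeros(100), fs=100.0, band=(40.0, 80.0))


class TestInstantaneousPhase:
    fs = 1000.0

    def _sinusoid(self):
        t = np.arange(0, 1, 1 / self.fs)
        return t, np.cos(2 * np.pi * 60 * t)

    def test_zero_phase_at_positive_peak(self):
        t, s = self._sinusoid()
        t_peak = 6 / 60.0  # exact cycle multiple: cos at maximum
        th = instantaneous_phase(s, t, t_peak, (t_peak - 0.05, t_peak + 0.05))
        assert abs(th) < 0.1

    def test_phase_advances_linearly_on_sinusoid(self):
        t, s = self._sinusoid()
        t0 = 0.4
        offsets = np.linspace(0, 1 / 60.0, 12, endpoint=False)
        est = np.array([
            instantaneous_phase(s, t, t0 + dt, (0.3, 0.6)) for dt in offsets])
        # estimator convention: theta = -omega * t (phase 0 at the peak)
        expected = -2 * np.pi * 60 * (t0 + offsets)
        err = np.angle(np.exp(1j * (est - expected)))
        assert np.abs(err).max() < 0.25

    def test_spike_outside_window_rejected(self):
        t, s = self._sinusoid()
        with pytest.raises(ValueError):
            instantaneous_phase(s, t, 0.9, (0.1, 0.2))

    def test_zero_variance_window_rejected(self):
        t = np.arange(0, 1, 1 / self.fs)
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros_like(t), t, 0.5, (0.4, 0.6))


class TestCircularMeanZ:
    def test_coherent_phases(self):
        z = circular_mean_Z([1.2] * 9)
        assert abs(z) == pytest.approx(1.0)
        assert np.angle(z) == pytest.approx(1.2)

    def test_uniform_phases_cancel(self):
        th = np.random.default_rng(4).uniform(-np.pi, np.pi, 100_000)
        assert abs(circular_mean_Z(th)) < 0.02

    def test_antipodal_pair_cancels(self):
        assert abs(circular_mean_Z([0.0, np.pi])) == pytest.approx(0.0, abs=1e-12)

    def test_axial_option_doubles_angles(self):
        # antipodal pair is perfectly concentrated as axial data
        z = circular_mean_Z([0.0, np.pi], axial=True)
        assert abs(z) == pytest.approx(1.0)


class TestBootstrapPopulationPhase:
    def test_identical_z_values_give_p_zero(self):
        z = [np.exp(1j * 0.7)] * 10
        mean_phase, p = bootstrap_population_phase(z, reps=2000, seed=0)
        assert mean_phase == pytest.approx(0.7)
        assert p == 0.0

    def test_scattered_angles_give_large_p(self):
        rng = np.random.default_rng(5)
        angles = rng.uniform(-np.pi, np.pi, 24)
        z = 0.6 * np.exp(1j * angles)
        _, p = bootstrap_population_phase(z, reps=4000, seed=1)
        assert p > 0.05

    def test_concentrated_population_significant_at_large_n(self):
        rng = np.random.default_rng(6)
        angles = rng.vonmises(-2.3, 5.0, 218)
        z = 0.7 * np.exp(1j * angles)
        mean_phase, p = bootstrap_population_phase(z, reps=10000, seed=2)
        assert p < 1e-3
        assert abs(np.angle(np.exp(1j * (mean_phase + 2.3)))) < 0.3

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_population_phase([1 + 0j], seed=0)


class TestSyntheticSessionRecovery:
    def test_injected_phase_recovered_within_tolerance(self):
        errs = []
        for seed in range(12):
            session = make_synthetic_session(lock_phase=-2.3,
                                             lock_concentration=5.0,
                                             n_trials=25, seed=seed)
            res = analyze_session(session)
            errs.append(np.angle(np.exp(1j * (res.mean_phase + 2.3))))
        assert abs(np.mean(errs)) < 0.3

    def test_no_locking_gives_weak_synchronization(self):
        strengths = []
        for seed in range(6):
            session = make_synthetic_session(lock_concentration=0.0,
                                             n_trials=25, seed=seed)
            strengths.append(analyze_session(session).strength)
        locked = analyze_session(
            make_synthetic_session(lock_concentration=8.0, n_trials=25, seed=99))
        assert np.mean(strengths) < locked.strength

    def test_locking_strength_monotone_in_concentration(self):
        mean_strength = {}
        for kappa in (0.0, 2.0, 10.0):
            vals = [
                analyze_session(make_synthetic_session(
                    lock_concentration=kappa, n_trials=25, seed=s)).strength
                for s in range(6)]
            mean_strength[kappa] = np.mean(vals)
        assert mean_strength[0.0] < mean_strength[2.0] < mean_strength[10.0]

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_session(n_trials=0, seed=0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_session(lock_concentration=-1.0, seed=0)


def test_session_roundtrip_csv(tmp_path):
    session = make_synthetic_session(n_trials=4, seed=3)
    write_session(session, tmp_path / "spikes.csv", tmp_path / "lfp.csv")
    back = read_session(tmp_path / "spikes.csv", tmp_path / "lfp.csv")
    assert back.n_trials == session.n_trials
    assert back.fs == session.fs
    for a, b in zip(back.trials, session.trials):
        assert np.allclose(a, b)
    assert np.allclose(back.lfp, session.lfp)
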