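"""Single-voxel VSD trace processing: filters, baseline, noise, alpha fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from spinevolt import vsd
from spinevolt.traces import OpticalTrace

DT = 0.02  # ms (50 kHz)


def make_trace(samples, dt=DT, **kw):
    return OpticalTrace(np.asarray(samples, float), dt=dt, **kw)


# ---------------------------------------------------------------------------
# artifact removal
# ---------------------------------------------------------------------------

class TestArtifactRemoval:
    def test_zero_length_window_is_identity(self):
        tr = make_trace(np.sin(np.arange(500) * 0.1))
        out = vsd.remove_uncaging_artifact(tr, (10.0, 10.0))
        assert np.allclose(out.samples, tr.samples)

    def test_spike_on_constant_removed(self):
        x = np.full(1000, 5.0)
        x[500:510] = 99.0
        tr = make_trace(x)
        out = vsd.remove_uncaging_artifact(tr, (500 * DT, 510 * DT))
        assert np.allclose(out.samples, 5.0)

    def test_linear_ramp_restored_exactly(self):
        t = np.arange(1000) * DT
        ramp = 2.0 + 0.3 * t
        x = ramp.copy()
        x[400:425] += 50.0
        out = vsd.remove_uncaging_artifact(make_trace(x), (400 * DT, 425 * DT))
        assert np.allclose(out.samples, ramp, atol=1e-12)

    def test_window_outside_trace_raises(self):
        with pytest.raises(ValueError):
            vsd.remove_uncaging_artifact(make_trace(np.zeros(100)), (5.0, 100.0))


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------

class TestEpspFilter:
    def test_unit_dc_gain_on_constant(self):
        out = vsd.lowpass_epsp(make_trace(np.full(5000, 3.7)))
        assert np.allclose(out.samples, 3.7, atol=1e-9)

    def test_transient_peak_and_onset_preserved(self):
        """A 12 ms FWHM alpha transient loses <5% peak and its onset moves
        by less than 1.5 ms through the chain."""
        t = np.arange(0, 120, DT)
        k1, k2 = vsd.rates_for_fwhm(12.0)
        w = vsd.alpha_waveform(t - 40.0, 1.0, k1, k2)
        w /= w.max()
        out = vsd.lowpass_epsp(make_trace(w)).samples
        assert out.max() > 0.95
        onset_true = t[np.argmax(w > 0.05)]
        onset_filt = t[np.argmax(out > 0.05)]
        assert abs(onset_filt - onset_true) < 1.5

    def test_white_noise_sd_matches_fft_oracle(self):
        """Post-chain noise SD agrees with the frequency-domain prediction
        from the chain's transfer function within 5%."""
        rng = np.random.default_rng(7)
        reps = [
            vsd.lowpass_epsp(make_trace(rng.standard_normal(60000))).samples[3000:-3000].std()
            for _ in range(6)
        ]
        # oracle: |H(f)|^2 integral via FFT of the impulse response
        n = 1 << 15
        imp = np.zeros(n)
        imp[n // 2] = 1.0
        h = vsd.lowpass_epsp(make_trace(imp)).samples
        pred = np.sqrt(np.mean(np.abs(np.fft.fft(h)) ** 2))
        assert np.mean(reps) == pytest.approx(pred, rel=0.05)

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError):
            vsd.lowpass_epsp(make_trace(np.zeros(10)))


class TestBapFilter:
    def test_zero_phase_on_symmetric_pulse(self):
        t = np.arange(0, 50, DT)
        pulse = np.exp(-0.5 * ((t - 25) / 1.5) ** 2)
        out = vsd.lowpass_bap(make_trace(pulse)).samples
        assert abs(t[np.argmax(out)] - 25.0) <= DT

    def test_constant_passes(self):
        out = vsd.lowpass_bap(make_trace(np.full(4000, -1.5)))
        assert np.allclose(out.samples, -1.5, atol=1e-9)

    def test_amplitude_response_is_squared_single_pass(self):
        """Forward–backward filtering has |H|² magnitude response (FFT
        oracle on a chirp, within 2% over the passband)."""
        t = np.arange(0, 200, DT)
        x = signal.chirp(t, f0=0.01, f1=2.0, t1=200.0)  # kHz since t in ms
        y = vsd.lowpass_bap(make_trace(x)).samples
        sos = signal.cheby1(5, 0.5, 1.0 / (0.5 / DT), btype="low", output="sos")
        w, h = signal.sosfreqz(sos, worN=4096)
        f_khz = w / np.pi * (0.5 / DT)
        X = np.fft.rfft(x * np.hanning(x.size))
        Y = np.fft.rfft(y * np.hanning(x.size))
        freqs = np.fft.rfftfreq(x.size, DT)
        band = (freqs > 0.05) & (freqs < 0.8)
        emp = np.abs(Y[band]) / np.abs(X[band])
        pred = np.interp(freqs[band], f_khz, np.abs(h) ** 2)
        assert np.median(np.abs(emp - pred) / pred) < 0.02


# ---------------------------------------------------------------------------
# baseline model
# ---------------------------------------------------------------------------

class TestBleachFit:
    def test_exact_model_recovered(self):
        t = np.arange(0, 120, DT)
        model = vsd.BleachModel(f0=1000.0, a_on=0.04, tau_on=15.0,
                                a_bl=0.08, tau_bl=400.0)
        tr = make_trace(model(t))
        fit = vsd.fit_bleach(tr)
        resid = np.linalg.norm(tr.samples - fit(t))
        assert resid < 1e-6 * np.linalg.norm(tr.samples)

    def test_flat_trace_amplitudes_vanish(self):
        fit = vsd.fit_bleach(make_trace(np.full(4000, 800.0)))
        assert abs(fit(np.array([0.0]))[0] - 800.0) < 1e-3
        span = fit(np.arange(0, 80, DT))
        assert np.ptp(span) < 1e-3

    def test_transient_survives_subtraction(self):
        """Fitting the baseline with the response window excluded and
        subtracting preserves an injected alpha transient within 5%."""
        t = np.arange(0, 120, DT)
        base = vsd.BleachModel(f0=1000.0, a_on=0.04, tau_on=15.0,
                               a_bl=0.08, tau_bl=400.0)(t)
        k1, k2 = vsd.rates_for_fwhm(12.0)
        dff = 3.0 * vsd.alpha_waveform(t - 40.0, 1.0, k1, k2) / vsd.AlphaFit(
            K=1.0, k1=k1, k2=k2).amplitude
        tr = make_trace(base * (1 + dff / 100.0))
        fit = vsd.fit_bleach(tr, exclude_window=(40.0, 100.0))
        recovered = vsd.subtract_bleach(tr, fit)
        assert recovered.samples.max() == pytest.approx(3.0, rel=0.05)


# ---------------------------------------------------------------------------
# noise estimate
# ---------------------------------------------------------------------------

class TestNoiseEstimate:
    def test_zero_trace(self):
        est = vsd.estimate_noise(make_trace(np.zeros(2000)))
        assert est.sigma == 0.0 and est.threshold == 0.0

    def test_threshold_is_exactly_2p5_sigma(self):
        est = vsd.NoiseEstimate(sigma=0.444)
        assert est.threshold == 2.5 * 0.444

    def test_known_filtered_noise_level(self):
        """Filtered white noise scaled to a 0.63% windowed SD is estimated
        within 10% (Monte-Carlo over seeds)."""
        gain = vsd.filter_noise_gain(DT, window_ms=5.0)
        rng = np.random.default_rng(0)
        est = []
        for _ in range(10):
            x = (0.63 / gain) * rng.standard_normal(30000)
            f = vsd.lowpass_epsp(make_trace(x))
            est.append(vsd.estimate_noise(f).sigma)
        assert np.mean(est) == pytest.approx(0.63, rel=0.10)

    def test_median_robust_to_sparse_transient(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20000)
        clean = vsd.estimate_noise(vsd.lowpass_epsp(make_trace(x)))
        x2 = x.copy()
        x2[10000:10600] += 40.0  # transient in <10% of windows
        dirty = vsd.estimate_noise(vsd.lowpass_epsp(make_trace(x2)))
        assert dirty.sigma == pytest.approx(clean.sigma, rel=0.15)

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            vsd.estimate_noise(make_trace(np.zeros(10)))


# ---------------------------------------------------------------------------
# alpha-like fit
# ---------------------------------------------------------------------------

class TestAlphaFit:
    def test_closed_form_peak_and_amplitude(self):
        fit = vsd.AlphaFit(K=10.0, k1=1.0, k2=0.1)
        assert fit.t_peak == pytest.approx(np.log(10.0) / 0.9, abs=1e-12)
        assert fit.amplitude == pytest.approx(6.9684, abs=5e-4)

    @settings(max_examples=60, deadline=None)
    @given(K=st.floats(0.5, 50), k2=st.floats(0.02, 0.5),
           ratio=st.floats(1.5, 40))
    def test_amplitude_and_fwhm_match_dense_grid(self, K, k2, ratio):
        """Closed-form amplitude and root-found FWHM agree with brute-force
        evaluation of the waveform on a dense grid to 1e-6 relative."""
        k1 = k2 * ratio
        fit = vsd.AlphaFit(K=K, k1=k1, k2=k2)
        t = np.linspace(0, 40 * fit.t_peak, 400000)
        y = vsd.alpha_waveform(t, K, k1, k2)
        assert fit.amplitude == pytest.approx(y.max(), rel=1e-6)
        above = t[y >= 0.5 * y.max()]
        assert fit.fwhm == pytest.approx(above[-1] - above[0], rel=1e-3)

    def test_degenerate_equal_rates_limit(self):
        k = 0.2
        t = np.linspace(0, 50, 1000)
        lim = vsd.alpha_waveform(t, 2.0, k + 4e-7, k - 4e-7)
        exact = 2.0 * k * t * np.exp(-k * t)
        assert np.allclose(lim, exact, rtol=1e-4)

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            vsd.AlphaFit(K=1.0, k1=0.1, k2=1.0)


class TestDetectAndFit:
    def _dff_trace(self, amp, sigma, seed, fwhm=12.0, n_ms=120.0, t0=40.0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, n_ms, DT)
        k1, k2 = vsd.rates_for_fwhm(fwhm)
        ref = vsd.AlphaFit(K=1.0, k1=k1, k2=k2)
        clean = amp * vsd.alpha_waveform(t - t0, 1.0, k1, k2) / ref.amplitude
        gain = vsd.filter_noise_gain(DT, window_ms=5.0)
        noise = (sigma / gain) * rng.standard_normal(t.size) if sigma else 0.0
        tr = vsd.lowpass_epsp(make_trace(clean + noise, uncaging_time=t0))
        return tr.with_samples(tr.samples, units="pct_dff")

    def test_zero_amplitude_reports_limit(self):
        tr = self._dff_trace(0.0, 0.2, seed=3)
        noise = vsd.estimate_noise(tr)
        det = vsd.detect_and_fit(tr, noise, uncaging_time=40.0)
        assert not det.detected
        assert det.limit_dff == noise.threshold == 2.5 * noise.sigma

    def test_strong_transient_always_detected_and_recovered(self):
        """Amplitude 4× threshold: detected on every seed, with the median
        amplitude error small (the tight Monte-Carlo bound over 100 traces
        lives in the acceptance suite)."""
        kernel = vsd.chain_impulse_response(DT)
        errs = []
        for seed in range(12):
            sigma = 0.2
            amp = 4 * 2.5 * sigma
            tr = self._dff_trace(amp, sigma, seed=seed)
            det = vsd.detect_and_fit(tr, vsd.NoiseEstimate(sigma), uncaging_time=40.0,
                                     filter_kernel=kernel)
            assert det.detected
            errs.append(det.fit.amplitude / amp - 1)
        assert abs(np.median(errs)) < 0.1

    def test_filter_aware_fit_is_exact_on_noiseless_data(self):
        """With the chain kernel supplied, fitting the filtered transient
        returns the unfiltered amplitude and FWHM exactly."""
        kernel = vsd.chain_impulse_response(DT)
        amp = 2.0
        tr = self._dff_trace(amp, 0.0, seed=0)
        det = vsd.detect_and_fit(tr, vsd.NoiseEstimate(1e-6), uncaging_time=40.0,
                                 filter_kernel=kernel)
        assert det.fit.amplitude == pytest.approx(amp, rel=1e-4)
        assert det.fit.fwhm == pytest.approx(12.0, rel=1e-3)

    def test_detection_monotone_in_amplitude(self):
        """At fixed noise and seed, detection never flips back to
        below-threshold as the true amplitude grows."""
        sigma = 0.25
        states = []
        for amp in np.linspace(0, 3.0, 13):
            tr = self._dff_trace(amp, sigma, seed=11)
            det = vsd.detect_and_fit(tr, vsd.NoiseEstimate(sigma), uncaging_time=40.0)
            states.append(det.detected)
        first_true = states.index(True) if True in states else len(states)
        assert all(states[first_true:])


class TestSpikeTriggeredAverage:
    def _bap(self, t, ts):
        return np.exp(-0.5 * ((t - ts) / 0.8) ** 2)

    def test_identical_trials_with_shifts_recover_waveform(self):
        t = np.arange(0, 50, DT)
        shifts = [-1.0, 0.0, 1.4]
        trials = [make_trace(self._bap(t, 25 + s)) for s in shifts]
        avg = vsd.spike_triggered_average(trials, [25 + s for s in shifts])
        ref = self._bap(t, 25.0)
        core = slice(500, -500)
        assert np.allclose(avg.samples[core], ref[core], atol=1e-6)

    def test_single_trial_identity(self):
        t = np.arange(0, 50, DT)
        tr = make_trace(self._bap(t, 25.0))
        avg = vsd.spike_triggered_average([tr], [25.0])
        assert np.allclose(avg.samples, tr.samples)

    def test_beats_naive_average_under_jitter(self):
        """With 1 ms spike-time jitter, aligned averaging preserves ≥97% of
        the true peak while naive averaging loses ≥10%."""
        rng = np.random.default_rng(5)
        t = np.arange(0, 50, DT)
        trials, times = [], []
        for _ in range(30):
            ts = 25.0 + rng.normal(0, 1.0)
            trials.append(make_trace(self._bap(t, ts) + 0.02 * rng.standard_normal(t.size)))
            times.append(ts)
        sta = vsd.spike_triggered_average(trials, times)
        naive = np.mean([tr.samples for tr in trials], axis=0)
        assert sta.samples.max() >= 0.97
        assert naive.max() <= 0.90
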