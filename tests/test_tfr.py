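"""Morlet decomposition, ITPC and baseline normalization."""

import numpy as np
import pytest

from assr.tfr import (
    MorletSpec,
    TFMap,
    compute_itpc,
    itpc_from_epochs,
    morlet_kernel,
    morlet_transform,
    normalize_percent_change,
    window_average,
)


def measured_fwhm_s(freq_hz, spec, fs):
    """Envelope FWHM read off the sampled kernel, half-max crossings
    located by linear interpolation."""
    kernel = morlet_kernel(freq_hz, spec, fs)
    env = np.abs(kernel)
    t = (np.arange(len(kernel)) - (len(kernel) - 1) // 2) / fs
    half = env.max() / 2.0
    above = np.flatnonzero(env >= half)
    lo, hi = above[0], above[-1]

    def cross(i, j):
        return t[i] + (half - env[i]) * (t[j] - t[i]) / (env[j] - env[i])

    return cross(hi, hi + 1) - cross(lo, lo - 1)


def brute_force_itpc(coeffs):
    """Independent loop-based resultant length across trials."""
    n_trials, n_vertices, n_freqs, n_times = coeffs.shape
    out = np.zeros((n_vertices, n_freqs, n_times))
    for v in range(n_vertices):
        for f in range(n_freqs):
            for s in range(n_times):
                acc = 0j
                for r in range(n_trials):
                    c = coeffs[r, v, f, s]
                    acc += c / abs(c)
                out[v, f, s] = abs(acc) / n_trials
    return out


class FakeEpochs:
    def __init__(self, data, times_s):
        self.data = data
        self.times_s = times_s


def _sine_epochs(freq=40.0, fs=500.0, n_trials=3, phase=0.0, amp=1.0):
    times = np.arange(-750, 751) / fs
    x = amp * np.cos(2 * np.pi * freq * times + phase)
    data = np.tile(x, (n_trials, 1, 1))
    return FakeEpochs(data, times)


class TestMorletKernel:
    @pytest.mark.parametrize("fs", [500.0, 1000.0])
    def test_envelope_fwhm_is_time_resolution(self, fs):
        assert measured_fwhm_s(40.0, MorletSpec(), fs) == pytest.approx(0.3, abs=1.0 / fs)

    def test_envelope_scales_inversely_with_frequency(self):
        spec = MorletSpec()
        assert measured_fwhm_s(35.0, spec, 1000.0) == pytest.approx(0.3 * 40 / 35, abs=2e-3)
        assert measured_fwhm_s(45.0, spec, 1000.0) == pytest.approx(0.3 * 40 / 45, abs=2e-3)

    def test_kernel_energy_normalized(self):
        k = morlet_kernel(40.0, MorletSpec(), 500.0)
        assert np.sum(np.abs(k) ** 2) == pytest.approx(1.0, rel=1e-12)


class TestMorletTransform:
    def test_stationary_sinusoid_has_constant_demodulated_phase(self):
        # coefficient phase is the instantaneous phase 2*pi*f*t + phi;
        # after demodulating the carrier it is constant over the interior
        epochs = _sine_epochs()
        coeffs = morlet_transform(epochs, MorletSpec())
        f40 = np.argmin(np.abs(MorletSpec().freq_grid_hz - 40.0))
        interior = slice(300, 1200)
        t = epochs.times_s[interior]
        demod = np.unwrap(np.angle(coeffs[0, 0, f40, interior])) - 2 * np.pi * 40.0 * t
        assert np.ptp(demod) < 1e-6

    def test_linearity_in_amplitude(self):
        base = _sine_epochs(amp=1.0)
        scaled = FakeEpochs(3.0 * base.data, base.times_s)
        c1 = morlet_transform(base, MorletSpec())
        c2 = morlet_transform(scaled, MorletSpec())
        np.testing.assert_allclose(np.abs(c2), 3.0 * np.abs(c1), rtol=1e-10)
        np.testing.assert_allclose(np.angle(c2), np.angle(c1), atol=1e-10)

    def test_supra_nyquist_grid_rejected(self):
        epochs = _sine_epochs(fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_transform(epochs, MorletSpec(freq_grid_hz=np.array([40.0, 60.0])))


class TestComputeItpc:
    def test_aligned_phases_give_one(self):
        coeffs = np.full((5, 2, 3, 4), 2.0 * np.exp(1j * 0.7))
        tf = compute_itpc(coeffs, np.arange(3.0) + 1, np.arange(4.0))
        np.testing.assert_allclose(tf.values, 1.0, atol=1e-12)

    def test_symmetric_phases_cancel(self):
        phases = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        coeffs = np.exp(1j * phases).reshape(3, 1, 1, 1)
        tf = compute_itpc(coeffs, np.array([1.0]), np.array([0.0]))
        assert tf.values[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_two_orthogonal_phases(self):
        coeffs = np.array([1.0 + 0j, 1j]).reshape(2, 1, 1, 1)
        tf = compute_itpc(coeffs, np.array([1.0]), np.array([0.0]))
        assert tf.values[0, 0, 0] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        coeffs = rng.normal(size=(7, 2, 3, 5)) + 1j * rng.normal(size=(7, 2, 3, 5))
        tf = compute_itpc(coeffs, np.arange(3.0) + 1, np.arange(5.0))
        np.testing.assert_allclose(tf.values, brute_force_itpc(coeffs), atol=1e-12)

    def test_invariant_to_per_trial_amplitude_scaling(self, rng):
        coeffs = rng.normal(size=(6, 2, 2, 4)) + 1j * rng.normal(size=(6, 2, 2, 4))
        gains = rng.uniform(0.1, 10, size=(6, 1, 1, 1))
        a = compute_itpc(coeffs, np.arange(2.0) + 1, np.arange(4.0))
        b = compute_itpc(gains * coeffs, np.arange(2.0) + 1, np.arange(4.0))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_uniform_phases_match_closed_form(self, rng):
        n = 40
        phases = rng.uniform(0, 2 * np.pi, size=(n, 1, 1, 2000))
        tf = compute_itpc(np.exp(1j * phases), np.array([1.0]), np.arange(2000.0))
        assert tf.values.mean() == pytest.approx(np.sqrt(np.pi / (4 * n)), rel=0.02)

    def test_zero_coefficient_policy(self):
        coeffs = np.ones((3, 1, 1, 2), dtype=complex)
        coeffs[0, 0, 0, 0] = 0.0
        with pytest.raises(ValueError, match="undefined phase"):
            compute_itpc(coeffs, np.array([1.0]), np.arange(2.0))
        tf = compute_itpc(coeffs, np.array([1.0]), np.arange(2.0), on_zero="exclude")
        np.testing.assert_allclose(tf.values, 1.0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="2 trials"):
            compute_itpc(np.ones((1, 1, 1, 1), dtype=complex), np.array([1.0]), np.array([0.0]))


class TestFusedPath:
    def test_fused_itpc_equals_reference_path(self, one_subject):
        subject, _ = one_subject
        spec = MorletSpec(freq_grid_hz=np.arange(38.0, 43.0))
        coeffs = morlet_transform(subject, spec)
        ref = compute_itpc(coeffs, spec.freq_grid_hz, subject.times_s, spec=spec)
        fused = itpc_from_epochs(subject, spec)
        np.testing.assert_allclose(fused.values, ref.values, atol=1e-12)

    def test_single_precision_close_to_double(self, one_subject):
        subject, _ = one_subject
        spec = MorletSpec(freq_grid_hz=np.arange(38.0, 43.0))
        double = itpc_from_epochs(subject, spec)
        single = itpc_from_epochs(subject, spec, single_precision=True)
        np.testing.assert_allclose(single.values, double.values, atol=1e-4)


def _map(values, freqs, times, kind="raw_itpc", n_trials=10):
    return TFMap(values=values, freqs_hz=freqs, times_s=times, kind=kind, n_trials=n_trials)


class TestNormalization:
    times = np.linspace(-1.0, 1.0, 201)
    freqs = np.array([39.0, 40.0, 41.0])

    def test_constant_map_normalizes_to_zero(self):
        tf = _map(np.full((2, 3, 201), 0.25), self.freqs, self.times)
        out = normalize_percent_change(tf)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)
        assert out.kind == "normalized_itpc"

    def test_doubling_is_plus_hundred_percent(self):
        values = np.full((1, 3, 201), 0.3)
        values[:, :, self.times > 0] = 0.6
        out = normalize_percent_change(_map(values, self.freqs, self.times))
        np.testing.assert_allclose(out.values[:, :, self.times > 0], 100.0, atol=1e-10)

    def test_arithmetic_example(self):
        # baseline samples all 2, in-window value 3 -> 50%
        times = np.array([-0.4, -0.3, -0.25, 0.5])
        values = np.array([[[2.0, 2.0, 2.0, 3.0]]])
        out = normalize_percent_change(
            TFMap(values, np.array([40.0]), times, "normalized_itpc", 5)
        )
        assert out.values[0, 0, -1] == pytest.approx(50.0)

    def test_zero_baseline_raises_with_location(self):
        values = np.full((2, 3, 201), 0.2)
        values[1, 2, self.times <= -0.2] = 0.0
        with pytest.raises(ValueError, match="vertex 1.*41"):
            normalize_percent_change(_map(values, self.freqs, self.times))


class TestWindowAverage:
    times = np.linspace(-1.0, 1.0, 201)
    freqs = np.arange(35.0, 46.0)

    def test_constant_map_returns_constant(self):
        tf = _map(np.full((3, 11, 201), 0.7), self.freqs, self.times)
        np.testing.assert_allclose(window_average(tf), 0.7, atol=1e-12)

    def test_default_band_selects_three_bins(self):
        values = np.zeros((1, 11, 201))
        band = (self.freqs >= 39) & (self.freqs <= 41)
        assert band.sum() == 3
        values[0, band, :] = 1.0
        tf = _map(values, self.freqs, self.times)
        assert window_average(tf)[0] == pytest.approx(1.0)

    def test_empty_selection_rejected(self):
        tf = _map(np.zeros((1, 11, 201)), self.freqs, self.times)
        with pytest.raises(ValueError, match="empty"):
            window_average(tf, freq_band_hz=(100.0, 110.0))

    def test_edge_contaminated_window_rejected(self, one_subject):
        subject, _ = one_subject
        tf = itpc_from_epochs(subject, MorletSpec())
        with pytest.raises(ValueError, match="edge"):
            window_average(tf, time_window_s=(1.0, 1.5))

    def test_normalize_then_average_order_matters_iff_baselines_differ(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0.1, 0.9, size=(2, 3, 201))
        tf = _map(values, np.array([39.0, 40.0, 41.0]), self.times)
        norm_first = window_average(normalize_percent_change(tf))

        # averaging the raw map over the band first, then normalizing
        band_avg = values.mean(axis=1, keepdims=True)
        tf_avg = _map(band_avg, np.array([40.0]), self.times)
        avg_first = window_average(normalize_percent_change(tf_avg))
        assert not np.allclose(norm_first, avg_first, atol=1e-6)

        # equal baseline means across frequencies: the two orders agree
        base = values[:, :1, :].copy()
        eq = np.concatenate([base, base + 0.0, base + 0.0], axis=1)
        tf_eq = _map(eq, np.array([39.0, 40.0, 41.0]), self.times)
        a = window_average(normalize_percent_change(tf_eq))
        tf_eq_avg = _map(eq.mean(axis=1, keepdims=True), np.array([40.0]), self.times)
        b = window_average(normalize_percent_change(tf_eq_avg))
        np.testing.assert_allclose(a, b, atol=1e-9)
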