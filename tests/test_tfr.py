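import numpy as np
import pytest
from scipy.signal import convolve

from tfspm.tfr import (TFStack, WaveletError, WaveletParams, crop,
                       log_baseline_correct, morlet_kernel, tf_power)

FS = 1000.0


class TestKernel:
    def test_sigma_closed_form(self):
        """sigma_t = n_cycles / (2 pi f): 7 cycles at 100 Hz ~ 11.14 ms."""
        p = WaveletParams(fs_hz=FS)
        w = morlet_kernel(100.0, p)
        sigma_expected = 7.0 / (2 * np.pi * 100.0)
        assert len(w) == 2 * int(np.ceil(5 * sigma_expected * FS)) + 1
        env = np.abs(w)  # Gaussian with scale sigma_t (weight by env itself)
        t = (np.arange(len(w)) - len(w) // 2) / FS
        sigma_fit = np.sqrt((env * t ** 2).sum() / env.sum())
        assert abs(sigma_fit - sigma_expected) / sigma_expected < 0.01

    @pytest.mark.parametrize("f", [4.0, 50.0, 121.0, 299.0])
    def test_unit_energy_and_near_zero_mean(self, f):
        w = morlet_kernel(f, WaveletParams(fs_hz=FS))
        assert np.sum(np.abs(w) ** 2) / FS == pytest.approx(1.0, rel=1e-12)
        assert np.abs(w.sum()) < 1e-3 * np.abs(w).sum()

    def test_nyquist_rejected(self):
        with pytest.raises(WaveletError):
            morlet_kernel(500.0, WaveletParams(fs_hz=FS))
        with pytest.raises(WaveletError):
            WaveletParams(freqs_hz=np.array([600.0]), fs_hz=FS)


class TestPower:
    def test_pure_sine_peaks_at_its_frequency(self):
        t = np.arange(3001) / FS
        x = np.sin(2 * np.pi * 50 * t)
        p = WaveletParams(freqs_hz=np.arange(4.0, 301.0, 2.0), fs_hz=FS)
        st = tf_power(x[None, None, :], -1000.0, p)
        avg = st.data[0, 0].mean(axis=1)
        assert st.freqs_hz[np.argmax(avg)] == 50.0

    def test_zero_signal_and_quadratic_scaling(self):
        p = WaveletParams(freqs_hz=np.array([40.0, 80.0]), fs_hz=FS)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 1, 900))
        assert not tf_power(np.zeros_like(x), 0.0, p).data.any()
        a = tf_power(x, 0.0, p).data
        b = tf_power(3.0 * x, 0.0, p).data
        assert np.allclose(b, 9.0 * a, rtol=1e-10)

    def test_matches_direct_convolution_oracle(self):
        """FFT path equals direct time-domain convolution to ~1e-10."""
        rng = np.random.default_rng(1)
        p = WaveletParams(freqs_hz=np.array([20.0, 121.0]), fs_hz=FS)
        x = rng.standard_normal(1200)
        st = tf_power(x[None, None, :], 0.0, p)
        for j, f in enumerate(p.freqs_hz):
            w = morlet_kernel(f, p)
            ref = np.abs(convolve(x, w, mode="same", method="direct") / FS) ** 2
            err = np.abs(st.data[0, 0, j] - ref).max() / ref.max()
            assert err < 1e-10

    def test_time_decimation_is_exact_subsampling(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 1, 1501))
        p = WaveletParams(freqs_hz=np.array([10.0, 95.0]), fs_hz=FS)
        full = tf_power(x, -500.0, p)
        dec = tf_power(x, -500.0, p, time_decim=5)
        assert np.allclose(full.data[..., ::5], dec.data, rtol=1e-9)
        assert np.allclose(full.times_ms[::5], dec.times_ms)

    def test_short_epoch_rejected(self):
        p = WaveletParams(freqs_hz=np.array([4.0]), fs_hz=FS)
        with pytest.raises(WaveletError, match="shorter"):
            tf_power(np.zeros((1, 1, 500)), 0.0, p)

    def test_impulse_temporal_fwhm(self):
        """Power response to an impulse has FWHM 2 sqrt(2 ln 2) sigma_t /
        sqrt(2) within 5%."""
        f = 50.0
        p = WaveletParams(freqs_hz=np.array([f]), fs_hz=FS)
        x = np.zeros((1, 1, 2001))
        x[0, 0, 1000] = 1.0
        st = tf_power(x, -1000.0, p)
        prof = st.data[0, 0, 0]
        half = prof.max() / 2
        above = np.where(prof >= half)[0]
        fwhm_ms = st.times_ms[above[-1]] - st.times_ms[above[0]]
        sigma_t = 7.0 / (2 * np.pi * f)
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma_t / np.sqrt(2) * 1000
        assert abs(fwhm_ms - expected) / expected < 0.05


class TestCropAndBaseline:
    def test_crop_sample_count(self):
        p = WaveletParams(freqs_hz=np.array([50.0]), fs_hz=FS)
        st = tf_power(np.zeros((1, 1, 3001)) + 1e-6, -1000.0, p)
        c = crop(st, -200.0, 500.0)
        assert c.data.shape[-1] == 701
        assert c.times_ms[0] == -200.0 and c.times_ms[-1] == 500.0

    def test_crop_full_range_is_identity(self):
        p = WaveletParams(freqs_hz=np.array([50.0]), fs_hz=FS)
        st = tf_power(np.random.default_rng(0).standard_normal((1, 1, 801)),
                      -400.0, p)
        c = crop(st, st.times_ms[0], st.times_ms[-1])
        assert np.array_equal(c.data, st.data)

    def test_crop_outside_range_errors(self):
        p = WaveletParams(freqs_hz=np.array([50.0]), fs_hz=FS)
        st = tf_power(np.zeros((1, 1, 801)), -400.0, p)
        with pytest.raises(ValueError, match="crop"):
            crop(st, -600.0, 200.0)

    def test_cropped_values_free_of_circular_edge_effects(self):
        """The crop window reproduces an oracle computed on a 2x longer
        zero-padded epoch (no wrap-around contamination) even at 4 Hz."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(3001)
        p = WaveletParams(freqs_hz=np.array([4.0, 10.0]), fs_hz=FS)
        a = crop(tf_power(x[None, None, :], -1000.0, p), -200.0, 500.0)
        xpad = np.concatenate([np.zeros(3000), x, np.zeros(3000)])
        b = crop(tf_power(xpad[None, None, :], -4000.0, p), -200.0, 500.0)
        rel = np.abs(a.data - b.data).max() / b.data.max()
        assert rel < 1e-6

    def test_log_baseline_closed_forms(self):
        times = np.arange(-200.0, 501.0)
        freqs = np.array([10.0, 50.0])
        base = np.ones((1, 1, 2, len(times)))
        st = TFStack(base.copy(), times, freqs, "raw_power")
        out = log_baseline_correct(st)
        assert np.allclose(out.values if hasattr(out, "values") else out.data,
                           0.0)
        doubled = base.copy()
        doubled[..., times > 0] = 2.0  # baseline window is -200..0 inclusive
        out2 = log_baseline_correct(TFStack(doubled, times, freqs,
                                            "raw_power"))
        assert np.allclose(out2.data[..., times > 0], np.log(2.0))
        assert out2.stage == "log_baseline_corrected"

    def test_zero_baseline_power_errors(self):
        times = np.arange(-200.0, 501.0)
        st = TFStack(np.zeros((1, 1, 1, len(times))), times,
                     np.array([10.0]), "raw_power")
        with pytest.raises(ValueError, match="noise floor"):
            log_baseline_correct(st)

    def test_stationary_noise_post_equals_baseline_level(self):
        """For stationary noise the corrected grand mean is the same in the
        post-stimulus and baseline windows (no spurious activation);
        Monte-Carlo with 500 trials at one frequency."""
        rng = np.random.default_rng(4)
        x = rng.standard_normal((500, 1, 1501))
        p = WaveletParams(freqs_hz=np.array([80.0]), fs_hz=FS)
        st = crop(tf_power(x, -500.0, p, time_decim=4,
                           single_precision=True), -200.0, 500.0)
        out = log_baseline_correct(st)
        post = out.data[..., out.times_ms > 50].mean(axis=(1, 2, 3))
        base = out.data[..., out.times_ms <= 0].mean(axis=(1, 2, 3))
        diff = post - base
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se
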