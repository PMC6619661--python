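import numpy as np
import pandas as pd
import pytest

from sleeptriage import (
    band_power, duration_ratio, extract_features, mean_amplitude,
    mean_frequency, normalize_features, power_ratio,
)
from sleeptriage.errors import ChannelResolutionError
from sleeptriage.features import FEATURE_NAMES

FS = 256.0
T30 = np.arange(int(30 * FS)) / FS


def sine(freq, amp, t=T30):
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandPower:
    def test_pure_sine_parseval(self):
        # A^2/2 for a 50 uV, 10 Hz sine
        p = band_power(sine(10, 50), FS, 8, 13)
        assert p == pytest.approx(1250.0, rel=0.02)

    def test_zero_signal(self):
        assert band_power(np.zeros(int(30 * FS)), FS, 0, 30) == 0.0

    def test_two_tone_split(self):
        x = sine(2, 40) + sine(10, 40)
        lo = band_power(x, FS, 0, 4)
        mid = band_power(x, FS, 8, 13)
        total = band_power(x, FS, 0, 30)
        assert lo == pytest.approx(mid, rel=0.05)
        assert lo == pytest.approx(total / 2, rel=0.05)

    def test_band_outside_nyquist(self):
        with pytest.raises(ValueError):
            band_power(sine(10, 1), FS, 100, 200)

    def test_subband_subadditivity(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(int(30 * FS)) * 20
        parts = (band_power(x, FS, 0, 4) + band_power(x, FS, 8, 13)
                 + band_power(x, FS, 22, 30))
        assert parts <= band_power(x, FS, 0, 30) * 1.001

    def test_quadratic_amplitude_scaling(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(int(30 * FS))
        base = band_power(x, FS, 0, 30)
        for gain in (0.5, 2.0, 7.0):
            assert band_power(gain * x, FS, 0, 30) == \
                pytest.approx(gain ** 2 * base, rel=1e-9)


class TestPowerRatio:
    def test_pure_delta(self):
        assert power_ratio(sine(2, 30), FS, (0, 4), (0, 30)) > 0.95

    def test_pure_alpha_has_no_delta(self):
        assert power_ratio(sine(10, 30), FS, (0, 4), (0, 30)) < 0.05

    def test_equal_power_split(self):
        x = sine(2, 30) + sine(25, 30)
        assert power_ratio(x, FS, (0, 4), (0, 30)) == pytest.approx(0.5, abs=0.05)

    def test_zero_denominator_floor(self):
        assert power_ratio(np.zeros(int(30 * FS)), FS, (0, 4), (0, 30)) == 0.0

    def test_numerator_must_be_contained(self):
        with pytest.raises(ValueError):
            power_ratio(sine(10, 1), FS, (0, 10), (4, 30))


class TestMeanFrequency:
    def test_pure_tone_centroid(self):
        assert mean_frequency(sine(10, 50), FS) == pytest.approx(10.0, abs=0.25)

    def test_two_tone_centroid(self):
        x = sine(5, 30) + sine(25, 30)
        assert mean_frequency(x, FS) == pytest.approx(15.0, abs=0.5)

    def test_flat_spectrum_centroid(self):
        # band-limited white noise, flat over 0-30 Hz -> centroid ~ mid-band
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(100):
            white = rng.standard_normal(int(30 * FS))
            spec = np.fft.rfft(white)
            f = np.fft.rfftfreq(white.size, 1 / FS)
            spec[f > 30] = 0
            vals.append(mean_frequency(np.fft.irfft(spec, white.size), FS))
        assert np.mean(vals) == pytest.approx(15.0, abs=1.0)

    def test_zero_power_warns_and_returns_zero(self):
        assert mean_frequency(np.zeros(int(30 * FS)), FS) == 0.0


class TestDurationRatios:
    def test_continuous_alpha_saturates(self):
        assert duration_ratio(sine(10, 50), FS, "alpha") >= 0.9

    def test_slow_wave_amplitude_criterion(self):
        # 150 uV p-p passes the 75 uV criterion, 30 uV p-p does not
        assert duration_ratio(sine(1, 75), FS, "sws") >= 0.9
        assert duration_ratio(sine(1, 15), FS, "sws") <= 0.1

    def test_half_epoch_spindle_bursts(self):
        x = np.concatenate([sine(13, 40, T30[:T30.size // 2]),
                            np.zeros(T30.size - T30.size // 2)])
        assert duration_ratio(x, FS, "spindle") == pytest.approx(0.5, abs=0.1)

    def test_unknown_detector(self):
        with pytest.raises(ValueError):
            duration_ratio(sine(10, 50), FS, "vertex")

    @pytest.mark.parametrize("detector", ["alpha", "spindle", "sws"])
    def test_polarity_flip_invariance(self, detector):
        rng = np.random.default_rng(9)
        x = sine(10, 30) + sine(1, 60) + 5 * rng.standard_normal(T30.size)
        assert duration_ratio(x, FS, detector) == \
            duration_ratio(-x, FS, detector)


class TestMeanAmplitude:
    def test_rectified_sine(self):
        assert mean_amplitude(sine(7, 42)) == \
            pytest.approx(2 * 42 / np.pi, rel=0.01)

    def test_constants(self):
        assert mean_amplitude(np.zeros(100)) == 0.0
        assert mean_amplitude(np.full(100, -5.0)) == 5.0

    def test_linear_amplitude_scaling(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(1000)
        base = mean_amplitude(x)
        for gain in (0.5, 3.0):
            assert mean_amplitude(gain * x) == pytest.approx(gain * base)


class TestExtractFeatures:
    def _channels(self, eeg, eog=None, emg=None):
        zero = np.zeros(T30.size)
        return {"EEG": (eeg, FS), "EOG": (eog if eog is not None else zero, FS),
                "EMG": (emg if emg is not None else zero, FS)}

    def test_n3_epoch_is_slow_wave_dominated(self):
        f = extract_features(self._channels(sine(1, 75)))
        assert f.sws_E > 0.5
        assert f.r0_4_E > 0.8

    def test_wake_epoch_alpha_and_tone(self):
        rng = np.random.default_rng(11)
        emg = 30 * rng.standard_normal(T30.size)
        f = extract_features(self._channels(sine(10, 40), emg=emg))
        assert f.alpha_E > 0.5
        assert f.amp_M > 20.0

    def test_all_zero_channels(self):
        f = extract_features(self._channels(np.zeros(T30.size)))
        for name in FEATURE_NAMES:
            assert getattr(f, name) == 0.0

    def test_missing_role_raises(self):
        with pytest.raises(ChannelResolutionError, match="EMG"):
            extract_features({"EEG": (sine(10, 40), FS), "EOG": (sine(1, 20), FS)})

    def test_deterministic(self):
        chans = self._channels(sine(10, 40), sine(0.5, 50), sine(3, 10))
        assert extract_features(chans) == extract_features(chans)


class TestNormalizeFeatures:
    def _table(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.random((n, len(FEATURE_NAMES))) * 100,
                            columns=list(FEATURE_NAMES))

    def test_values_within_unit_interval(self):
        norm = normalize_features(self._table())
        assert (norm.to_numpy() >= 0).all() and (norm.to_numpy() <= 1).all()

    def test_constant_column_maps_to_half(self):
        df = self._table()
        df["amp_M"] = 7.0
        assert (normalize_features(df)["amp_M"] == 0.5).all()

    def test_rank_order_preserved_within_unclipped_range(self):
        df = self._table(seed=2)
        norm = normalize_features(df)
        for col in df.columns:
            inner = (norm[col] > 0) & (norm[col] < 1)
            raw = df[col][inner].to_numpy()
            scaled = norm[col][inner].to_numpy()
            assert (np.argsort(raw) == np.argsort(scaled)).all()

    def test_single_epoch_rejected(self):
        with pytest.raises(ValueError):
            normalize_features(self._table(n=1))
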