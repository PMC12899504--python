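import numpy as np
import pytest

from footcontact import (
    FilterSpec,
    TriaxialSignal,
    UniformSignal,
    derivative,
    downsample_to,
    lowpass,
    map_time_to_index,
    resultant,
)
from footcontact.errors import ParameterError, SignalLengthError, TimeRangeError


def sine(freq, rate=60.0, duration=5.0, amp=1.0):
    t = np.arange(int(duration * rate)) / rate
    return UniformSignal(amp * np.sin(2 * np.pi * freq * t), rate)


def butter_gain(f, cutoff=20.0, order=3, passes=2):
    """Analytic Butterworth magnitude response (squared for zero-phase)."""
    return (1.0 / np.sqrt(1.0 + (f / cutoff) ** (2 * order))) ** passes


def mid_amplitude(sig):
    n = len(sig)
    return np.abs(sig.values[n // 4 : 3 * n // 4]).max()


class TestLowpass:
    def test_dc_gain_unity(self):
        sig = UniformSignal(np.full(100, 5.0), 60.0)
        out = lowpass(sig, FilterSpec(20.0, 3))
        np.testing.assert_allclose(out.values, 5.0, rtol=1e-9)

    def test_passband_amplitude_preserved(self):
        out = lowpass(sine(1.0), FilterSpec(20.0, 3))
        assert mid_amplitude(out) == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuation_matches_analytic(self):
        out = lowpass(sine(25.0), FilterSpec(20.0, 3))
        assert mid_amplitude(out) <= butter_gain(25.0) + 0.05

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = UniformSignal(rng.normal(size=200), 60.0)
        y = UniformSignal(rng.normal(size=200), 60.0)
        combo = UniformSignal(2.0 * x.values + 3.0 * y.values, 60.0)
        lhs = lowpass(combo).values
        rhs = 2.0 * lowpass(x).values + 3.0 * lowpass(y).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_zero_phase_preserves_pulse_timing(self):
        t = np.arange(300) / 60.0
        pulse = UniformSignal(np.exp(-0.5 * ((t - 2.5) / 0.1) ** 2), 60.0)
        out = lowpass(pulse, FilterSpec(20.0, 3, zero_phase=True))
        assert abs(int(np.argmax(out.values)) - int(np.argmax(pulse.values))) <= 1

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            lowpass(sine(1.0), FilterSpec(30.0, 3))  # cutoff at Nyquist
        with pytest.raises(SignalLengthError):
            lowpass(UniformSignal(np.zeros(5), 60.0), FilterSpec(20.0, 3))


class TestResultant:
    def test_pythagorean_triple(self):
        acc = TriaxialSignal(
            UniformSignal(np.array([3.0, 0.0]), 60.0),
            UniformSignal(np.array([4.0, 0.0]), 60.0),
            UniformSignal(np.array([0.0, 0.0]), 60.0),
        )
        np.testing.assert_allclose(resultant(acc).values, [5.0, 0.0])

    def test_matches_elementwise_norm(self):
        rng = np.random.default_rng(1)
        xyz = rng.normal(size=(3, 100))
        acc = TriaxialSignal(*(UniformSignal(c, 60.0) for c in xyz))
        expected = np.array(
            [np.sqrt(sum(xyz[a][i] ** 2 for a in range(3))) for i in range(100)]
        )
        np.testing.assert_allclose(resultant(acc).values, expected, atol=1e-12)


class TestDerivative:
    def test_ramp_and_constant(self):
        t = np.arange(60) / 60.0
        ramp = derivative(UniformSignal(2.0 * t, 60.0))
        np.testing.assert_allclose(ramp.values, 2.0, atol=1e-9)
        const = derivative(UniformSignal(np.full(60, 3.0), 60.0))
        np.testing.assert_allclose(const.values, 0.0, atol=1e-12)

    def test_sine_matches_analytic_cosine(self):
        f, rate = 2.0, 60.0
        t = np.arange(300) / rate
        d = derivative(UniformSignal(np.sin(2 * np.pi * f * t), rate))
        expected = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        # central differences: error bounded by (h^2 / 6) * max|f'''|
        bound = (1 / rate) ** 2 / 6 * (2 * np.pi * f) ** 3 * 1.05
        assert np.abs(d.values[1:-1] - expected[1:-1]).max() <= bound

    def test_too_short(self):
        with pytest.raises(SignalLengthError):
            derivative(UniformSignal(np.array([1.0, 2.0]), 60.0))


class TestDownsample:
    def test_constant_preserved(self):
        sig = UniformSignal(np.full(1000, 700.0), 1000.0)
        out = downsample_to(sig, 60.0)
        assert out.rate == 60.0 and out.t0 == sig.t0
        interior = out.values[5:-5]
        np.testing.assert_allclose(interior, 700.0, atol=1e-6)

    def test_sine_amplitude_within_two_percent(self):
        t = np.arange(2000) / 1000.0
        sig = UniformSignal(np.sin(2 * np.pi * 5.0 * t), 1000.0)
        out = downsample_to(sig, 60.0)
        assert mid_amplitude(out) == pytest.approx(1.0, rel=0.02)

    def test_duration_preserved(self):
        sig = UniformSignal(np.zeros(1000), 1000.0)
        out = downsample_to(sig, 60.0)
        assert len(out) == 60
        assert len(out) / out.rate == pytest.approx(len(sig) / sig.rate)

    def test_upsampling_rejected(self):
        with pytest.raises(ParameterError):
            downsample_to(UniformSignal(np.zeros(100), 60.0), 120.0)


class TestTimeToIndex:
    sig60 = UniformSignal(np.zeros(120), 60.0)

    @pytest.mark.parametrize(
        "t,expected",
        [(0.5, 30), (0.0, 0), (1.5 / 60, 2), (0.9783, 59)],
    )
    def test_nearest_with_half_up(self, t, expected):
        assert map_time_to_index(t, self.sig60) == expected

    def test_out_of_span(self):
        with pytest.raises(TimeRangeError):
            map_time_to_index(-0.5, self.sig60)
        with pytest.raises(TimeRangeError):
            map_time_to_index(2.01, self.sig60)

    def test_downsample_commutes_with_event_mapping(self):
        # an event planted at time t lands within 1 target-rate sample
        t_event = 0.7214
        t = np.arange(3000) / 1000.0
        sig = UniformSignal(np.exp(-0.5 * ((t - t_event) / 0.05) ** 2), 1000.0)
        low = downsample_to(sig, 60.0)
        idx = int(np.argmax(low.values))
        assert abs(idx - map_time_to_index(t_event, low)) <= 1
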