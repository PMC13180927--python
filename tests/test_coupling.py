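import numpy as np
import pytest
from scipy import signal as sps

from neurocoupling.core import SampledSeries
from neurocoupling.coupling import (
    CoherenceSettings,
    OperatingBoundary,
    cmh,
    estimate_boundary,
    gait_frequency,
    gait_phase,
    gcc,
    interpret_gcc,
)
from neurocoupling.signals import GaitEvents

from _oracles import percentile_linear, welch_msc


def strikes(stride=1.0, n=40, start=0.0):
    """Alternating heel strikes with a fixed stride duration."""
    times, feet = [], []
    t = start
    for i in range(n):
        times.append(t)
        feet.append("L" if i % 2 == 0 else "R")
        t += stride / 2
    return GaitEvents(np.array(times), tuple(feet))


class TestGaitPhase:
    def test_zero_at_heel_strike_and_pi_midway(self):
        ev = strikes(stride=1.0, n=10)
        grid = np.array([0.0, 0.5, 1.0, 1.5])
        phase = gait_phase(ev, grid).values
        assert phase[0] == pytest.approx(0.0)
        assert phase[1] == pytest.approx(np.pi)
        assert phase[2] == pytest.approx(0.0, abs=1e-9)
        assert phase[3] == pytest.approx(np.pi)

    def test_constant_strides_give_1hz_sawtooth(self):
        ev = strikes(stride=1.0, n=40)
        grid = np.arange(0.0, 18.0, 0.05)
        phase = gait_phase(ev, grid).values
        expected = 2 * np.pi * np.mod(grid, 1.0)
        assert np.allclose(phase, expected, atol=1e-9)

    def test_too_few_events_rejected(self):
        ev = GaitEvents(np.array([0.0, 0.5, 1.0]), ("L", "R", "L"))
        with pytest.raises(ValueError, match=">= 3"):
            gait_phase(ev, np.arange(0, 1, 0.1))


class TestGaitFrequency:
    @pytest.mark.parametrize("stride, expected", [(1.0, 1.0), (0.8, 1.25)])
    def test_constant_strides(self, stride, expected):
        assert gait_frequency(strikes(stride=stride)) == pytest.approx(expected)

    def test_median_of_jittered_strides(self):
        # left-foot strides 0.9, 1.0, 1.1 -> median 1.0 s -> 1.0 Hz
        left = np.array([0.0, 0.9, 1.9, 3.0])
        times = np.sort(np.concatenate([left, left[:-1] + 0.45]))
        feet = tuple("L" if t in left else "R" for t in times)
        ev = GaitEvents(times, feet)
        assert gait_frequency(ev) == pytest.approx(1.0)


def phase_series(fs=32.0, dur=80.0, f=1.0):
    t = np.arange(0, dur, 1 / fs)
    phase = 2 * np.pi * np.mod(t * f, 1.0)
    return SampledSeries(0.0, fs, phase, units="rad", epoch_s=dur + 1)


def env_series(values, fs=32.0):
    v = np.asarray(values, dtype=float)
    return SampledSeries(0.0, fs, v, units="au", epoch_s=v.size / fs + 1)


class TestGCC:
    def test_noiseless_cosine_of_phase_is_fully_coherent(self):
        ph = phase_series()
        theta = env_series(np.cos(ph.values))
        assert gcc(theta, ph, 1.0) >= 0.99

    @pytest.mark.parametrize("n", [640, 1024, 2560])
    def test_matches_brute_force_welch_oracle(self, n):
        rng = np.random.default_rng(n)
        fs = 32.0
        est = CoherenceSettings(n_segments=8, segment_s=n / fs / 5.0)
        ph = phase_series(fs=fs, dur=n / fs)
        theta = env_series(rng.normal(size=n), fs=fs)
        got = gcc(theta, ph, 1.0, est)
        nperseg = int(round(est.segment_s * fs))
        freqs, msc, n_seg = welch_msc(theta.values, np.cos(ph.values), fs, nperseg)
        want = msc[int(np.argmin(np.abs(freqs - 1.0)))]
        assert n_seg >= est.n_segments
        assert got == pytest.approx(float(want), abs=1e-8)

    def test_monotone_decreasing_in_noise(self):
        ph = phase_series()
        clean = np.cos(ph.values)
        vals = []
        for i, sd in enumerate([0.0, 0.5, 1.0, 2.0, 4.0]):
            rng = np.random.default_rng(77 + i)
            theta = env_series(clean + sd * rng.normal(size=clean.size))
            vals.append(gcc(theta, ph, 1.0))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_constant_envelope_rejected(self):
        ph = phase_series()
        with pytest.raises(ValueError, match="zero-variance"):
            gcc(env_series(np.ones(ph.n)), ph, 1.0)

    def test_short_record_rejected(self):
        ph = phase_series(dur=10.0)
        theta = env_series(np.cos(ph.values))
        with pytest.raises(ValueError, match="too short"):
            gcc(theta, ph, 1.0, CoherenceSettings(n_segments=8, segment_s=8.0))


class TestInterpretGCC:
    @pytest.mark.parametrize("gcc_value", [0.9, 0.5, 0.1])
    @pytest.mark.parametrize("scd_level", ["low", "high"])
    @pytest.mark.parametrize("neq_state", ["degraded", "preserved"])
    def test_full_rule_table(self, gcc_value, scd_level, neq_state):
        threshold = 0.75
        reading = interpret_gcc(gcc_value, scd_level, neq_state, threshold)
        elevated = gcc_value > threshold
        if elevated and scd_level == "low" and neq_state == "degraded":
            expected = "compensatory_overcontrol"
        elif elevated and scd_level == "high" and neq_state == "preserved":
            expected = "adaptive_recruitment"
        else:
            expected = "indeterminate"
        assert reading.label == expected
        assert reading.elevated == elevated

    def test_non_elevated_is_always_indeterminate(self):
        for scd_level in ("low", "high"):
            for neq_state in ("degraded", "preserved"):
                assert interpret_gcc(0.2, scd_level, neq_state, 0.75).label == "indeterminate"


def cmfi_series(values, fs=1.0):
    v = np.asarray(values, dtype=float)
    return SampledSeries(0.0, fs, v, units="index", epoch_s=v.size / fs + 1)


class TestEstimateBoundary:
    def test_degenerate_failure_preceding_demand(self):
        series = cmfi_series(np.full(100, 0.8))
        sessions = [(series, [20.0, 40.0, 60.0, 80.0, 99.0])]
        b = estimate_boundary(challenge_sessions=sessions)
        assert b.C_star == pytest.approx(0.8)
        assert b.method == "challenge_response"
        assert b.n_support == 5

    def test_normative_quantile_matches_percentile_oracle(self):
        samples = np.linspace(0, 1, 101)
        b = estimate_boundary(normative_cmfi=samples, method="normative_quantile", q=0.9)
        assert b.C_star == pytest.approx(percentile_linear(samples, 90))
        assert b.C_star == pytest.approx(0.9)

    def test_insufficient_challenge_support_is_an_error(self):
        series = cmfi_series(np.full(100, 0.5))
        with pytest.raises(ValueError, match="insufficient support"):
            estimate_boundary(challenge_sessions=[(series, [10.0, 30.0, 50.0])])

    def test_insufficient_normative_support_is_an_error(self):
        with pytest.raises(ValueError, match="insufficient support"):
            estimate_boundary(normative_cmfi=np.linspace(0, 1, 10),
                              method="normative_quantile")

    def test_lower_decile_of_failure_preceding_demand(self, rng):
        vals = rng.uniform(0.2, 1.0, 200)
        series = cmfi_series(vals)
        failures = [50.0, 100.0, 150.0, 180.0, 199.0]
        b = estimate_boundary(challenge_sessions=[(series, failures)])
        pre = np.concatenate([vals[int(f) - 5:int(f)] for f in failures])
        assert b.C_star == pytest.approx(percentile_linear(pre, 10), abs=1e-12)


class TestCMH:
    def boundary(self, c):
        return OperatingBoundary(C_star=c, method="normative_quantile",
                                 quantile_q=0.9, n_support=50)

    @pytest.mark.parametrize("c_star, current, expected",
                             [(0.8, 0.6, 0.2), (0.7, 0.7, 0.0), (0.5, 0.7, -0.2)])
    def test_headroom_sign_semantics(self, c_star, current, expected):
        assert cmh(self.boundary(c_star), current) == pytest.approx(expected)

    def test_antitone_in_current_demand_monotone_in_boundary(self, rng):
        for _ in range(200):
            c1, c2 = np.sort(rng.uniform(0, 1, 2))
            b1, b2 = np.sort(rng.uniform(0, 1, 2))
            x = rng.uniform(0, 1)
            assert cmh(self.boundary(x), c2) <= cmh(self.boundary(x), c1)
            assert cmh(self.boundary(b1), x) <= cmh(self.boundary(b2), x)
            assert -1.0 <= cmh(self.boundary(b1), x) <= 1.0
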