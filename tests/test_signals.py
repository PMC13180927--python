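import numpy as np
import pytest
from scipy import signal as sps

from neurocoupling.core import ReferenceDistribution, SampledSeries, validate_weights
from neurocoupling.signals import (
    ALPHA_BAND,
    THETA_BAND,
    BandDefinition,
    GaitEvents,
    alpha_suppression,
    bandpower_envelope,
    gait_cost,
    instability,
    neural_demand,
    step_asymmetry,
    stride_variability,
)

from _oracles import analytic_envelope_sq, biquad_cascade_filtfilt, moving_average_same
from conftest import unit_series

FS = 64.0


def make_series(values, fs=FS):
    return SampledSeries(t0=0.0, fs=fs, values=values, units="uV")


class TestBandpowerEnvelope:
    def test_zero_signal_gives_zero_envelope(self):
        env = bandpower_envelope(make_series(np.zeros(512)), THETA_BAND)
        assert np.allclose(env.values, 0.0)

    def test_theta_sinusoid_dominates_alpha_band(self):
        t = np.arange(1024) / FS
        x = make_series(np.sin(2 * np.pi * 6.0 * t))
        theta_env = bandpower_envelope(x, THETA_BAND).values
        alpha_env = bandpower_envelope(x, ALPHA_BAND).values
        # compare in the steady-state interior, away from filter edge transients
        sl = slice(128, -128)
        assert np.mean(theta_env[sl]) > 10 * np.mean(alpha_env[sl])
        # cross-check band dominance with a plain periodogram on the same data
        f, pxx = sps.periodogram(x.values, fs=FS)
        theta_power = pxx[(f >= 4) & (f < 8)].sum()
        alpha_power = pxx[(f >= 8) & (f < 13)].sum()
        assert theta_power > 10 * alpha_power

    def test_matches_brute_force_filter_hilbert_oracle(self, rng):
        x = rng.normal(size=1024)
        window_s = 0.25
        env = bandpower_envelope(make_series(x), THETA_BAND, window_s=window_s).values
        sos = sps.butter(4, [THETA_BAND.f_lo, THETA_BAND.f_hi], btype="bandpass",
                         fs=FS, output="sos")
        filtered = biquad_cascade_filtfilt(sos, x)
        power = analytic_envelope_sq(filtered)
        expected = moving_average_same(power, int(round(window_s * FS)))
        rms = np.sqrt(np.mean((env - np.maximum(expected, 0.0)) ** 2))
        assert rms < 1e-6

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            bandpower_envelope(make_series(np.zeros(512), fs=20.0),
                               BandDefinition("beta", 13, 30))

    def test_band_edges_validated(self):
        with pytest.raises(ValueError, match="f_lo"):
            BandDefinition("bad", 10.0, 5.0)


class TestAlphaSuppression:
    REF = ReferenceDistribution("alpha", 1.0, 5.0)

    @pytest.mark.parametrize("power, expected", [(5.0, 0.0), (1.0, 1.0), (3.0, 0.5)])
    def test_inverts_normalized_alpha(self, power, expected):
        s = make_series(np.full(64, power))
        out = alpha_suppression(s, self.REF)
        assert np.allclose(out.values, expected)


def alternating_events(step=0.5, n=40, start=0.0):
    times = start + step * np.arange(n)
    feet = tuple("L" if i % 2 == 0 else "R" for i in range(n))
    return GaitEvents(times, feet)


class TestGaitEvents:
    def test_strictly_increasing_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            GaitEvents(np.array([0.0, 1.0, 1.0]), ("L", "R", "L"))

    def test_alternation_violations_flagged_not_fatal(self):
        ev = GaitEvents(np.array([0.0, 0.5, 1.0]), ("L", "L", "R"))
        assert ev.alternation_violations == (1,)


class TestStepAsymmetry:
    def test_perfectly_alternating_gait_has_zero_asymmetry(self):
        ev = alternating_events()
        s = step_asymmetry(ev, window_s=5.0)
        assert np.allclose(s.values[s.quality], 0.0)

    def test_known_left_right_split(self):
        # left steps 0.6 s, right steps 0.4 s: |0.6-0.4| / 0.5 = 0.4
        times, feet = [0.0], ["R"]
        t = 0.0
        for _ in range(20):
            t += 0.6
            times.append(t)
            feet.append("L")
            t += 0.4
            times.append(t)
            feet.append("R")
        ev = GaitEvents(np.array(times), tuple(feet))
        s = step_asymmetry(ev, window_s=10.0)
        assert np.allclose(s.values[s.quality], 0.4)

    def test_single_foot_window_is_a_flagged_gap(self):
        ev = GaitEvents(np.arange(6, dtype=float), ("L",) * 6)
        s = step_asymmetry(ev, window_s=5.0)
        assert not s.quality.any()
        assert np.all(np.isnan(s.values))


class TestStrideVariability:
    def test_constant_strides_have_zero_cv(self):
        s = stride_variability(alternating_events(), window_s=10.0)
        assert np.allclose(s.values[s.quality], 0.0, atol=1e-12)

    def test_cv_matches_brute_force_sd_over_mean(self):
        # one foot stepping with strides alternating 1.0, 1.2 s
        strides = [1.0, 1.2] * 6
        times, feet = [0.0], ["L"]
        t = 0.0
        for st_ in strides:
            t += st_ / 2
            times.append(t)
            feet.append("R")
            t += st_ / 2
            times.append(t)
            feet.append("L")
        ev = GaitEvents(np.array(times), tuple(feet))
        s = stride_variability(ev, window_s=t + 1.0)
        observed = [1.0, 1.2] * 5 + [1.0, 1.2][: len(strides) - 1]
        both_feet = np.diff(np.array(times)[::2]).tolist() + np.diff(np.array(times)[1::2]).tolist()
        expected = np.std(both_feet, ddof=1) / np.mean(both_feet)
        assert s.values[s.quality][0] == pytest.approx(expected, abs=1e-12)

    def test_empty_window_is_a_flagged_gap(self):
        ev = alternating_events(n=30)
        s = stride_variability(ev, window_s=5.0, t_start=-20.0, t_end=20.0)
        assert not s.quality[0]  # window before any event


class TestGaitCost:
    def test_equal_inputs_pass_through(self):
        v = unit_series([0.3, 0.7, 0.1], fs=1.0)
        out = gait_cost(v, v)
        assert np.allclose(out.values, v.values)

    @pytest.mark.parametrize("a, b, expected", [(1.0, 0.0, 0.5), (0.2, 0.6, 0.4)])
    def test_fixed_half_half_coefficients(self, a, b, expected):
        out = gait_cost(unit_series([a] * 3, fs=1.0), unit_series([b] * 3, fs=1.0))
        assert np.allclose(out.values, expected)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="common time grid"):
            gait_cost(unit_series([0.1] * 4, fs=1.0), unit_series([0.1] * 4, fs=2.0))


class TestNeuralDemand:
    def test_convex_combination_identity(self):
        v = unit_series([0.2, 0.5, 0.9], fs=1.0)
        out = neural_demand(v, v, v)
        assert np.allclose(out.values, v.values)

    def test_degenerate_weights_pass_through_theta(self):
        w = validate_weights(("theta", "alpha_sup", "beta_ctrl"), (1.0, 0.0, 0.0))
        theta = unit_series([0.1, 0.9, 0.4], fs=1.0)
        other = unit_series([0.5, 0.5, 0.5], fs=1.0)
        out = neural_demand(theta, other, other, w)
        assert np.allclose(out.values, theta.values)

    def test_weighted_sum_matches_direct_evaluation(self):
        w = validate_weights(("theta", "alpha_sup", "beta_ctrl"), (0.5, 0.3, 0.2))
        out = neural_demand(
            unit_series([0.2], fs=1.0), unit_series([0.4], fs=1.0),
            unit_series([0.9], fs=1.0), w)
        assert out.values[0] == pytest.approx(0.5 * 0.2 + 0.3 * 0.4 + 0.2 * 0.9)
        assert out.values[0] == pytest.approx(0.40)

    def test_unnormalized_input_rejected(self):
        bad = unit_series([1.5, 0.2, 0.1], fs=1.0)
        ok = unit_series([0.5, 0.2, 0.1], fs=1.0)
        with pytest.raises(ValueError, match="normalized"):
            neural_demand(bad, ok, ok)

    def test_monotone_in_each_component(self, rng):
        w = validate_weights(("theta", "alpha_sup", "beta_ctrl"), (0.4, 0.35, 0.25))
        base = rng.uniform(0, 1, 3)
        for j in range(3):
            lo, hi = np.sort(rng.uniform(0, 1, 2))
            args_lo = [unit_series([base[k] if k != j else lo], fs=1.0) for k in range(3)]
            args_hi = [unit_series([base[k] if k != j else hi], fs=1.0) for k in range(3)]
            assert neural_demand(*args_lo, w).values[0] <= neural_demand(*args_hi, w).values[0]


class TestInstability:
    REFS = tuple(ReferenceDistribution(f"c{i}", 0.0, 2.0) for i in range(3))

    def series(self, v):
        return unit_series([v] * 4, fs=2.0)

    def test_all_at_q10_gives_zero(self):
        out = instability(self.series(0.0), self.series(0.0), self.series(0.0), self.REFS)
        assert np.allclose(out.values, 0.0)

    def test_all_at_q90_gives_one(self):
        out = instability(self.series(2.0), self.series(2.0), self.series(2.0), self.REFS)
        assert np.allclose(out.values, 1.0)

    def test_one_component_at_q90_gives_one_third(self):
        out = instability(self.series(2.0), self.series(0.0), self.series(0.0), self.REFS)
        assert np.allclose(out.values, 1.0 / 3.0)


class TestRangeInvariants:
    def test_composites_stay_in_unit_interval_under_fuzzing(self, rng):
        refs = tuple(ReferenceDistribution(f"r{i}", 0.2, 1.7) for i in range(3))
        for _ in range(200):
            n = int(rng.integers(2, 30))
            mk = lambda: unit_series(rng.uniform(0, 1, n), fs=1.0)
            raw = lambda: unit_series(rng.uniform(-1, 4, n), fs=1.0)
            N = neural_demand(mk(), mk(), mk())
            G = gait_cost(mk(), mk())
            I = instability(raw(), raw(), raw(), refs)
            for s in (N, G, I):
                assert np.all((s.values >= 0) & (s.values <= 1))
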