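"""Person-level composite signals: neural demand N(t), gait cost G(t), instability I(t).

N(t) is a convex combination of three normalized EEG band-power proxies
(frontal-midline theta for control demand, parietal-occipital alpha
suppression for perceptual engagement, sensorimotor beta for motor-set
maintenance).  G(t) combines step asymmetry and stride-time variability with
the fixed coefficients 0.5/0.5.  I(t) averages three normalized
sway/pressure channels (mediolateral sway, anterior-posterior sway, support
shift).  All three live in [0, 1].

Normalization happens here via stratum references (see
:mod:`neurocoupling.core`); the combination operations refuse mismatched
time grids rather than resampling silently — resampling is the I/O layer's
job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ReferenceDistribution, SampledSeries, WeightVector, normalize

__all__ = [
    "BandDefinition",
    "GaitEvents",
    "THETA_BAND",
    "ALPHA_BAND",
    "BETA_BAND",
    "bandpower_envelope",
    "alpha_suppression",
    "neural_demand",
    "step_asymmetry",
    "stride_variability",
    "gait_cost",
    "instability",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"band '{self.name}': need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]")


# Default band edges; the band names are standard, the exact edges configurable.
THETA_BAND = BandDefinition("theta", 4.0, 8.0)
ALPHA_BAND = BandDefinition("alpha", 8.0, 13.0)
BETA_BAND = BandDefinition("beta", 13.0, 30.0)


@dataclass(frozen=True)
class GaitEvents:
    """Heel-strike times with foot labels.

    Times must be strictly increasing.  Feet are expected to alternate;
    violations are recorded in ``alternation_violations`` (sample indices of
    the second event of each same-foot pair) but are not fatal.
    """

    times: np.ndarray
    foot: tuple[str, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if not np.all(np.isfinite(t)):
            raise ValueError("event times must be finite")
        if np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValueError(f"event times must be strictly increasing (violation at event {bad})")
        if len(self.foot) != t.size:
            raise ValueError("one foot label per event required")
        bad_labels = {f for f in self.foot} - {"L", "R"}
        if bad_labels:
            raise ValueError(f"foot labels must be 'L' or 'R', got {sorted(bad_labels)}")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def alternation_violations(self) -> tuple[int, ...]:
        return tuple(
            i for i in range(1, self.n) if self.foot[i] == self.foot[i - 1]
        )

    def foot_times(self, foot: str) -> np.ndarray:
        return self.times[[f == foot for f in self.foot]]

    def stride_times(self, foot: str) -> np.ndarray:
        """Intervals between successive same-foot heel strikes."""
        return np.diff(self.foot_times(foot))

    def step_times(self) -> tuple[np.ndarray, np.ndarray]:
        """(left-step, right-step) durations.

        A left step ends at a left heel strike (interval from the preceding
        right strike); symmetrically for right steps.  Same-foot pairs are
        skipped.
        """
        left, right = [], []
        for i in range(1, self.n):
            if self.foot[i] == self.foot[i - 1]:
                continue
            dt = self.times[i] - self.times[i - 1]
            (left if self.foot[i] == "L" else right).append(dt)
        return np.asarray(left), np.asarray(right)


def bandpower_envelope(raw: SampledSeries, band: BandDefinition, window_s: float = 1.0) -> SampledSeries:
    """Sliding-window band power of a raw channel.

    Zero-phase 4th-order Butterworth bandpass, squared magnitude of the
    analytic signal, then a moving average over ``window_s``.  Output is
    non-negative, on the input grid.  Requires fs > 2*f_hi.
    """
    if raw.fs <= 2 * band.f_hi:
        raise ValueError(
            f"sampling rate {raw.fs} Hz too low for band '{band.name}' "
            f"(need fs > {2 * band.f_hi} Hz)"
        )
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    sos = sps.butter(4, [band.f_lo, band.f_hi], btype="bandpass", fs=raw.fs, output="sos")
    # zero-phase via zero-state forward-backward passes: no edge padding or
    # fitted initial conditions, at the cost of a short edge transient
    forward = sps.sosfilt(sos, raw.values)
    filtered = sps.sosfilt(sos, forward[::-1])[::-1]
    power = np.abs(sps.hilbert(filtered)) ** 2
    win = max(1, int(round(window_s * raw.fs)))
    kernel = np.ones(win) / win
    smoothed = np.convolve(power, kernel, mode="same")
    return raw.replace_values(np.maximum(smoothed, 0.0), units=f"{raw.units}^2" if raw.units else "power")


def alpha_suppression(alpha_power: SampledSeries, ref: ReferenceDistribution) -> SampledSeries:
    """Alpha-suppression proxy: 1 - normalized alpha power.

    Higher values mean stronger suppression of parietal-occipital alpha,
    i.e. more active perceptual engagement, so the proxy points in the same
    "more demand" direction as the theta and beta components.
    """
    return alpha_power.replace_values(1.0 - normalize(alpha_power.values, ref), units="normalized")


def _check_common_grid(*series: SampledSeries) -> None:
    first = series[0]
    for s in series[1:]:
        if not first.same_grid(s):
            raise ValueError(
                "series are not on a common time grid "
                f"(t0/fs/n: {first.t0}/{first.fs}/{first.n} vs {s.t0}/{s.fs}/{s.n}); "
                "resample in the I/O layer first"
            )


def _check_unit_interval(name: str, s: SampledSeries) -> None:
    good = s.quality[s.epoch_index(s.times)]
    v = s.values[good]
    if v.size and (np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12):
        raise ValueError(f"{name} must be normalized to [0,1] before combination")


def _merged_quality(*series: SampledSeries) -> np.ndarray:
    q = series[0].quality.copy()
    for s in series[1:]:
        q &= s.quality
    return q


def neural_demand(
    theta: SampledSeries,
    alpha_sup: SampledSeries,
    beta_ctrl: SampledSeries,
    w: WeightVector | None = None,
) -> SampledSeries:
    """Composite neural control-demand signal N(t).

    N(t) = w_theta*theta(t) + w_alpha*alpha_sup(t) + w_beta*beta(t), a
    pointwise convex combination of the three normalized band proxies;
    bounded in [0, 1].  Inputs must already be normalized and share a grid.
    """
    if w is None:
        w = WeightVector.uniform(("theta", "alpha_sup", "beta_ctrl"))
    if len(w.names) != 3:
        raise ValueError("neural_demand requires a 3-component weight vector")
    _check_common_grid(theta, alpha_sup, beta_ctrl)
    for name, s in (("theta", theta), ("alpha_sup", alpha_sup), ("beta_ctrl", beta_ctrl)):
        _check_unit_interval(name, s)
    vals = (
        w.values[0] * theta.values
        + w.values[1] * alpha_sup.values
        + w.values[2] * beta_ctrl.values
    )
    return SampledSeries(
        t0=theta.t0, fs=theta.fs, values=np.clip(vals, 0.0, 1.0), units="index",
        quality=_merged_quality(theta, alpha_sup, beta_ctrl), epoch_s=theta.epoch_s,
    )


def _windowed_gait_series(
    events: GaitEvents,
    window_s: float,
    stat,
    min_required: int,
    t_start: float | None = None,
    t_end: float | None = None,
) -> SampledSeries:
    """One value of ``stat`` per non-overlapping window; flagged NaN where
    the window has insufficient events."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t_start = events.times[0] if t_start is None else t_start
    t_end = events.times[-1] if t_end is None else t_end
    n_win = max(1, math.ceil((t_end - t_start) / window_s))
    vals = np.full(n_win, np.nan)
    qual = np.zeros(n_win, dtype=bool)
    for k in range(n_win):
        lo, hi = t_start + k * window_s, t_start + (k + 1) * window_s
        mask = (events.times >= lo) & (events.times < hi)
        idx = np.flatnonzero(mask)
        if idx.size >= min_required:
            sub = GaitEvents(events.times[idx], tuple(events.foot[i] for i in idx))
            v = stat(sub)
            if v is not None and math.isfinite(v):
                vals[k] = v
                qual[k] = True
    return SampledSeries(
        t0=t_start, fs=1.0 / window_s, values=vals, units="raw",
        quality=qual, epoch_s=window_s,
    )


def _raw_asymmetry(sub: GaitEvents) -> float | None:
    left, right = sub.step_times()
    if left.size == 0 or right.size == 0:
        return None
    mean_l, mean_r = float(np.mean(left)), float(np.mean(right))
    mean_step = 0.5 * (mean_l + mean_r)  # balanced: invariant to unequal step counts
    if mean_step <= 0:
        return None
    return abs(mean_l - mean_r) / mean_step


def _raw_stride_cv(sub: GaitEvents) -> float | None:
    strides = np.concatenate([sub.stride_times("L"), sub.stride_times("R")])
    if strides.size < 2:
        return None
    m = float(np.mean(strides))
    if m <= 0:
        return None
    return float(np.std(strides, ddof=1)) / m


def step_asymmetry(
    events: GaitEvents,
    window_s: float,
    ref: ReferenceDistribution | None = None,
    t_start: float | None = None,
    t_end: float | None = None,
) -> SampledSeries:
    """Windowed step asymmetry: |mean left-step - mean right-step| / mean step.

    One value per non-overlapping window of ``window_s`` seconds; windows
    with fewer than 4 alternating events are flagged as gaps (quality False,
    value NaN), never imputed.  With ``ref`` the raw ratio is normalized to
    [0, 1]; without, the raw ratio is returned.
    """
    s = _windowed_gait_series(events, window_s, _raw_asymmetry, 4, t_start, t_end)
    if ref is None:
        return s
    out = s.values.copy()
    out[s.quality] = normalize(out[s.quality], ref)
    return s.replace_values(out, units="normalized")


def stride_variability(
    events: GaitEvents,
    window_s: float,
    ref: ReferenceDistribution | None = None,
    t_start: float | None = None,
    t_end: float | None = None,
) -> SampledSeries:
    """Windowed stride-time coefficient of variation (sd/mean over strides).

    A stride is the interval between successive same-foot heel strikes.
    Windows with fewer than 4 same-foot stride-defining events are flagged
    gaps.  With ``ref`` the raw CV is normalized to [0, 1].
    """

    def stat(sub: GaitEvents) -> float | None:
        if sub.stride_times("L").size + sub.stride_times("R").size < 2:
            return None
        return _raw_stride_cv(sub)

    # 4 events of one foot -> 3 strides; require >= 5 events so at least
    # ~4 same-foot strides are plausible, but the stat guard is what decides.
    s = _windowed_gait_series(events, window_s, stat, 4, t_start, t_end)
    if ref is None:
        return s
    out = s.values.copy()
    out[s.quality] = normalize(out[s.quality], ref)
    return s.replace_values(out, units="normalized")


def gait_cost(asym: SampledSeries, varstride: SampledSeries) -> SampledSeries:
    """Gait control-cost signal G(t) = 0.5*asym(t) + 0.5*varstride(t).

    The equal coefficients are fixed, not configurable.  Inputs must be
    normalized to [0,1] and share a grid; output is in [0, 1] with quality
    the conjunction of the inputs' flags.
    """
    _check_common_grid(asym, varstride)
    _check_unit_interval("asym", asym)
    _check_unit_interval("varstride", varstride)
    vals = 0.5 * asym.values + 0.5 * varstride.values
    return SampledSeries(
        t0=asym.t0, fs=asym.fs, values=vals, units="index",
        quality=_merged_quality(asym, varstride), epoch_s=asym.epoch_s,
    )


def instability(
    mlsway: SampledSeries,
    apsway: SampledSeries,
    supportshift: SampledSeries,
    refs: tuple[ReferenceDistribution, ReferenceDistribution, ReferenceDistribution],
) -> SampledSeries:
    """Instability signal I(t): mean of the three normalized sway components.

    I(t) = [norm(ml) + norm(ap) + norm(shift)] / 3, each channel normalized
    against its own stratum reference; bounded in [0, 1].
    """
    _check_common_grid(mlsway, apsway, supportshift)
    parts = [
        normalize(s.values, r)
        for s, r in zip((mlsway, apsway, supportshift), refs)
    ]
    vals = (parts[0] + parts[1] + parts[2]) / 3.0
    return SampledSeries(
        t0=mlsway.t0, fs=mlsway.fs, values=vals, units="index",
        quality=_merged_quality(mlsway, apsway, supportshift), epoch_s=mlsway.epoch_s,
    )
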