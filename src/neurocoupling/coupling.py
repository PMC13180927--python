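"""Gait-cognition coherence (GCC) and cognitive-motor headroom (CMH).

GCC is the magnitude-squared coherence between the frontal-theta power
envelope and the gait phase, evaluated at the gait frequency (the
reciprocal of the median stride time).  Gait phase advances linearly from 0
to 2*pi between successive same-foot heel strikes and is embedded as
cos(phase) to give a real narrowband reference for the coherence estimate
(Welch, Hann window, 50% overlap).

GCC must never be read univariately: the same elevated coherence can mean
compensatory over-control (reduced gait automaticity) in a low-demand
environment with degraded efficiency, or adaptive recruitment in a
high-demand environment with preserved efficiency.  ``interpret_gcc``
encodes exactly that context-conditional rule table and returns
"indeterminate" everywhere else.

CMH = C* - CMFI_current measures reserve relative to an individualized
operating boundary C*, estimated either from challenge-response data (the
lower tail of demand observed to precede instability failures) or as a
normative stratum quantile — never a universal fixed threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import SampledSeries
from .signals import GaitEvents, _check_common_grid

__all__ = [
    "CoherenceSettings",
    "OperatingBoundary",
    "GCCContextReading",
    "gait_phase",
    "gait_frequency",
    "gcc",
    "interpret_gcc",
    "estimate_boundary",
    "cmh",
]


@dataclass(frozen=True)
class CoherenceSettings:
    """Welch estimator settings for GCC: Hann window, 50% overlap."""

    n_segments: int = 8
    segment_s: float = 8.0

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("need at least 2 Welch segments")
        if self.segment_s <= 0:
            raise ValueError("segment_s must be positive")

    def as_dict(self) -> dict[str, float]:
        return {"n_segments": self.n_segments, "segment_s": self.segment_s,
                "window": "hann", "overlap": 0.5}


@dataclass(frozen=True)
class OperatingBoundary:
    """An individualized operating boundary C* on the CMFI scale."""

    C_star: float
    method: str
    quantile_q: float
    n_support: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.C_star <= 1.0:
            raise ValueError(f"C_star must lie in [0,1], got {self.C_star}")
        if self.method not in ("challenge_response", "normative_quantile"):
            raise ValueError(f"unknown boundary method {self.method!r}")
        if not 0 < self.quantile_q < 1:
            raise ValueError("quantile_q must lie in (0,1)")


@dataclass(frozen=True)
class GCCContextReading:
    """A context-conditional reading of a GCC value."""

    gcc: float
    elevated: bool
    scd_level: str
    neq_state: str
    label: str


def gait_phase(events: GaitEvents, grid: np.ndarray, foot: str = "L") -> SampledSeries:
    """Gait phase on a time grid: linear 0 -> 2*pi between same-foot strikes.

    Phase is 0 at each reference-foot heel strike and wraps at the next one.
    Grid points outside the covered span take the boundary phases (0 before
    the first strike, approaching 2*pi after the last).  Requires at least
    3 same-foot events.
    """
    strikes = events.foot_times(foot)
    if strikes.size < 3:
        raise ValueError(f"gait_phase: need >= 3 '{foot}'-foot events, got {strikes.size}")
    t = np.asarray(grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("grid must be a 1-D array of >= 2 timestamps")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("grid must be uniform and strictly increasing")
    # stride index and fractional position within the stride
    idx = np.clip(np.searchsorted(strikes, t, side="right") - 1, 0, strikes.size - 2)
    frac = (t - strikes[idx]) / (strikes[idx + 1] - strikes[idx])
    phase = 2.0 * np.pi * np.clip(frac, 0.0, 1.0 - 1e-12)
    return SampledSeries(t0=float(t[0]), fs=1.0 / float(dt[0]), values=phase,
                         units="rad", epoch_s=max(1.0, float(t[-1] - t[0])))


def gait_frequency(events: GaitEvents, foot: str = "L") -> float:
    """Gait (stride) frequency: reciprocal of the median same-foot stride time."""
    strides = events.stride_times(foot)
    if strides.size < 2:
        raise ValueError(f"gait_frequency: need >= 3 '{foot}'-foot events")
    return 1.0 / float(np.median(strides))


def gcc(
    theta_env: SampledSeries,
    phase: SampledSeries,
    f_gait: float,
    est: CoherenceSettings | None = None,
) -> float:
    """Gait-cognition coherence at the gait frequency, in [0, 1].

    Magnitude-squared coherence between the theta envelope and cos(phase),
    Welch-averaged (Hann, 50% overlap, ``est.n_segments`` segments of
    ``est.segment_s`` seconds), read off at the frequency bin nearest
    ``f_gait``.  Zero-variance inputs are an error (coherence undefined).
    """
    if est is None:
        est = CoherenceSettings()
    _check_common_grid(theta_env, phase)
    if f_gait <= 0:
        raise ValueError("f_gait must be positive")
    x = np.asarray(theta_env.values, dtype=float)
    y = np.cos(np.asarray(phase.values, dtype=float))
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("gcc: zero-variance input channel, coherence undefined")
    fs = theta_env.fs
    nperseg = int(round(est.segment_s * fs))
    min_len = nperseg + (est.n_segments - 1) * (nperseg - nperseg // 2)
    if x.size < min_len:
        raise ValueError(
            f"record too short for {est.n_segments} Welch segments of {est.segment_s} s "
            f"at 50% overlap: need {min_len} samples, have {x.size}"
        )
    f, cxy = sps.coherence(x, y, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2)
    k = int(np.argmin(np.abs(f - f_gait)))
    return float(np.clip(cxy[k], 0.0, 1.0))


_RULES = {
    # (elevated, scd_level, neq_state) -> label
    (True, "low", "degraded"): "compensatory_overcontrol",
    (True, "high", "preserved"): "adaptive_recruitment",
}


def interpret_gcc(
    gcc_value: float,
    scd_level: str,
    neq_state: str,
    elevation_threshold: float,
) -> GCCContextReading:
    """Context-conditional reading of a coherence value.

    Elevated GCC in a low-demand environment with degraded efficiency reads
    as compensatory over-control (reduced automaticity); elevated GCC in a
    high-demand environment with preserved efficiency reads as adaptive
    recruitment; every other cell of the rule table — including any
    non-elevated GCC — is indeterminate.
    """
    if not 0.0 <= gcc_value <= 1.0:
        raise ValueError(f"gcc must lie in [0,1], got {gcc_value}")
    if scd_level not in ("low", "high"):
        raise ValueError("scd_level must be 'low' or 'high'")
    if neq_state not in ("degraded", "preserved"):
        raise ValueError("neq_state must be 'degraded' or 'preserved'")
    elevated = gcc_value > elevation_threshold
    label = _RULES.get((elevated, scd_level, neq_state), "indeterminate")
    return GCCContextReading(gcc=gcc_value, elevated=elevated,
                             scd_level=scd_level, neq_state=neq_state, label=label)


def estimate_boundary(
    challenge_sessions: list[tuple[SampledSeries, list[float]]] | None = None,
    normative_cmfi: np.ndarray | None = None,
    method: str = "challenge_response",
    q: float | None = None,
    pre_failure_s: float = 5.0,
) -> OperatingBoundary:
    """Estimate an individualized operating boundary C*.

    challenge_response: C* is the q-quantile (default q = 0.10, the lower
    tail) of CMFI observed in the ``pre_failure_s`` seconds preceding
    instability-failure events across challenge sessions — the least demand
    seen to precede failure, a conservative boundary.  Requires at least 5
    failure-preceding epochs.

    normative_quantile: C* is the q-quantile (default q = 0.90) of at least
    20 in-stratum CMFI samples.

    Insufficient support is an error; there is no silent universal default.
    """
    if method == "challenge_response":
        q = 0.10 if q is None else q
        if not challenge_sessions:
            raise ValueError("challenge_response boundary requires challenge sessions")
        pre: list[np.ndarray] = []
        n_epochs = 0
        for series, failures in challenge_sessions:
            for t_fail in failures:
                i_lo = int(np.ceil((t_fail - pre_failure_s - series.t0) * series.fs - 1e-9))
                i_hi = int(np.ceil((t_fail - series.t0) * series.fs - 1e-9))
                i_lo, i_hi = max(i_lo, 0), min(i_hi, series.n)
                if i_hi > i_lo:
                    seg = series.values[i_lo:i_hi]
                    seg = seg[np.isfinite(seg)]
                    if seg.size:
                        pre.append(seg)
                        n_epochs += 1
        if n_epochs < 5:
            raise ValueError(
                f"insufficient support for challenge_response boundary: "
                f"{n_epochs} failure-preceding epochs, need >= 5"
            )
        samples = np.concatenate(pre)
        c_star = float(np.quantile(samples, q, method="linear"))
        return OperatingBoundary(C_star=float(np.clip(c_star, 0, 1)),
                                 method=method, quantile_q=q, n_support=n_epochs)
    if method == "normative_quantile":
        q = 0.90 if q is None else q
        if normative_cmfi is None:
            raise ValueError("normative_quantile boundary requires in-stratum CMFI samples")
        samples = np.asarray(normative_cmfi, dtype=float).ravel()
        samples = samples[np.isfinite(samples)]
        if samples.size < 20:
            raise ValueError(
                f"insufficient support for normative_quantile boundary: "
                f"{samples.size} samples, need >= 20"
            )
        c_star = float(np.quantile(samples, q, method="linear"))
        return OperatingBoundary(C_star=float(np.clip(c_star, 0, 1)),
                                 method=method, quantile_q=q, n_support=int(samples.size))
    raise ValueError(f"unknown boundary method {method!r}")


def cmh(boundary: OperatingBoundary, cmfi_current: float) -> float:
    """Cognitive-Motor Headroom: CMH = C* - CMFI_current, in [-1, 1].

    Positive: operating below the modeled boundary (reserve available).
    Near zero: limited reserve.  Negative: operating beyond the modeled safe
    zone — sustained negative CMH is the caller's persistence rule to apply;
    this function reports the instantaneous value.
    """
    if not 0.0 <= cmfi_current <= 1.0:
        raise ValueError(f"cmfi_current must lie in [0,1], got {cmfi_current}")
    return float(boundary.C_star - cmfi_current)
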