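"""Perturbation-recovery scoring: per-event BRC and per-bin aggregation.

For each perturbation event, recovery time t_rec is the earliest time after
onset at which the instability signal I(t) stays below a preregistered
criterion c for a full dwell period; the residual error E_res is the mean
instability over a fixed post-recovery window.  The event score

    BRC_k = (1 - E_res_k) * exp(-t_rec_k / tau)

lies in [0, 1]: 1 for instantaneous, residual-free recovery, falling with
both slower return and worse residual instability.  Events that never meet
the criterion within the search window are censored and score 0 (the
conservative limit as t_rec -> infinity).  Session-level BRC is the median
of event scores within caller-defined perturbation-magnitude bins.

All criterion parameters (c, dwell, windows, tau) must be fixed before
outcome analysis; they are echoed verbatim into every output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import SampledSeries

__all__ = [
    "PerturbationEvent",
    "RecoveryCriterion",
    "RecoveryResult",
    "detect_recovery",
    "residual_error",
    "brc_event",
    "score_event",
    "brc_aggregate",
]


@dataclass(frozen=True)
class PerturbationEvent:
    """A perturbation onset with its standardized magnitude-bin label."""

    onset: float
    magnitude_bin: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.onset):
            raise ValueError("onset must be finite")
        if not self.magnitude_bin:
            raise ValueError("magnitude_bin label must be non-empty")


@dataclass(frozen=True)
class RecoveryCriterion:
    """Preregistered recovery criterion on the instability signal.

    threshold: recovery requires I(t) < threshold; dwell: for at least this
    long; max_window: search horizon after onset (censored beyond);
    residual_window: averaging window for E_res after recovery; tau: the
    recovery time constant of the exponential discount.
    """

    threshold: float = 0.5
    dwell: float = 1.0
    max_window: float = 10.0
    residual_window: float = 2.0
    tau: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must lie in (0,1), got {self.threshold}")
        for name in ("dwell", "max_window", "residual_window", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dwell > self.max_window:
            raise ValueError("dwell must not exceed max_window")

    def as_dict(self) -> dict[str, float]:
        return {
            "threshold": self.threshold, "dwell": self.dwell,
            "max_window": self.max_window,
            "residual_window": self.residual_window, "tau": self.tau,
        }


@dataclass(frozen=True)
class RecoveryResult:
    """Per-event recovery outcome; censored events carry brc = 0."""

    event: PerturbationEvent
    t_rec: float
    e_res: float
    brc: float
    censored: bool

    def __post_init__(self) -> None:
        if self.censored:
            if self.brc != 0.0:
                raise ValueError("censored events must score brc = 0")
        else:
            if not 0.0 <= self.brc <= 1.0:
                raise ValueError(f"brc must lie in [0,1], got {self.brc}")
            if not 0.0 <= self.e_res <= 1.0:
                raise ValueError(f"e_res must lie in [0,1], got {self.e_res}")
            if self.t_rec < 0:
                raise ValueError("t_rec must be non-negative")


def _slice_indices(I: SampledSeries, t_lo: float, t_hi: float) -> tuple[int, int]:
    """Sample indices covering [t_lo, t_hi) on I's grid (half-open)."""
    i_lo = int(np.ceil((t_lo - I.t0) * I.fs - 1e-9))
    i_hi = int(np.ceil((t_hi - I.t0) * I.fs - 1e-9))
    return max(i_lo, 0), min(i_hi, I.n)


def _check_coverage(I: SampledSeries, t_lo: float, t_hi: float, what: str) -> None:
    if I.t0 > t_lo + 1e-9 or I.t0 + (I.n - 1) / I.fs < t_hi - 1.0 / I.fs - 1e-9:
        raise ValueError(f"instability series does not cover the {what} [{t_lo}, {t_hi})")
    i_lo, i_hi = _slice_indices(I, t_lo, t_hi)
    t = I.times[i_lo:i_hi]
    bad = ~I.quality[I.epoch_index(t)]
    if np.any(bad):
        gap_t = t[bad]
        raise ValueError(
            f"quality gap inside the {what}: flagged-bad samples at "
            f"t={gap_t[0]:.3f}..{gap_t[-1]:.3f} s"
        )


def detect_recovery(
    I: SampledSeries, event: PerturbationEvent, crit: RecoveryCriterion
) -> tuple[float, bool]:
    """Earliest dwell-sustained return of I(t) below the criterion.

    Returns ``(t_rec, censored)``: t_rec is the delay from onset to the
    first sample time tau_0 >= onset with I < threshold throughout
    [tau_0, tau_0 + dwell); censored is True (t_rec = max_window) when no
    such time exists within the search horizon.  A quality gap overlapping
    the search window is an error.
    """
    onset = event.onset
    _check_coverage(I, onset, onset + crit.max_window, "recovery search window")
    i_on, i_end = _slice_indices(I, onset, onset + crit.max_window)
    below = I.values[i_on:i_end] < crit.threshold
    n_dwell = max(1, int(round(crit.dwell * I.fs)))
    # sustained[j] == True iff below[j : j+n_dwell] are all True
    if below.size < n_dwell:
        return crit.max_window, True
    csum = np.concatenate([[0], np.cumsum(below.astype(int))])
    window_sums = csum[n_dwell:] - csum[:-n_dwell]
    sustained = window_sums == n_dwell
    hits = np.flatnonzero(sustained)
    if hits.size == 0:
        return crit.max_window, True
    t_hit = I.times[i_on + hits[0]]
    return max(0.0, float(t_hit - onset)), False


def residual_error(
    I: SampledSeries, event: PerturbationEvent, t_rec: float, crit: RecoveryCriterion
) -> float:
    """Mean instability over the fixed post-recovery window — E_res in [0, 1].

    Defined only for non-censored recoveries; a censored event scores
    brc = 0 directly and never reaches this computation.
    """
    if t_rec < 0 or not math.isfinite(t_rec):
        raise ValueError("residual_error: t_rec must be finite and non-negative (not censored)")
    t_lo = event.onset + t_rec
    t_hi = t_lo + crit.residual_window
    _check_coverage(I, t_lo, t_hi, "residual window")
    i_lo, i_hi = _slice_indices(I, t_lo, t_hi)
    if i_hi <= i_lo:
        raise ValueError("residual window contains no samples")
    e = float(np.mean(I.values[i_lo:i_hi]))
    return float(np.clip(e, 0.0, 1.0))


def brc_event(t_rec: float, e_res: float, tau: float) -> float:
    """Event recovery score: (1 - E_res) * exp(-t_rec / tau), in [0, 1]."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if not 0.0 <= e_res <= 1.0:
        raise ValueError(f"e_res must lie in [0,1], got {e_res}")
    if t_rec < 0:
        raise ValueError(f"t_rec must be non-negative, got {t_rec}")
    return (1.0 - e_res) * math.exp(-t_rec / tau)


def score_event(
    I: SampledSeries, event: PerturbationEvent, crit: RecoveryCriterion
) -> RecoveryResult:
    """Full per-event pipeline: detect recovery, residual error, BRC score."""
    t_rec, censored = detect_recovery(I, event, crit)
    if censored:
        return RecoveryResult(event=event, t_rec=t_rec, e_res=1.0, brc=0.0, censored=True)
    e_res = residual_error(I, event, t_rec, crit)
    return RecoveryResult(event=event, t_rec=t_rec, e_res=e_res,
                          brc=brc_event(t_rec, e_res, crit.tau), censored=False)


def brc_aggregate(results: list[RecoveryResult]) -> dict[str, float]:
    """Per-bin median of event BRC scores.

    Even-count bins use the midpoint of the two central values (numpy's
    median convention).  Bins arise from the events' magnitude labels;
    there are no empty bins by construction.
    """
    bins: dict[str, list[float]] = {}
    for r in results:
        bins.setdefault(r.event.magnitude_bin, []).append(r.brc)
    return {b: float(np.median(v)) for b, v in sorted(bins.items())}
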