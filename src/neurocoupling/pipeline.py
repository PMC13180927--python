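"""Session orchestration: from aligned channels to index series.

A :class:`SessionData` bundle holds the aligned per-session channels (EEG
band-power envelopes, heel-strike events, sway/pressure channels,
perturbation list).  :func:`compute_session_indices` derives N(t), G(t),
I(t) on a common analysis-window grid, fuses them into CMFI, builds the
motor-performance composite and NEQ, and applies the quality-governance
rules: a missing modality yields an explicitly partial CMFI and suppresses
any index whose definition needs that modality, with a reason code — values
are never imputed.

Reference percentiles can be supplied (between-person / between-condition
strata) or fitted within the session; which one is scientifically
appropriate depends on the question, so both are supported and the choice
is recorded in the run manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    IndexSeries,
    ModalityQuality,
    ReferenceDistribution,
    SampledSeries,
    WeightVector,
    fit_reference,
    normalize,
)
from .coupling import CoherenceSettings, gait_frequency, gait_phase, gcc
from .indices import DEFAULT_EPSILON, cmfi, motor_performance, neq
from .recovery import RecoveryCriterion, brc_aggregate, score_event
from .signals import (
    GaitEvents,
    _windowed_gait_series,
    alpha_suppression,
    gait_cost,
    instability,
    neural_demand,
    step_asymmetry,
    stride_variability,
)
from .recovery import PerturbationEvent

__all__ = [
    "SessionData",
    "PipelineConfig",
    "SessionResult",
    "REFERENCE_FEATURES",
    "collect_raw_features",
    "fit_session_references",
    "compute_session_indices",
]

#: Raw features that need a reference distribution for normalization.
REFERENCE_FEATURES = (
    "theta", "alpha", "beta", "asym", "stride_cv", "cadence", "ml", "ap", "shift",
)


@dataclass
class SessionData:
    """Aligned per-session channels; ``None`` marks a missing modality."""

    theta: SampledSeries | None = None
    alpha: SampledSeries | None = None
    beta: SampledSeries | None = None
    gait: GaitEvents | None = None
    ml: SampledSeries | None = None
    ap: SampledSeries | None = None
    shift: SampledSeries | None = None
    perturbations: tuple[PerturbationEvent, ...] = ()

    @property
    def has_neural(self) -> bool:
        return self.theta is not None and self.alpha is not None and self.beta is not None

    @property
    def has_gait(self) -> bool:
        return self.gait is not None

    @property
    def has_instability(self) -> bool:
        return self.ml is not None and self.ap is not None and self.shift is not None

    @property
    def span(self) -> tuple[float, float]:
        t0s, t1s = [], []
        for s in (self.theta, self.alpha, self.beta, self.ml, self.ap, self.shift):
            if s is not None:
                t0s.append(s.t0)
                t1s.append(s.t0 + s.duration)
        if self.gait is not None:
            t0s.append(float(self.gait.times[0]))
            t1s.append(float(self.gait.times[-1]))
        if not t0s:
            raise ValueError("session has no channels at all")
        return min(t0s), max(t1s)


@dataclass
class PipelineConfig:
    """All tunables that affect emitted numbers (echoed into the manifest)."""

    window_s: float = 5.0
    epsilon: float = DEFAULT_EPSILON
    stratum_label: str = "session"
    cmfi_weights: WeightVector = field(
        default_factory=lambda: WeightVector.uniform(("neural", "gait", "instability")))
    neural_weights: WeightVector = field(
        default_factory=lambda: WeightVector.uniform(("theta", "alpha_sup", "beta_ctrl")))
    motor_weights: WeightVector = field(
        default_factory=lambda: WeightVector.uniform(("speed", "gait_cost_inv", "instability_inv")))
    scd_weights: WeightVector = field(
        default_factory=lambda: WeightVector.uniform(("PC", "LV", "TD", "VTA")))
    recovery: RecoveryCriterion = field(default_factory=RecoveryCriterion)
    coherence: CoherenceSettings = field(default_factory=CoherenceSettings)
    references: dict[str, ReferenceDistribution] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "window_s": self.window_s,
            "epsilon": self.epsilon,
            "stratum_label": self.stratum_label,
            "cmfi_weights": self.cmfi_weights.as_dict(),
            "neural_weights": self.neural_weights.as_dict(),
            "motor_weights": self.motor_weights.as_dict(),
            "scd_weights": self.scd_weights.as_dict(),
            "recovery_criterion": self.recovery.as_dict(),
            "coherence": self.coherence.as_dict(),
            "references": {
                k: {"stratum": r.stratum_label, "q10": r.q10_ref, "q90": r.q90_ref}
                for k, r in sorted(self.references.items())
            },
            "motor_performance_definition":
                "M = w1*cadence_norm + w2*(1-G) + w3*(1-I)",
        }


@dataclass
class SessionResult:
    """Everything one session yields, plus reason codes for absent indices."""

    N: SampledSeries | None
    G: SampledSeries | None
    I_win: SampledSeries | None
    I_full: SampledSeries | None
    M: SampledSeries | None
    cmfi: IndexSeries | None
    neq: IndexSeries | None
    gcc: float | None
    f_gait: float | None
    brc_by_bin: dict[str, float]
    brc_events: list
    qualities: list[ModalityQuality]
    reasons: dict[str, str]

    def mean(self, series: IndexSeries | SampledSeries | None) -> float:
        if series is None:
            return math.nan
        s = series.series if isinstance(series, IndexSeries) else series
        good = s.quality[s.epoch_index(s.times)]
        vals = s.values[good]
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals)) if vals.size else math.nan

    @property
    def mean_cmfi(self) -> float:
        return self.mean(self.cmfi)

    @property
    def mean_neq(self) -> float:
        return self.mean(self.neq)


def _cadence_stat(sub: GaitEvents) -> float | None:
    strides = np.concatenate([sub.stride_times("L"), sub.stride_times("R")])
    if strides.size < 1:
        return None
    m = float(np.mean(strides))
    return 1.0 / m if m > 0 else None


def collect_raw_features(data: SessionData, window_s: float) -> dict[str, np.ndarray]:
    """Raw (pre-normalization) feature samples from one session, per feature.

    Used to fit stratum reference percentiles, typically pooled across the
    sessions that define the stratum.
    """
    out: dict[str, np.ndarray] = {}
    for name in ("theta", "alpha", "beta", "ml", "ap", "shift"):
        s = getattr(data, name)
        if s is not None:
            good = s.quality[s.epoch_index(s.times)]
            out[name] = s.values[good]
    if data.gait is not None:
        t0, t1 = data.span
        for name, series in (
            ("asym", step_asymmetry(data.gait, window_s, t_start=t0, t_end=t1)),
            ("stride_cv", stride_variability(data.gait, window_s, t_start=t0, t_end=t1)),
            ("cadence", _windowed_gait_series(data.gait, window_s, _cadence_stat, 4, t0, t1)),
        ):
            out[name] = series.values[series.quality]
    return out


def fit_session_references(
    datas: list[SessionData], window_s: float, stratum_label: str
) -> dict[str, ReferenceDistribution]:
    """Fit reference percentiles on features pooled across sessions.

    Pooling across the sessions of a condition/cohort gives a between-person
    (or between-session) stratum reference; passing a single session gives a
    within-session reference.
    """
    pooled: dict[str, list[np.ndarray]] = {}
    for d in datas:
        for k, v in collect_raw_features(d, window_s).items():
            pooled.setdefault(k, []).append(v)
    refs = {}
    for k, chunks in pooled.items():
        samples = np.concatenate(chunks)
        if samples.size >= 10:
            try:
                refs[k] = fit_reference(samples, stratum_label)
            except ValueError:
                pass  # degenerate spread: leave the feature without a reference
    return refs


def _block_average(s: SampledSeries, t_start: float, window_s: float, n_win: int) -> SampledSeries:
    """Mean of a dense series over non-overlapping analysis windows.

    A window is good only if every covering source epoch is good and it
    contains at least one sample.
    """
    vals = np.full(n_win, np.nan)
    qual = np.zeros(n_win, dtype=bool)
    for k in range(n_win):
        lo, hi = t_start + k * window_s, t_start + (k + 1) * window_s
        i_lo = int(np.ceil((lo - s.t0) * s.fs - 1e-9))
        i_hi = int(np.ceil((hi - s.t0) * s.fs - 1e-9))
        i_lo, i_hi = max(i_lo, 0), min(i_hi, s.n)
        if i_hi <= i_lo:
            continue
        t = s.times[i_lo:i_hi]
        if np.all(s.quality[s.epoch_index(t)]):
            vals[k] = float(np.mean(s.values[i_lo:i_hi]))
            qual[k] = True
    return SampledSeries(t0=t_start, fs=1.0 / window_s, values=vals, units=s.units,
                         quality=qual, epoch_s=window_s)


def compute_session_indices(
    data: SessionData,
    config: PipelineConfig | None = None,
    refs: dict[str, ReferenceDistribution] | None = None,
    compute_gcc: bool = True,
) -> SessionResult:
    """Derive all indices one session supports, on the analysis-window grid.

    ``refs`` (or ``config.references``) supply stratum percentiles; any
    feature without a supplied reference gets a within-session fit.  Missing
    modalities make CMFI partial and suppress NEQ/GCC/BRC as their
    definitions require, with reason codes in ``result.reasons``.
    """
    config = config or PipelineConfig()
    if not (data.has_neural or data.has_gait or data.has_instability):
        raise ValueError("all modalities missing: no index can be computed")

    refs = dict(config.references) | dict(refs or {})
    missing = [k for k in REFERENCE_FEATURES if k not in refs]
    if missing:
        fitted = fit_session_references([data], config.window_s, config.stratum_label)
        for k in missing:
            if k in fitted:
                refs[k] = fitted[k]

    t0, t1 = data.span
    w = config.window_s
    n_win = max(1, math.floor((t1 - t0) / w + 1e-9))
    t_end = t0 + n_win * w
    reasons: dict[str, str] = {}

    N_win = N_full = None
    if data.has_neural and all(k in refs for k in ("theta", "alpha", "beta")):
        theta_n = data.theta.replace_values(normalize(data.theta.values, refs["theta"]))
        alpha_s = alpha_suppression(data.alpha, refs["alpha"])
        beta_n = data.beta.replace_values(normalize(data.beta.values, refs["beta"]))
        N_full = neural_demand(theta_n, alpha_s, beta_n, config.neural_weights)
        N_win = _block_average(N_full, t0, w, n_win)
    elif data.has_neural:
        reasons["N"] = "no usable reference for an EEG envelope channel (degenerate spread or too few samples)"
    else:
        reasons["N"] = "neural modality absent (no eeg_envelopes input)"

    G_win = speed_win = None
    if data.has_gait and all(k in refs for k in ("asym", "stride_cv")):
        asym = step_asymmetry(data.gait, w, refs["asym"], t_start=t0, t_end=t_end)
        var = stride_variability(data.gait, w, refs["stride_cv"], t_start=t0, t_end=t_end)
        G_win = gait_cost(asym, var)
        if "cadence" in refs:
            cad = _windowed_gait_series(data.gait, w, _cadence_stat, 4, t0, t_end)
            cv = cad.values.copy()
            cv[cad.quality] = normalize(cv[cad.quality], refs["cadence"])
            speed_win = cad.replace_values(cv, units="normalized")
    elif data.has_gait:
        reasons["G"] = "no usable reference for a gait feature (too few analysis windows or degenerate spread)"
    else:
        reasons["G"] = "gait modality absent (no gait_events input)"

    I_win = I_full = None
    if data.has_instability and all(k in refs for k in ("ml", "ap", "shift")):
        I_full = instability(data.ml, data.ap, data.shift,
                             (refs["ml"], refs["ap"], refs["shift"]))
        I_win = _block_average(I_full, t0, w, n_win)
    elif data.has_instability:
        reasons["I"] = "no usable reference for a sway channel (degenerate spread or too few samples)"
    else:
        reasons["I"] = "instability modality absent (no sway input)"

    qualities = []
    for name, s in (("neural", N_win), ("gait", G_win), ("instability", I_win)):
        if s is not None:
            qualities.append(ModalityQuality(name, s.usable_fraction))

    cmfi_series = None
    if N_win is not None or G_win is not None or I_win is not None:
        cmfi_series = cmfi(N_win, G_win, I_win, config.cmfi_weights, qualities)

    M_win = neq_series = None
    if N_win is None:
        reasons["NEQ"] = "requires neural demand N(t): " + reasons.get("N", "unavailable")
    elif G_win is None or I_win is None or speed_win is None:
        reasons["NEQ"] = "requires the motor-performance composite (gait + instability)"
    else:
        M_win = motor_performance(speed_win, G_win, I_win, config.motor_weights)
        neq_series = neq(M_win, N_win, config.epsilon, config.stratum_label)

    gcc_val = f_gait = None
    if compute_gcc:
        if data.theta is None:
            reasons["GCC"] = "requires the frontal-theta envelope"
        elif data.gait is None:
            reasons["GCC"] = "requires gait events for the phase reference"
        else:
            try:
                f_gait = gait_frequency(data.gait)
                theta_for_gcc = (
                    data.theta.replace_values(normalize(data.theta.values, refs["theta"]))
                    if "theta" in refs else data.theta
                )
                phase = gait_phase(data.gait, theta_for_gcc.times)
                gcc_val = gcc(theta_for_gcc, phase, f_gait, config.coherence)
            except ValueError as e:
                reasons["GCC"] = str(e)

    brc_events: list = []
    brc_by_bin: dict[str, float] = {}
    if data.perturbations:
        if I_full is None:
            reasons["BRC"] = "requires the instability signal I(t)"
        else:
            for ev in data.perturbations:
                try:
                    brc_events.append(score_event(I_full, ev, config.recovery))
                except ValueError as e:
                    reasons[f"BRC[{ev.onset}]"] = str(e)
            if brc_events:
                brc_by_bin = brc_aggregate(brc_events)

    return SessionResult(
        N=N_win, G=G_win, I_win=I_win, I_full=I_full, M=M_win,
        cmfi=cmfi_series, neq=neq_series, gcc=gcc_val, f_gait=f_gait,
        brc_by_bin=brc_by_bin, brc_events=brc_events,
        qualities=qualities, reasons=reasons,
    )
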