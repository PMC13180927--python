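"""Synthetic multimodal session generator with known ground truth.

Real sessions of this kind — synchronized EEG band-power envelopes, heel
strikes, sway channels, perturbation lists — require instrumented corridors
and human participants.  The generator emulates exactly the statistical
structure the indices consume, nothing more (no biomechanical gait model,
no vestibular simulation): a slowly varying latent demand trace drives the
mean of every channel through configurable coupling gains, Gaussian
observation noise is added, and perturbations inject exponentially decaying
instability pulses whose analytic criterion-crossing times are known.

That makes every index testable end to end: higher latent demand must raise
theta/beta power, suppress alpha, inflate stride variability and sway, and
therefore raise CMFI and depress NEQ — the directional prediction that
:func:`run_h1_experiment` checks at desk scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SampledSeries
from .pipeline import (
    PipelineConfig,
    SessionData,
    compute_session_indices,
    fit_session_references,
)
from .recovery import PerturbationEvent, RecoveryCriterion, detect_recovery

__all__ = [
    "PerturbationSpec",
    "SessionConfig",
    "SyntheticSession",
    "generate_session",
    "run_h1_experiment",
    "recovery_ground_truth_check",
]

# Latent-demand dynamics: AR(1) on a 1 Hz grid.  The 0.95 coefficient gives
# fluctuations with ~20 s correlation time; innovation SD 0.02 keeps the
# stationary SD near 0.064 so the trace stays close to its set level.
_AR_COEF = 0.95
_AR_INNOV_SD = 0.02

# Channel means: base + gain * demand.  Bases are in arbitrary band-power /
# sway units; gains are calibrated so that moving the demand set-point from
# 0.2 to 0.8 shifts mean CMFI by roughly 0.3 under default weights.
_THETA_BASE = 1.0
_ALPHA_BASE = 3.0
_BETA_BASE = 0.8
_SWAY_BASE = 0.2
_CV_BASE = 0.03  # stride-time CV at zero demand


@dataclass(frozen=True)
class PerturbationSpec:
    """An injected perturbation: onset, bin label, pulse peak and decay."""

    onset: float
    magnitude_bin: str
    injected_peak: float = 1.0
    decay_s: float = 2.0

    def __post_init__(self) -> None:
        if self.injected_peak <= 0 or self.decay_s <= 0:
            raise ValueError("injected_peak and decay_s must be positive")


@dataclass(frozen=True)
class SessionConfig:
    """Generative parameters of one synthetic session."""

    duration: float = 60.0
    fs: float = 25.0
    scd_true: float = 0.5
    gain_theta: float = 0.6
    gain_alpha: float = 0.6
    gain_beta: float = 0.45
    gain_gaitvar: float = 0.04
    gain_sway: float = 0.15
    noise_sd: float = 0.5
    stride_mean: float = 1.1
    gcc_mod_depth: float = 0.0
    perturbations: tuple[PerturbationSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if not self.duration * self.fs >= 256:
            problems.append(f"duration*fs must be >= 256, got {self.duration * self.fs}")
        if self.fs <= 0:
            problems.append("fs must be positive")
        if not 0.0 <= self.scd_true <= 1.0:
            problems.append(f"scd_true must lie in [0,1], got {self.scd_true}")
        for name in ("gain_theta", "gain_alpha", "gain_beta", "gain_gaitvar",
                     "gain_sway", "noise_sd", "gcc_mod_depth"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.stride_mean <= 0:
            problems.append(f"stride_mean must be positive, got {self.stride_mean}")
        for p in self.perturbations:
            if not 0 <= p.onset <= self.duration:
                problems.append(f"perturbation onset {p.onset} outside [0, {self.duration}]")
        if problems:
            raise ValueError("invalid SessionConfig: " + "; ".join(problems))

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "duration", "fs", "scd_true", "gain_theta", "gain_alpha", "gain_beta",
            "gain_gaitvar", "gain_sway", "noise_sd", "stride_mean",
            "gcc_mod_depth", "seed")}
        d["perturbations"] = [
            {"onset": p.onset, "magnitude_bin": p.magnitude_bin,
             "injected_peak": p.injected_peak, "decay_s": p.decay_s}
            for p in self.perturbations
        ]
        return d


@dataclass
class SyntheticSession:
    """Generated channels plus the ground truth that produced them."""

    config: SessionConfig
    eeg: pd.DataFrame          # t, theta, alpha, beta, quality
    gait_events: pd.DataFrame  # t, foot
    sway: pd.DataFrame         # t, ml, ap, shift
    perturbations: pd.DataFrame  # onset, magnitude_bin
    ground_truth: dict = field(default_factory=dict)

    def as_session_data(self) -> SessionData:
        fs = self.config.fs
        t0 = float(self.eeg["t"].iloc[0])
        mk = lambda col, df: SampledSeries(
            t0=t0, fs=fs, values=df[col].to_numpy(), units="au")
        return SessionData(
            theta=mk("theta", self.eeg),
            alpha=mk("alpha", self.eeg),
            beta=mk("beta", self.eeg),
            gait=_events_from_frame(self.gait_events),
            ml=mk("ml", self.sway),
            ap=mk("ap", self.sway),
            shift=mk("shift", self.sway),
            perturbations=tuple(
                PerturbationEvent(float(r.onset), str(r.magnitude_bin))
                for r in self.perturbations.itertuples()
            ),
        )

    def write(self, out_dir: str | Path) -> Path:
        """Write the four CSV schemas plus ground_truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.eeg.to_csv(out / "eeg_envelopes.csv", index=False, float_format="%.17g")
        self.gait_events.to_csv(out / "gait_events.csv", index=False, float_format="%.17g")
        self.sway.to_csv(out / "sway.csv", index=False, float_format="%.17g")
        self.perturbations.to_csv(out / "perturbations.csv", index=False, float_format="%.17g")
        (out / "ground_truth.json").write_text(json.dumps(self.ground_truth, indent=1))
        return out


def _events_from_frame(df: pd.DataFrame):
    from .signals import GaitEvents

    return GaitEvents(df["t"].to_numpy(dtype=float), tuple(str(f) for f in df["foot"]))


def _latent_demand(cfg: SessionConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Latent demand on a 1 Hz grid: set level + AR(1) fluctuation, in [0,1]."""
    n = int(math.ceil(cfg.duration)) + 1
    stat_sd = _AR_INNOV_SD / math.sqrt(1 - _AR_COEF**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, stat_sd)
    innov = rng.normal(0.0, _AR_INNOV_SD, size=n - 1)
    for i in range(1, n):
        x[i] = _AR_COEF * x[i - 1] + innov[i - 1]
    t_lat = np.arange(n, dtype=float)
    return t_lat, np.clip(cfg.scd_true + x, 0.0, 1.0)


def _gait_times(cfg: SessionConfig, demand_at, rng: np.random.Generator):
    """Alternating heel strikes; stride CV and step-split jitter scale with demand."""
    times, feet = [], []
    t = float(rng.uniform(0, 0.2))
    foot = "L"
    while t < cfg.duration:
        d = float(demand_at(t))
        cv = _CV_BASE + cfg.gain_gaitvar * d
        stride = cfg.stride_mean * max(0.2, 1.0 + rng.normal(0.0, cv))
        split = float(np.clip(0.5 + rng.normal(0.0, cv / 2), 0.3, 0.7))
        for frac in (split, 1.0 - split):
            times.append(t)
            feet.append(foot)
            foot = "R" if foot == "L" else "L"
            t += stride * frac
    return np.asarray(times), tuple(feet)


def generate_session(cfg: SessionConfig) -> SyntheticSession:
    """Generate one fully synthetic session, reproducible from its seed.

    Latent demand D(t) (AR(1) around ``scd_true``) drives every channel:
    theta and beta band power and sway rise with demand, alpha power falls
    (alpha suppression), stride-time variability and step asymmetry grow.
    Perturbations add exponentially decaying pulses to all sway channels.
    ``gcc_mod_depth`` > 0 additionally modulates the theta envelope at the
    actual gait phase — the positive control for the coherence index.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    t_lat, d_lat = _latent_demand(cfg, rng)
    D = np.interp(t, t_lat, d_lat)
    demand_at = lambda x: np.interp(x, t_lat, d_lat)

    noise = lambda scale=1.0: rng.normal(0.0, cfg.noise_sd * scale, size=n)
    theta = np.maximum(_THETA_BASE + cfg.gain_theta * D + noise(), 0.0)
    alpha = np.maximum(_ALPHA_BASE - cfg.gain_alpha * D + noise(), 0.0)
    beta = np.maximum(_BETA_BASE + cfg.gain_beta * D + noise(), 0.0)

    gait_t, gait_f = _gait_times(cfg, demand_at, rng)

    if cfg.gcc_mod_depth > 0:
        from .coupling import gait_phase
        from .signals import GaitEvents

        events = GaitEvents(gait_t, gait_f)
        phase = gait_phase(events, t)
        theta = np.maximum(theta + cfg.gcc_mod_depth * np.cos(phase.values), 0.0)

    pulse = np.zeros(n)
    for p in cfg.perturbations:
        after = t >= p.onset
        pulse[after] += p.injected_peak * np.exp(-(t[after] - p.onset) / p.decay_s)

    # Sway-amplitude envelopes vary smoothly; low-pass the observation noise
    # (0.5 s moving average) so the instability signal is not sample-to-sample
    # white flicker.
    win = max(1, int(round(0.5 * cfg.fs)))
    kern = np.ones(win) / win
    sway_noise = lambda: np.convolve(noise(0.4), kern, mode="same")
    ml = np.maximum(_SWAY_BASE + cfg.gain_sway * D + pulse + sway_noise(), 0.0)
    ap = np.maximum(_SWAY_BASE + cfg.gain_sway * D + pulse + sway_noise(), 0.0)
    shift = np.maximum(_SWAY_BASE + cfg.gain_sway * D + pulse + sway_noise(), 0.0)

    eeg = pd.DataFrame({"t": t, "theta": theta, "alpha": alpha, "beta": beta,
                        "quality": np.ones(n, dtype=int)})
    gait = pd.DataFrame({"t": gait_t, "foot": list(gait_f)})
    sway = pd.DataFrame({"t": t, "ml": ml, "ap": ap, "shift": shift})
    pert = pd.DataFrame(
        {"onset": [p.onset for p in cfg.perturbations],
         "magnitude_bin": [p.magnitude_bin for p in cfg.perturbations]},
        columns=["onset", "magnitude_bin"],
    )
    ground_truth = {
        "scd_true": cfg.scd_true,
        "seed": cfg.seed,
        "latent_demand_t": t_lat.tolist(),
        "latent_demand": d_lat.tolist(),
        "perturbations": [
            {"onset": p.onset, "magnitude_bin": p.magnitude_bin,
             "injected_peak": p.injected_peak, "decay_s": p.decay_s}
            for p in cfg.perturbations
        ],
        "config": cfg.as_dict(),
    }
    return SyntheticSession(config=cfg, eeg=eeg, gait_events=gait, sway=sway,
                            perturbations=pert, ground_truth=ground_truth)


_H1_INVARIANT_FIELDS = (
    "duration", "fs", "gain_theta", "gain_alpha", "gain_beta", "gain_gaitvar",
    "gain_sway", "noise_sd", "stride_mean", "gcc_mod_depth", "perturbations",
)


def run_h1_experiment(
    n_per_arm: int,
    low_cfg: SessionConfig,
    high_cfg: SessionConfig,
    seeds,
    pipeline_config: PipelineConfig | None = None,
) -> dict:
    """Directional two-arm experiment: does higher latent demand raise CMFI and lower NEQ?

    The two arms must be identical except for ``scd_true`` (a confound
    guard).  For each replicate seed, ``n_per_arm`` sessions are generated
    per arm, reference percentiles are fitted on the pooled sessions of both
    arms (the shared stratum), and per-arm mean CMFI and NEQ are compared.
    Returns per-replicate arm means, differences, and their signs, plus the
    count of replicates with the predicted direction (CMFI higher, NEQ lower
    in the high-demand arm).
    """
    if n_per_arm < 10:
        raise ValueError(f"n_per_arm must be >= 10, got {n_per_arm}")
    for f in _H1_INVARIANT_FIELDS:
        if getattr(low_cfg, f) != getattr(high_cfg, f):
            raise ValueError(
                f"arms differ in '{f}': the two configs may differ only in scd_true"
            )
    pc = pipeline_config or PipelineConfig()
    replicates = []
    n_cmfi_positive = n_neq_negative = 0
    for rep, seed in enumerate(seeds):
        arm_means = {}
        datas = {}
        for arm, cfg in (("low", low_cfg), ("high", high_cfg)):
            arm_idx = 0 if arm == "low" else 1
            sessions = [
                generate_session(replace(
                    cfg, seed=(int(seed) * 20011 + arm_idx * 4001 + i) % (2**31 - 1)))
                for i in range(n_per_arm)
            ]
            datas[arm] = [s.as_session_data() for s in sessions]
        refs = fit_session_references(
            datas["low"] + datas["high"], pc.window_s, stratum_label="h1_pooled")
        for arm in ("low", "high"):
            cmfi_means, neq_means = [], []
            for d in datas[arm]:
                res = compute_session_indices(d, pc, refs=refs, compute_gcc=False)
                cmfi_means.append(res.mean_cmfi)
                neq_means.append(res.mean_neq)
            arm_means[arm] = {
                "cmfi": float(np.nanmean(cmfi_means)),
                "neq": float(np.nanmean(neq_means)),
            }
        d_cmfi = arm_means["high"]["cmfi"] - arm_means["low"]["cmfi"]
        d_neq = arm_means["high"]["neq"] - arm_means["low"]["neq"]
        n_cmfi_positive += d_cmfi > 0
        n_neq_negative += d_neq < 0
        replicates.append({
            "seed": int(seed),
            "low": arm_means["low"], "high": arm_means["high"],
            "delta_cmfi": d_cmfi, "delta_neq": d_neq,
            "sign_cmfi": int(np.sign(d_cmfi)), "sign_neq": int(np.sign(d_neq)),
        })
    n_rep = len(replicates)
    return {
        "n_per_arm": n_per_arm,
        "n_replicates": n_rep,
        "scd_true": {"low": low_cfg.scd_true, "high": high_cfg.scd_true},
        "replicates": replicates,
        "n_cmfi_positive": n_cmfi_positive,
        "n_neq_negative": n_neq_negative,
        "mean_delta_cmfi": float(np.mean([r["delta_cmfi"] for r in replicates])),
        "mean_delta_neq": float(np.mean([r["delta_neq"] for r in replicates])),
    }


def recovery_ground_truth_check(
    cfg: SessionConfig, crit: RecoveryCriterion
) -> list[dict]:
    """Timing error of recovery detection on noiseless injected pulses.

    For each configured perturbation, builds the analytic instability pulse
    I(t) = clamp(peak * exp(-(t - onset)/decay), 0, 1) on the session grid,
    runs the recovery detector, and compares the detected recovery time with
    the closed-form criterion crossing decay * ln(peak / threshold) (zero
    when the pulse never exceeds the threshold).
    """
    out = []
    for p in cfg.perturbations:
        n = int(round((crit.max_window + crit.residual_window) * cfg.fs)) + 1
        t = p.onset + np.arange(n) / cfg.fs
        vals = np.clip(p.injected_peak * np.exp(-(t - p.onset) / p.decay_s), 0.0, 1.0)
        I = SampledSeries(t0=float(t[0]), fs=cfg.fs, values=vals, units="index",
                          epoch_s=crit.max_window + crit.residual_window + 1.0)
        event = PerturbationEvent(p.onset, p.magnitude_bin)
        t_rec, censored = detect_recovery(I, event, crit)
        analytic = (
            p.decay_s * math.log(p.injected_peak / crit.threshold)
            if p.injected_peak > crit.threshold else 0.0
        )
        out.append({
            "onset": p.onset,
            "magnitude_bin": p.magnitude_bin,
            "detected_t_rec": t_rec,
            "analytic_t_rec": analytic,
            "censored": censored,
            "abs_error": abs(t_rec - analytic) if not censored else math.inf,
        })
    return out
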