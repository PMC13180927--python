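"""Composite indices: fused demand (CMFI), environmental demand (SCD), efficiency (NEQ).

CMFI(t) = w_N*N(t) + w_G*G(t) + w_I*I(t) is an instantaneous coupled demand
state in [0, 1].  SCD is a route-level environmental demand index built from
pattern complexity, luminance variance, transition density, and (inverted)
visual-tactile alignment.  NEQ(t) = M(t) / (N(t) + eps) is motor output per
unit neural demand, with a small stabilizing constant guarding the
denominator.

Quality governance is enforced here: a missing modality produces an
explicitly partial index with renormalized weights and reduced confidence —
never an imputed value — and losing every modality is a hard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    IndexSeries,
    IndexValue,
    ModalityQuality,
    SampledSeries,
    WeightVector,
    confidence as _confidence,
    renormalize_weights,
    validate_weights,
)
from .signals import _check_common_grid, _check_unit_interval, _merged_quality

__all__ = [
    "SCDComponents",
    "RouteAnnotation",
    "DEFAULT_EPSILON",
    "cmfi",
    "pattern_complexity",
    "luminance_variance",
    "transition_density",
    "visual_tactile_alignment",
    "scd",
    "motor_performance",
    "neq",
]

#: Default denominator-stabilizing constant for NEQ.
DEFAULT_EPSILON = 0.05

CMFI_MODALITIES = ("neural", "gait", "instability")

TRANSITION_KINDS = ("material", "texture", "color", "level", "edge")


@dataclass(frozen=True)
class SCDComponents:
    """Normalized environmental-demand components, each in [0, 1].

    PC: pattern complexity; LV: luminance variance; TD: transition density;
    VTA: visual-tactile alignment (an agreement proportion — higher
    alignment means lower demand, hence it enters the composite inverted).
    """

    PC: float
    LV: float
    TD: float
    VTA: float

    def __post_init__(self) -> None:
        for name in ("PC", "LV", "TD", "VTA"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"SCD component {name} must lie in [0,1], got {v}")


@dataclass(frozen=True)
class RouteAnnotation:
    """A route's length and its annotated perceptual transitions."""

    path_length: float
    transitions: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        if not (math.isfinite(self.path_length) and self.path_length > 0):
            raise ValueError(f"path_length must be positive, got {self.path_length}")
        for pos, kind in self.transitions:
            if not 0 <= pos <= self.path_length:
                raise ValueError(f"transition position {pos} outside [0, {self.path_length}]")
            if kind not in TRANSITION_KINDS:
                raise ValueError(f"transition kind {kind!r} not in {TRANSITION_KINDS}")


def cmfi(
    N: SampledSeries | None,
    G: SampledSeries | None,
    I: SampledSeries | None,
    w: WeightVector | None = None,
    qualities: list[ModalityQuality] | None = None,
) -> IndexSeries:
    """Cognitive-Motor Fusion Index: CMFI(t) = w_N*N + w_G*G + w_I*I.

    Pass ``None`` for a missing modality: the remaining weights are
    renormalized onto the simplex, the output is flagged ``partial=True``,
    and its confidence reflects only the contributing modalities' quality.
    All three missing is a hard error — no index is emitted.
    """
    if w is None:
        w = WeightVector.uniform(CMFI_MODALITIES)
    if tuple(w.names) != CMFI_MODALITIES:
        raise ValueError(f"CMFI weight vector must be named {CMFI_MODALITIES}")
    present = {name: s for name, s in zip(CMFI_MODALITIES, (N, G, I)) if s is not None}
    if not present:
        raise ValueError("cmfi: all modalities missing — no index can be emitted")
    partial = len(present) < len(CMFI_MODALITIES)
    w_eff = renormalize_weights(w, list(present)) if partial else w

    series_list = list(present.values())
    _check_common_grid(*series_list)
    for name, s in present.items():
        _check_unit_interval(name, s)

    vals = np.zeros(series_list[0].n)
    for name in w_eff.names:
        vals = vals + w_eff[name] * present[name].values
    out = SampledSeries(
        t0=series_list[0].t0, fs=series_list[0].fs,
        values=np.clip(vals, 0.0, 1.0), units="index",
        quality=_merged_quality(*series_list), epoch_s=series_list[0].epoch_s,
    )

    if qualities is None:
        qualities = [
            ModalityQuality(name, present[name].usable_fraction) for name in present
        ]
    conf = _confidence([q for q in qualities if q.modality in present], w_eff)
    return IndexSeries(series=out, confidence=conf, partial=partial,
                       contributing=tuple(present))


def pattern_complexity(image: np.ndarray) -> float:
    """Raw pattern complexity: spectral entropy of a route image, in bits.

    Shannon entropy of the normalized 2-D power-spectrum magnitude with the
    DC bin excluded.  A constant image has zero off-DC power and entropy 0.
    The raw value is normalized downstream against a stratum reference.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError(f"image must be 2-D and at least 16x16, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    spec = np.abs(np.fft.fft2(img)) ** 2
    spec_flat = spec.ravel().copy()
    spec_flat[0] = 0.0  # exclude DC
    total = spec_flat.sum()
    if total <= 0:
        return 0.0
    p = spec_flat[spec_flat > 0] / total
    return float(-(p * np.log2(p)).sum())


def luminance_variance(lux_samples) -> tuple[float, float]:
    """Raw luminance variation: (sample SD in lux, coefficient of variation).

    Both raw values are normalized downstream.  Requires at least two
    strictly positive lux samples.
    """
    lux = np.asarray(lux_samples, dtype=float).ravel()
    if lux.size < 2:
        raise ValueError(f"luminance_variance: need >= 2 samples, got {lux.size}")
    if not np.all(np.isfinite(lux)) or np.any(lux <= 0):
        raise ValueError("luminance_variance: all lux samples must be positive and finite")
    sd = float(np.std(lux, ddof=1))
    return sd, sd / float(np.mean(lux))


def transition_density(route: RouteAnnotation) -> float:
    """Raw transition density: annotated transitions per meter of route."""
    return len(route.transitions) / route.path_length


def visual_tactile_alignment(expected, actual) -> float:
    """Agreement proportion between expected and measured surface classes.

    Already a proportion in [0, 1]; it is not re-normalized.  Higher
    alignment lowers demand, so the SCD composite uses (1 - VTA).
    """
    exp, act = list(expected), list(actual)
    if len(exp) != len(act):
        raise ValueError(f"visual_tactile_alignment: length mismatch ({len(exp)} vs {len(act)})")
    if not exp:
        raise ValueError("visual_tactile_alignment: empty surface-class lists")
    return sum(e == a for e, a in zip(exp, act)) / len(exp)


def scd(components: SCDComponents, lam: WeightVector | None = None) -> IndexValue:
    """Spatial Cognitive Demand: lam_PC*PC + lam_LV*LV + lam_TD*TD + lam_VTA*(1-VTA).

    One value per route/condition, in [0, 1]; increasing in PC, LV and TD,
    decreasing in VTA.  Weights default to uniform (0.25 each).
    """
    if lam is None:
        lam = WeightVector.uniform(("PC", "LV", "TD", "VTA"))
    if set(lam.names) != {"PC", "LV", "TD", "VTA"}:
        raise ValueError("SCD weights must be named PC, LV, TD, VTA")
    value = (
        lam["PC"] * components.PC
        + lam["LV"] * components.LV
        + lam["TD"] * components.TD
        + lam["VTA"] * (1.0 - components.VTA)
    )
    return IndexValue(value=float(np.clip(value, 0.0, 1.0)), confidence=1.0,
                      partial=False, contributing=("environment",))


def motor_performance(
    gait_speed_norm: SampledSeries,
    G: SampledSeries,
    I: SampledSeries,
    w: WeightVector | None = None,
) -> SampledSeries:
    """Bounded motor-performance composite M(t).

    Default composition: M(t) = w1*speed_norm + w2*(1-G) + w3*(1-I) with
    uniform weights — high speed, low gait cost and low instability all pull
    M toward 1.  The composition is a declared configuration choice (echoed
    in run manifests) so preregistered alternatives can replace it.
    """
    if w is None:
        w = WeightVector.uniform(("speed", "gait_cost_inv", "instability_inv"))
    if len(w.names) != 3:
        raise ValueError("motor_performance requires a 3-component weight vector")
    _check_common_grid(gait_speed_norm, G, I)
    for name, s in (("gait_speed_norm", gait_speed_norm), ("G", G), ("I", I)):
        _check_unit_interval(name, s)
    vals = (
        w.values[0] * gait_speed_norm.values
        + w.values[1] * (1.0 - G.values)
        + w.values[2] * (1.0 - I.values)
    )
    return SampledSeries(
        t0=G.t0, fs=G.fs, values=np.clip(vals, 0.0, 1.0), units="index",
        quality=_merged_quality(gait_speed_norm, G, I), epoch_s=G.epoch_s,
    )


def neq(
    M: SampledSeries,
    N: SampledSeries,
    eps: float = DEFAULT_EPSILON,
    stratum_label: str = "",
) -> IndexSeries:
    """Neuroergonomic Efficiency Quotient: NEQ(t) = M(t) / (N(t) + eps).

    Motor performance per unit neural demand; higher is better.  The
    stabilizing constant ``eps`` caps the attainable value at 1/eps and
    guards against denominator blow-up at near-zero demand.  NEQ is best
    interpreted within person and stratum, so the stratum label travels with
    the output.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    _check_common_grid(M, N)
    _check_unit_interval("M", M)
    _check_unit_interval("N", N)
    vals = M.values / (N.values + eps)
    out = SampledSeries(
        t0=M.t0, fs=M.fs, values=vals,
        units=f"index(stratum={stratum_label})" if stratum_label else "index",
        quality=_merged_quality(M, N), epoch_s=M.epoch_s,
    )
    conf = min(M.usable_fraction, N.usable_fraction)
    return IndexSeries(series=out, confidence=conf, partial=False,
                       contributing=("neural", "gait", "instability"))
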