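"""Core domain types and the normalization / weighting / quality contract.

Every index in the package is a bounded, weighted composite of normalized
observables.  This module owns the three primitives those composites share:

* percentile-clamp normalization against a stratum-specific reference
  distribution (the 10th and 90th percentiles of a reference sample),
* weight vectors constrained to the probability simplex, and
* the quality-governance contract: every emitted index carries a confidence
  channel, an explicit partial flag when a modality is missing, and the list
  of modalities that actually contributed.  Missing modalities are never
  silently imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ReferenceDistribution",
    "WeightVector",
    "SampledSeries",
    "ModalityQuality",
    "IndexValue",
    "IndexSeries",
    "WEIGHT_SUM_TOL",
    "normalize",
    "fit_reference",
    "validate_weights",
    "renormalize_weights",
    "confidence",
]

#: Tolerance on |sum(weights) - 1| when validating a weight vector.
WEIGHT_SUM_TOL = 1e-9

#: Default epoch length (seconds) for per-epoch quality flags.
DEFAULT_EPOCH_S = 1.0


@dataclass(frozen=True)
class ReferenceDistribution:
    """Stratum-specific reference percentiles for percentile-clamp normalization.

    The stratum may be a cohort, an age band, a task condition, or a single
    person's own baseline — the label records which, but the normalization
    itself is agnostic (both within-person and between-person references are
    supported).
    """

    stratum_label: str
    q10_ref: float
    q90_ref: float

    def __post_init__(self) -> None:
        if not self.stratum_label:
            raise ValueError("stratum_label must be non-empty")
        if not (math.isfinite(self.q10_ref) and math.isfinite(self.q90_ref)):
            raise ValueError("reference percentiles must be finite")
        if not self.q90_ref > self.q10_ref:
            raise ValueError(
                f"degenerate reference spread in stratum '{self.stratum_label}': "
                f"q90 ({self.q90_ref}) must exceed q10 ({self.q10_ref})"
            )


@dataclass(frozen=True)
class WeightVector:
    """Named non-negative weights summing to one.

    Construct via :func:`validate_weights`; direct construction also
    validates.  Weights are user-set inputs — nothing in this package
    estimates them from data.
    """

    names: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")
        if len(self.names) == 0:
            raise ValueError("weight vector must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("weight names must be unique")
        for name, v in zip(self.names, self.values):
            if not math.isfinite(v):
                raise ValueError(f"weight '{name}' is not finite")
            if v < 0:
                raise ValueError(f"weight '{name}' is negative ({v})")
        s = math.fsum(self.values)
        if abs(s - 1.0) > WEIGHT_SUM_TOL:
            raise ValueError(f"weights sum to {s!r}, not 1 (tolerance {WEIGHT_SUM_TOL})")

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    @classmethod
    def uniform(cls, names: Sequence[str]) -> "WeightVector":
        """Uniform weights on the simplex — the package-wide default."""
        n = len(names)
        return cls(tuple(names), tuple(1.0 / n for _ in range(n)))


def _n_epochs(n_samples: int, fs: float, epoch_s: float) -> int:
    return max(1, math.ceil(n_samples / fs / epoch_s))


@dataclass(frozen=True)
class SampledSeries:
    """A uniformly sampled, unit-tagged channel with per-epoch quality flags.

    Epochs are half-open windows ``[t0 + k*epoch_s, t0 + (k+1)*epoch_s)``.
    Values must be finite wherever the covering epoch's quality flag is True;
    NaN is permitted only inside flagged-bad epochs (e.g. gait windows with
    too few events).
    """

    t0: float
    fs: float
    values: np.ndarray
    units: str = ""
    quality: np.ndarray | None = None
    epoch_s: float = DEFAULT_EPOCH_S

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise ValueError(f"fs must be a positive finite sampling rate, got {self.fs}")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        n_ep = _n_epochs(vals.size, self.fs, self.epoch_s)
        if self.quality is None:
            q = np.ones(n_ep, dtype=bool)
        else:
            q = np.asarray(self.quality, dtype=bool)
            if q.shape != (n_ep,):
                raise ValueError(
                    f"quality must have one flag per epoch: expected {n_ep}, got {q.size}"
                )
        object.__setattr__(self, "quality", q)
        good = q[self.epoch_index(self.times)]
        if not np.all(np.isfinite(vals[good])):
            raise ValueError("values must be finite inside good-quality epochs")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def usable_fraction(self) -> float:
        return float(np.mean(self.quality))

    def epoch_index(self, t: np.ndarray | float) -> np.ndarray:
        """Epoch numbers covering timestamps ``t`` (clipped to valid range)."""
        idx = np.floor((np.asarray(t) - self.t0) / self.epoch_s).astype(int)
        return np.clip(idx, 0, self.quality.size - 1)

    def same_grid(self, other: "SampledSeries") -> bool:
        return (
            self.n == other.n
            and math.isclose(self.fs, other.fs, rel_tol=1e-12)
            and math.isclose(self.t0, other.t0, abs_tol=1e-9)
        )

    def replace_values(self, values: np.ndarray, units: str | None = None) -> "SampledSeries":
        return SampledSeries(
            t0=self.t0,
            fs=self.fs,
            values=values,
            units=self.units if units is None else units,
            quality=self.quality.copy(),
            epoch_s=self.epoch_s,
        )


_MODALITIES = ("neural", "gait", "instability")


@dataclass(frozen=True)
class ModalityQuality:
    """Usable-epoch fraction and free-text flags for one input modality."""

    modality: str
    usable_fraction: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}, got {self.modality!r}")
        if not 0.0 <= self.usable_fraction <= 1.0:
            raise ValueError(f"usable_fraction must lie in [0,1], got {self.usable_fraction}")


@dataclass(frozen=True)
class IndexValue:
    """A scalar index with its governance metadata.

    ``partial`` is True when the value was computed from a strict subset of
    the index's nominal modalities (with weights renormalized); the
    ``contributing`` list records which modalities actually entered.
    """

    value: float
    confidence: float
    partial: bool
    contributing: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0,1], got {self.confidence}")
        if not self.contributing:
            raise ValueError("an index value must name at least one contributing modality")


@dataclass(frozen=True)
class IndexSeries:
    """A time-resolved index: a bounded series plus governance metadata."""

    series: SampledSeries
    confidence: float
    partial: bool
    contributing: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0,1], got {self.confidence}")
        if not self.contributing:
            raise ValueError("an index series must name at least one contributing modality")

    @property
    def values(self) -> np.ndarray:
        return self.series.values


def normalize(x, ref: ReferenceDistribution):
    """Percentile-clamp normalization: clamp((x - q10)/(q90 - q10), 0, 1).

    Maps the reference 10th percentile to 0 and the 90th to 1, clamping
    outside that range.  Monotone nondecreasing in ``x``.  Accepts scalars or
    arrays; non-finite input is rejected.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("normalize: input contains non-finite values")
    out = np.clip((arr - ref.q10_ref) / (ref.q90_ref - ref.q10_ref), 0.0, 1.0)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def fit_reference(samples, stratum_label: str) -> ReferenceDistribution:
    """Fit the 10th/90th reference percentiles of a stratum sample.

    Percentiles follow the linear-interpolation (type 7) convention.  A
    degenerate spread (q10 == q90, e.g. constant samples) is a hard error —
    normalization is undefined there and no silent fallback is taken.
    """
    arr = np.asarray(samples, dtype=float).ravel()
    if arr.size < 10:
        raise ValueError(f"fit_reference: need >= 10 samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("fit_reference: samples contain non-finite values")
    q10, q90 = np.percentile(arr, [10.0, 90.0], method="linear")
    if not q90 > q10:
        raise ValueError(
            f"degenerate reference spread in stratum '{stratum_label}': "
            f"q10 == q90 == {q10}"
        )
    return ReferenceDistribution(stratum_label, float(q10), float(q90))


def validate_weights(names: Sequence[str], values: Sequence[float]) -> WeightVector:
    """Validate weights onto the simplex.  Never silently renormalizes."""
    if len(names) != len(values):
        raise ValueError("names and values must have equal length")
    return WeightVector(tuple(names), tuple(float(v) for v in values))


def renormalize_weights(w: WeightVector, available: Sequence[str]) -> WeightVector:
    """Restrict a weight vector to the available modalities and rescale to 1.

    Used when a modality is missing: the caller must mark the resulting
    index as partial.  An empty ``available`` set is an error — no index is
    emitted when every modality is gone.
    """
    avail = list(available)
    if not avail:
        raise ValueError("renormalize_weights: no modalities available, no index can be emitted")
    unknown = [a for a in avail if a not in w.names]
    if unknown:
        raise ValueError(f"renormalize_weights: labels {unknown} not in weight vector {w.names}")
    if len(set(avail)) != len(avail):
        raise ValueError("renormalize_weights: duplicate labels in available")
    kept = [(n, w[n]) for n in w.names if n in avail]
    total = math.fsum(v for _, v in kept)
    if total <= 0:
        raise ValueError("renormalize_weights: available modalities carry zero total weight")
    return WeightVector(tuple(n for n, _ in kept), tuple(v / total for _, v in kept))


def confidence(qualities: Sequence[ModalityQuality], w: WeightVector) -> float:
    """Weight-weighted mean usable fraction: the index confidence channel.

    Equals 1 iff every weighted modality is fully usable; monotone
    nondecreasing in each usable fraction.  A weighted modality without a
    quality record is an error.
    """
    by_mod = {q.modality: q for q in qualities}
    vals = []
    for name in w.names:
        if name not in by_mod:
            raise ValueError(f"confidence: missing quality record for modality '{name}'")
        vals.append(w[name] * by_mod[name].usable_fraction)
    return float(min(1.0, max(0.0, math.fsum(vals))))
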