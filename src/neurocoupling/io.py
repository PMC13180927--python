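"""File I/O: session loading, resampling, YAML config, run manifest, outputs.

Input schemas (CSV, comma-separated, UTF-8, header row, timestamps in
seconds as floats):

* ``eeg_envelopes.csv`` — t, theta, alpha, beta[, quality (0/1)]
* ``gait_events.csv``   — t, foot (L/R)
* ``sway.csv``          — t, ml, ap, shift
* ``perturbations.csv`` — onset, magnitude_bin (optional file)

A missing file marks the corresponding modality absent; downstream indices
become partial or are suppressed with reason codes, never imputed.  Dense
channels are linearly resampled onto the slowest channel's grid; sampling
gaps (intervals longer than 1.5x the channel's median spacing) and
quality-0 rows are flagged into the per-epoch quality vectors.

Every run writes a manifest recording tool version, a hash of the full
configuration, the weights, the reference percentiles, the recovery
criterion, coherence settings and the per-modality quality summary — every
tunable that affects an emitted number.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ReferenceDistribution, SampledSeries, validate_weights
from .coupling import CoherenceSettings
from .pipeline import PipelineConfig, SessionData, SessionResult, compute_session_indices
from .recovery import PerturbationEvent, RecoveryCriterion
from .signals import GaitEvents

__all__ = [
    "SchemaError",
    "load_session",
    "load_config",
    "run_pipeline",
    "build_manifest",
    "write_outputs",
]

GAP_FACTOR = 1.5


class SchemaError(ValueError):
    """A CSV file violating its schema; names file, column, and row."""


def _read_csv(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:  # noqa: BLE001 - surface parse errors with the filename
        raise SchemaError(f"{path.name}: cannot parse CSV ({e})") from e
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column '{col}'")
    return df


def _check_increasing(path: Path, t: np.ndarray, col: str) -> None:
    if not np.all(np.isfinite(t)):
        row = int(np.flatnonzero(~np.isfinite(t))[0])
        raise SchemaError(f"{path.name}: column '{col}' row {row}: non-finite timestamp")
    d = np.diff(t)
    if np.any(d <= 0):
        row = int(np.argmax(d <= 0)) + 1
        raise SchemaError(
            f"{path.name}: column '{col}' row {row}: timestamps must be strictly increasing"
        )


def _gaps(t: np.ndarray) -> list[tuple[float, float]]:
    """Unsupported intervals: spacings over GAP_FACTOR x the median spacing.

    The sample at the gap's left edge is itself valid, so the unsupported
    interval starts one nominal spacing after it.
    """
    if t.size < 3:
        return []
    d = np.diff(t)
    med = float(np.median(d))
    return [(float(t[i]) + med, float(t[i + 1]))
            for i in np.flatnonzero(d > GAP_FACTOR * med)]


def _resample(
    t_src: np.ndarray,
    v_src: np.ndarray,
    grid: np.ndarray,
    fs: float,
    epoch_s: float,
    bad_intervals: list[tuple[float, float]],
    units: str = "au",
) -> SampledSeries:
    vals = np.interp(grid, t_src, v_src)
    n_ep = max(1, int(np.ceil(grid.size / fs / epoch_s)))
    qual = np.ones(n_ep, dtype=bool)
    ep_lo = grid[0] + np.arange(n_ep) * epoch_s
    ep_hi = ep_lo + epoch_s
    # epochs outside the source channel's own span are unsupported
    bad = (ep_hi <= t_src[0]) | (ep_lo >= t_src[-1])
    for lo, hi in bad_intervals:
        bad |= (ep_lo < hi) & (ep_hi > lo)
    qual[bad] = False
    return SampledSeries(t0=float(grid[0]), fs=fs, values=vals, units=units,
                         quality=qual, epoch_s=epoch_s)


def load_session(session_dir: str | Path, epoch_s: float = 1.0) -> SessionData:
    """Load a session directory into aligned channels.

    Dense channels are resampled onto the slowest channel's uniform grid;
    per-channel gaps and quality-0 EEG rows become False epoch flags.
    Schema violations raise :class:`SchemaError` naming file, column and row.
    """
    d = Path(session_dir)
    dense: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}

    eeg_path = d / "eeg_envelopes.csv"
    eeg_bad_rows: list[tuple[float, float]] = []
    if eeg_path.exists():
        df = _read_csv(eeg_path, ("t", "theta", "alpha", "beta"))
        t = df["t"].to_numpy(dtype=float)
        _check_increasing(eeg_path, t, "t")
        for col in ("theta", "alpha", "beta"):
            v = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)):
                row = int(np.flatnonzero(~np.isfinite(v))[0])
                raise SchemaError(f"{eeg_path.name}: column '{col}' row {row}: non-finite value")
            dense[col] = (t, v, _gaps(t))
        if "quality" in df.columns:
            q = df["quality"].to_numpy()
            dt = float(np.median(np.diff(t))) if t.size > 1 else epoch_s
            eeg_bad_rows = [(float(ti), float(ti) + dt) for ti in t[q == 0]]

    sway_path = d / "sway.csv"
    if sway_path.exists():
        df = _read_csv(sway_path, ("t", "ml", "ap", "shift"))
        t = df["t"].to_numpy(dtype=float)
        _check_increasing(sway_path, t, "t")
        for col in ("ml", "ap", "shift"):
            v = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)):
                row = int(np.flatnonzero(~np.isfinite(v))[0])
                raise SchemaError(f"{sway_path.name}: column '{col}' row {row}: non-finite value")
            dense[col] = (t, v, _gaps(t))

    gait = None
    gait_path = d / "gait_events.csv"
    if gait_path.exists():
        df = _read_csv(gait_path, ("t", "foot"))
        t = df["t"].to_numpy(dtype=float)
        _check_increasing(gait_path, t, "t")
        feet = tuple(str(f).strip().upper() for f in df["foot"])
        bad = [i for i, f in enumerate(feet) if f not in ("L", "R")]
        if bad:
            raise SchemaError(
                f"{gait_path.name}: column 'foot' row {bad[0]}: label must be L or R"
            )
        gait = GaitEvents(t, feet)

    perturbations: tuple[PerturbationEvent, ...] = ()
    pert_path = d / "perturbations.csv"
    if pert_path.exists():
        df = _read_csv(pert_path, ("onset", "magnitude_bin"))
        perturbations = tuple(
            PerturbationEvent(float(r.onset), str(r.magnitude_bin))
            for r in df.itertuples()
        )

    channels: dict[str, SampledSeries | None] = {
        k: None for k in ("theta", "alpha", "beta", "ml", "ap", "shift")}
    if dense:
        # slowest channel = largest median sample spacing
        def med_dt(item):
            t = item[1][0]
            return float(np.median(np.diff(t))) if t.size > 1 else np.inf

        slow_name, (t_slow, _, _) = max(dense.items(), key=med_dt)
        dt = float(np.median(np.diff(t_slow)))
        fs = 1.0 / dt
        n = int(np.floor((t_slow[-1] - t_slow[0]) / dt + 1e-9)) + 1
        grid = t_slow[0] + np.arange(n) * dt
        for name, (t_src, v_src, gaps) in dense.items():
            bad = list(gaps)
            if name in ("theta", "alpha", "beta"):
                bad += eeg_bad_rows
            channels[name] = _resample(t_src, v_src, grid, fs, epoch_s, bad)

    data = SessionData(
        theta=channels["theta"], alpha=channels["alpha"], beta=channels["beta"],
        gait=gait, ml=channels["ml"], ap=channels["ap"], shift=channels["shift"],
        perturbations=perturbations,
    )
    if not (data.has_neural or data.has_gait or data.has_instability):
        raise SchemaError(f"{d}: no input modality found (need at least one of "
                          "eeg_envelopes.csv, gait_events.csv, sway.csv)")
    return data


def _parse_weights(spec: dict, names: tuple[str, ...]):
    return validate_weights(tuple(spec.keys()), tuple(float(v) for v in spec.values())) \
        if spec else None


def load_config(path: str | Path | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (all keys optional).

    Recognized keys: window_s, epsilon, stratum_label, weights
    (cmfi/neural/motor/scd sub-maps name->weight), recovery (threshold,
    dwell, max_window, residual_window, tau), coherence (n_segments,
    segment_s), references (feature -> {stratum, q10, q90}).
    """
    cfg = PipelineConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("window_s", "epsilon"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "stratum_label" in raw:
        kwargs["stratum_label"] = str(raw["stratum_label"])
    weights = raw.get("weights", {})
    for yaml_key, attr, names in (
        ("cmfi", "cmfi_weights", ("neural", "gait", "instability")),
        ("neural", "neural_weights", ("theta", "alpha_sup", "beta_ctrl")),
        ("motor", "motor_weights", ("speed", "gait_cost_inv", "instability_inv")),
        ("scd", "scd_weights", ("PC", "LV", "TD", "VTA")),
    ):
        if yaml_key in weights:
            w = _parse_weights(weights[yaml_key], names)
            if w is not None:
                kwargs[attr] = w
    if "recovery" in raw:
        kwargs["recovery"] = RecoveryCriterion(**{k: float(v) for k, v in raw["recovery"].items()})
    if "coherence" in raw:
        c = raw["coherence"]
        kwargs["coherence"] = CoherenceSettings(
            n_segments=int(c.get("n_segments", 8)),
            segment_s=float(c.get("segment_s", 8.0)))
    if "references" in raw:
        kwargs["references"] = {
            k: ReferenceDistribution(str(v.get("stratum", k)), float(v["q10"]), float(v["q90"]))
            for k, v in raw["references"].items()
        }
    return PipelineConfig(**kwargs)


def build_manifest(config: PipelineConfig, refs_used: dict[str, ReferenceDistribution],
                   result: SessionResult, seed: int | None = None) -> dict:
    """Run manifest: every tunable affecting an emitted number, plus quality."""
    cfg_dict = config.as_dict()
    cfg_dict["references_used"] = {
        k: {"stratum": r.stratum_label, "q10": r.q10_ref, "q90": r.q90_ref}
        for k, r in sorted(refs_used.items())
    }
    blob = json.dumps(cfg_dict, sort_keys=True).encode()
    return {
        "tool": "neurocoupling",
        "version": __version__,
        "seed": seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "modality_quality": {
            q.modality: {"usable_fraction": q.usable_fraction, "flags": list(q.flags)}
            for q in result.qualities
        },
        "reason_codes": result.reasons,
    }


def _series_row(s, k):
    if s is None:
        return ""
    v = s.values[k]
    return "" if not np.isfinite(v) else f"{v:.10g}"


def write_outputs(result: SessionResult, config: PipelineConfig,
                  refs_used: dict[str, ReferenceDistribution],
                  out_dir: str | Path, seed: int | None = None) -> Path:
    """Write indices.csv, brc_summary.json, coupling_summary.json, manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    grid_src = next(s for s in (result.cmfi and result.cmfi.series, result.N,
                                result.G, result.I_win) if s is not None)
    rows = []
    neq_s = result.neq.series if result.neq else None
    cmfi_s = result.cmfi.series if result.cmfi else None
    for k, t in enumerate(grid_src.times):
        rows.append({
            "t": f"{t:.10g}",
            "N": _series_row(result.N, k),
            "G": _series_row(result.G, k),
            "I": _series_row(result.I_win, k),
            "CMFI": _series_row(cmfi_s, k),
            "NEQ": _series_row(neq_s, k),
            "confidence": f"{result.cmfi.confidence:.10g}" if result.cmfi else "",
            "partial": str(result.cmfi.partial).lower() if result.cmfi else "",
            "modalities": "|".join(result.cmfi.contributing) if result.cmfi else "",
        })
    pd.DataFrame(rows).to_csv(out / "indices.csv", index=False)

    brc_summary = {
        "criterion": config.recovery.as_dict(),
        "per_bin_median": result.brc_by_bin,
        "events": [
            {"onset": r.event.onset, "magnitude_bin": r.event.magnitude_bin,
             "t_rec": r.t_rec, "e_res": r.e_res, "brc": r.brc, "censored": r.censored}
            for r in result.brc_events
        ],
    }
    (out / "brc_summary.json").write_text(json.dumps(brc_summary, indent=1))

    coupling_summary = {
        "gcc": result.gcc,
        "f_gait_hz": result.f_gait,
        "estimator": config.coherence.as_dict(),
        "reason": result.reasons.get("GCC"),
    }
    (out / "coupling_summary.json").write_text(json.dumps(coupling_summary, indent=1))

    manifest = build_manifest(config, refs_used, result, seed)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def run_pipeline(session_dir: str | Path, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None, seed: int | None = None) -> SessionResult:
    """End-to-end: load a session directory, compute indices, write outputs."""
    config = config or PipelineConfig()
    data = load_session(session_dir)
    from .pipeline import REFERENCE_FEATURES, fit_session_references

    refs = dict(config.references)
    missing = [k for k in REFERENCE_FEATURES if k not in refs]
    if missing:
        fitted = fit_session_references([data], config.window_s, config.stratum_label)
        refs.update({k: v for k, v in fitted.items() if k in missing})
    result = compute_session_indices(data, config, refs=refs)
    if out_dir is not None:
        write_outputs(result, config, refs, out_dir, seed)
    return result
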