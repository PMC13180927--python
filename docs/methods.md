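# Methods

## Model and assumptions

The package treats a walking session as a four-layer chain — environmental
structure → neural control dynamics → motor output stability → adaptive
capacity — and computes bounded indices that are *partial observables* of
that chain, not measurements of any single latent mechanism. Three
commitments shape the implementation:

1. **Percentile-clamp normalization (reference strata).** Every raw
   observable is mapped to [0, 1] by
   `clamp((x − q10,ref)/(q90,ref − q10,ref), 0, 1)`, where the reference
   percentiles come from a named stratum (a cohort, a condition, or a
   person's own baseline). Percentiles use the linear-interpolation
   convention (the common "type 7"), chosen for continuity and ubiquity. A
   degenerate spread (q10 = q90) is a hard error: normalization is undefined
   there and no silent fallback is taken. Both within-person and
   between-person strata are supported; the stratum label travels with every
   reference so the choice is always traceable.

2. **Weighted composites on the simplex.** All multi-component indices are
   convex combinations. Weights must be non-negative and sum to 1 within
   1e-9; violations are errors, never silent renormalizations. No weights
   are estimated from data in this package — they are declared inputs,
   defaulting to uniform, except the gait-cost combination whose 0.5/0.5
   coefficients are fixed by definition.

3. **Quality governance.** Every emitted index carries a confidence channel
   (the weight-weighted mean usable-epoch fraction of its inputs, per-epoch
   flags on 1 s half-open windows by default). A missing modality produces
   an explicitly `partial` index with the remaining weights renormalized
   onto the simplex — never an imputed value — and indices whose definitions
   require the missing modality (NEQ without the neural channel, GCC without
   theta or gait, BRC without instability) are suppressed with a reason
   code. Losing every modality is a hard error.

## Signal derivations and numerical choices

* **Band-power envelopes** (when raw single-channel series are supplied;
  pipelines normally ingest pre-cleaned envelopes): 4th-order Butterworth
  bandpass applied forward-backward with zero initial state (zero-phase, no
  edge padding — deterministic at the cost of a short edge transient),
  squared magnitude of the FFT analytic signal, 1 s rectangular smoothing.
  Default bands: theta 4–8 Hz, alpha 8–13 Hz, beta 13–30 Hz; configurable.
  Requires fs > 2·f_hi.
* **Alpha suppression** is `1 − norm(alpha power)`, so all three neural
  components point in the "more demand/engagement" direction.
* **Step vs stride:** a step is the interval between contralateral heel
  strikes, a stride between ipsilateral ones. Asymmetry uses steps
  (`|mean_L − mean_R| / mean step`, with the denominator the balanced mean
  `(mean_L + mean_R)/2` so the ratio is invariant to unequal step counts in
  a window); variability uses the stride-time coefficient of variation.
  Both are computed on non-overlapping analysis windows (default 5 s) and
  normalized before the fixed 0.5/0.5 combination — required for the
  declared G(t) ∈ [0, 1] range. Windows with fewer than 4 events are
  flagged gaps (quality False, value NaN), never filled.
* **Motor performance M(t)** has no canonical definition; the default is
  `M = (cadence_norm + (1 − G) + (1 − I)) / 3`, where the speed proxy is
  normalized cadence (reciprocal mean stride time per window, standing in
  for gait speed when no displacement measure exists). The composition
  string is echoed into every run manifest so preregistered alternatives can
  replace it explicitly.
* **Recovery detection:** recovery time is the earliest sample after
  perturbation onset at which the instability signal stays below the
  criterion threshold for a full dwell period (default 1 s — a bare
  threshold would let single-sample dips count). Defaults: threshold 0.5,
  search horizon 10 s, residual window 2 s, τ = 2 s; all must be fixed
  before outcome analysis and are echoed verbatim into outputs. Events that
  never meet the criterion are censored and score 0 — the conservative limit
  of the recovery score as t_rec → ∞. Per-bin aggregation is the median,
  midpoint convention for even counts.
* **Coherence (GCC):** Welch estimator with periodic Hann window, 50%
  overlap, default 8 segments of 8 s, evaluated at the frequency bin nearest
  the gait frequency (reciprocal median ipsilateral stride time). The gait
  phase (linear 0→2π between ipsilateral strikes) enters as cos(phase) to
  give a real narrowband reference. Zero-variance inputs are an error.
* **Operating boundary C\*:** either the 0.10 quantile of CMFI observed in
  the 5 s preceding instability failures (challenge-response — the *least*
  demand seen to precede failure, a conservative reading; ≥ 5
  failure-preceding epochs required) or the 0.90 quantile of ≥ 20 in-stratum
  CMFI samples (normative). Insufficient support is an error; there is no
  universal default threshold. CMH is reported per epoch; persistence rules
  for "sustained" negative headroom are left to the caller.
* **GCC interpretation** is a fixed rule table: elevated GCC (above the
  configured threshold, default in-stratum 75th percentile) + low SCD +
  degraded NEQ → compensatory over-control; elevated + high SCD + preserved
  NEQ → adaptive recruitment; everything else → indeterminate. Coherence is
  never read univariately.
* **I/O:** CSV (comma, UTF-8, header row, seconds as floats), read with
  round-trip float parsing so write→load is exact. Channels are linearly
  resampled onto the slowest channel's grid in the I/O layer only — the
  signal operations refuse mismatched grids. Sampling gaps (spacing > 1.5×
  the channel median; the unsupported interval starts one nominal spacing
  after the last good sample) and quality-0 rows become False epoch flags.

## The synthetic session generator

`neurocoupling.synth` emulates exactly the statistical structure the indices
consume. A latent demand trace D(t) — the configured set level plus an AR(1)
fluctuation (coefficient 0.95 on a 1 Hz grid, innovation SD 0.02, hence
stationary SD ≈ 0.064 and ~20 s correlation time) — drives every channel:

* theta = 1.0 + 0.6·D, beta = 0.8 + 0.45·D, alpha = 3.0 − 0.6·D (floored at
  0), each plus Gaussian noise (SD 0.5 in channel units);
* sway channels = 0.2 + 0.15·D plus low-passed noise (0.5 s moving average
  of white noise at 0.4× the EEG noise SD — sway-amplitude envelopes vary
  smoothly, not as sample-to-sample flicker);
* stride times ~ Normal with mean `stride_mean` (default 1.1 s) and CV
  0.03 + 0.04·D; the left/right split fraction jitters with the same CV, so
  both gait-cost components rise with demand;
* perturbations add `peak·exp(−(t−onset)/decay)` pulses to all sway
  channels, with the analytic criterion-crossing time `decay·ln(peak/c)`
  recorded as ground truth;
* an optional positive control (`gcc_mod_depth > 0`) modulates the theta
  envelope by cos(actual gait phase), which must drive GCC above the noise
  floor.

Defaults are 60 s sessions at 25 Hz. The coupling gains were calibrated once
so that moving the demand set level from 0.2 to 0.8 shifts mean CMFI by
≈ 0.3 under uniform weights — a contrast a 20-session-per-arm sign test
resolves comfortably — and then frozen.

**What the generator does not emulate:** biomechanics (no pendulum gait, no
vestibular or proprioceptive dynamics), EEG artifacts and their cleaning
(inputs are already band-power envelopes; artifact governance is a
reporting concern, not computation here), non-Gaussian noise, missing-data
patterns of real hardware, and any empirically validated gain or decay
values — none exist yet for these constructs. Passing tests therefore show
that the *estimators and governance rules* behave as specified on data with
known structure; they say nothing about construct validity in humans.

## The directional demand experiment

`run_h1_experiment` generates two arms identical except for the latent
demand set level (a confound guard rejects any other difference), fits
reference percentiles on the *pooled* sessions of both arms — a
between-session stratum; fitting references within each session would centre
every session near 0.5 and erase the contrast — and compares per-arm mean
CMFI and NEQ per replicate seed. With set levels 0.2 vs 0.8 and 20 sessions
per arm, the high-demand arm shows higher CMFI and lower NEQ in essentially
every replicate.

## Problem sizes

Desk-scale throughout, as the package's own verification design: 1 000
randomized inputs per equation-fidelity check, 10 000 fuzzed range draws
plus 20 random sessions, 50 seeded recovery traces against the
exhaustive-scan oracle, coherence fixtures of 64–1024 samples, and 20
replicates × 2 arms × 20 sessions for the directional experiment.

## Known limitations

* Weights, reference percentiles, the elevation threshold for GCC, and the
  recovery criterion are all user-declared; nothing here validates them.
* SCD's pattern-complexity extractor is spectral entropy of route imagery
  only; contrast-weighted spatial-frequency variants are accepted solely as
  precomputed inputs.
* The neural composite assumes the three band proxies may be summarized
  additively; if they are better modeled as partially distinct processes,
  they should enter downstream models separately — the per-component series
  are exposed for exactly that reason.
* NEQ comparisons are meaningful only within person and stratum; the
  package tags outputs with the stratum label but computes no cross-stratum
  comparisons.
* Within-session reference fitting (the fallback when no stratum percentiles
  are supplied) centres indices on the session's own distribution and is
  unsuitable for between-session comparison; perturbation pulses also
  inflate within-session sway references slightly.
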