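# neurocoupling

Bounded indices of embodied cognitive-motor coupling during locomotion in
built environments — for neuroergonomics researchers, rehabilitation
scientists, and environment/route assessors who work with synchronized
mobile-EEG band-power envelopes, heel-strike events, and sway/pressure
channels.

There is no routine equivalent of blood pressure or gait speed for the
*coupled* burden an environment places on cognition and locomotion: clinical
instruments capture capacity snapshots, and design practice has no
quantitative feedback at all. This package implements a six-index language
for that coupling, each index bounded, percentile-normalized against an
explicit reference stratum, and governed by strict missing-data rules.

## The indices

With `norm(x) = clamp((x − q10,ref) / (q90,ref − q10,ref), 0, 1)` against
stratum reference percentiles, and all weights non-negative and summing to 1:

| Index | Definition | Range |
|---|---|---|
| **N(t)** | `w_θ·θ_f + w_α·α_sup + w_β·β_ctrl` — neural control demand from normalized frontal-midline theta, parietal-occipital alpha suppression (`1 − norm(alpha)`), and sensorimotor beta | [0, 1] |
| **G(t)** | `0.5·asym(t) + 0.5·var_stride(t)` — gait control cost from normalized step asymmetry and stride-time CV | [0, 1] |
| **I(t)** | `[norm(ml) + norm(ap) + norm(shift)] / 3` — instability from mediolateral sway, anterior-posterior sway, support shift | [0, 1] |
| **CMFI(t)** | `w_N·N + w_G·G + w_I·I` — instantaneous coupled demand state | [0, 1] |
| **SCD** | `λ_PC·PC + λ_LV·LV + λ_TD·TD + λ_VTA·(1 − VTA)` — environmental demand from pattern complexity, luminance variance, transition density, visual-tactile alignment | [0, 1] |
| **NEQ(t)** | `M(t) / (N(t) + ε)` — motor performance per unit neural demand, ε = 0.05 | [0, 1/ε] |
| **BRC_k** | `(1 − E_res,k) · exp(−t_rec,k / τ)` per perturbation, aggregated as per-bin medians | [0, 1] |
| **GCC** | magnitude-squared coherence between the θ-envelope and cos(gait phase) at the gait frequency | [0, 1] |
| **CMH** | `C* − CMFI_current` — headroom to an individualized operating boundary | [−1, 1] |

Quality governance is non-optional: every index carries a confidence channel
(weight-weighted usable-epoch fraction); a missing modality yields an
explicitly *partial* estimate with renormalized weights, never an imputed
value; and losing every modality is a hard error.

Because no public dataset of this kind exists, the package ships a synthetic
multimodal session generator (`neurocoupling.synth`) in which a latent
demand trace drives every channel with known coupling gains — so every
equation, governance rule, and the directional prediction "higher
environmental demand ⇒ higher CMFI, lower NEQ" is testable end to end.

## Worked example

Generate a 60 s session at a moderate demand level (`scd_true = 0.3`) with
two balance perturbations, then run the full pipeline:

```bash
neurocoupling simulate --config session.yaml --seed 3 --out session/
neurocoupling report session/ --out results/
```

with `session.yaml`:

```yaml
duration: 60.0
scd_true: 0.3
perturbations:
  - {onset: 20.0, magnitude_bin: mild,   injected_peak: 1.0, decay_s: 2.0}
  - {onset: 40.0, magnitude_bin: strong, injected_peak: 1.5, decay_s: 3.0}
```

prints:

```json
{"mean_cmfi": 0.39511947275725867, "mean_neq": 1.0415898885262596,
 "gcc": 0.15331894127642057,
 "brc_per_bin": {"mild": 0.10918363278077348, "strong": 0.026489223786469816},
 "reasons": {}}
```

Reading the numbers: mean CMFI ≈ 0.40 says the session sits in the lower
half of the session's own demand range (references were fitted
within-session here; supply stratum percentiles in a config YAML for
between-person comparisons). Mean NEQ ≈ 1.04 means motor output roughly
matches neural demand per unit. GCC ≈ 0.15 is an unremarkable
theta–gait-phase coherence — and it must never be read alone: the
`gcc` subcommand accepts `--scd-level/--neq-state` to produce the
context-conditional reading (compensatory over-control vs adaptive
recruitment vs indeterminate). The BRC medians score the two recoveries: the
mild perturbation (detected recovery after 3.48 s, residual instability
0.38) earns 0.109; the stronger, slower-decaying one earns less. `results/`
also contains `indices.csv` (per-window N, G, I, CMFI, NEQ with confidence,
partial flag and contributing modalities), `brc_summary.json`,
`coupling_summary.json`, and `manifest.json` recording every tunable that
affected any number.

Other subcommands: `scd` (route-level environmental demand from a route
YAML), `brc`, `gcc`, `headroom` (operating boundary C* and the CMH series),
`indices`.

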