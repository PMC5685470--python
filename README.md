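# refframe

Reference-frame analysis of visual/vestibular heading tuning: a tested,
reusable pipeline for quantifying whether a neuron's heading tuning is
eye-centered, head-centered, or intermediate, together with a synthetic-data
generator that makes every analysis stage verifiable by parameter recovery
without any neural recordings.

## What it does

- **`refframe.core_io`** — tidy trial-table data model (CSV in/out), spike
  windowing (middle 1 s of the 2 s stimulus), tuning-curve construction
  (mean ± s.e.m. per heading), one-way-ANOVA tuning significance, and the
  heading-estimation condition scheduler.
- **`refframe.synthetic_data`** — wrapped-Gaussian tuning generator with a
  continuous eye-vs-head frame parameter `lambda_frame` (0 = head-centered,
  1 = eye-centered), multiplicative eye-position gain fields, pursuit
  half-range shift distortion controlled by a compensation parameter `c`,
  Gaussian-Fano/Poisson trial noise, Gaussian velocity profiles, and a
  behavioral heading-report simulator.
- **`refframe.displacement_index`** — cross-covariance displacement index
  (DI) between tuning curves at static eye positions (1-degree circular
  interpolation, lag search over [-180, 180]), bootstrap 95% CIs by
  within-cell resampling, and the four-way head/eye/intermediate/unclassified
  classification.
- **`refframe.pursuit_shift`** — 3-step partial-shift analysis under smooth
  pursuit (amplitude scaling, half-range splitting with per-half
  interpolation, correlation-maximizing half shifts), converted to a pursuit
  DI with a 30-degree predicted-shift denominator; a whole-curve
  cross-covariance variant is available for method comparison.
- **`refframe.model_fitting`** — joint 16-parameter eye-centered and
  head-centered wrapped-Gaussian fits across the three eye positions
  (bounded least squares with analytic Jacobian and seeded restarts),
  partial-correlation model comparison, Fisher r-to-Z, and the 1.645
  criterion; fits with r² < 0.6 are excluded.
- **`refframe.gain_analysis`** — evoked-response (max − min) gain
  quantification across eye positions with a label-permutation significance
  test and monotonic / non-monotonic / none categorization.
- **`refframe.behavior`** — saccade-ring endpoint to reported-heading
  mapping, reward-window scoring, circular means/SDs, and fixation-dependent
  estimation error.

## CLI

```sh
# generate a synthetic trial table
refframe simulate --config sim.yaml --out trials.csv --seed 17

# per-neuron analyses (JSON output)
refframe tuning     --in trials.csv --neuron syn0000 --modality visual
refframe di         --in trials.csv --boot 1000 --seed 7 --out di.json
refframe pursuit-di --in trials.csv --method partial_shift --out pdi.json
refframe fit-models --in trials.csv --restarts 20 --seed 7 --out fits.json
refframe gain       --in trials.csv --boot 1000 --seed 7 --out gain.json
refframe behavior   --in saccades.csv --out behavior.json
```

`sim.yaml` keys: `n_neurons`, `lambda_frame`, `reps`, `heading_step_deg`,
`eccentricity_deg`, `pursuit_comp`, `noise: {kind, fano}`,
`gain: {kind, strength}`.

Trial tables are UTF-8 CSV with header
`neuron_id,modality,protocol,eye_pos_deg,pursuit_dir,heading_deg,repetition`
plus exactly one of `rate_hz` or `spike_times_s` (semicolon-separated
seconds). Externally deposited files with different headers can be ingested
via the `column_map` argument of `load_trial_table`.

## Conventions

Headings are azimuths in [0, 360) with 0° = rightward, 90° = forward.
Positive DI means tuning displacement in the direction of gaze displacement.
Spike windows are half-open `[start, end)`. All stochastic steps take an
explicit seed; identical seeds give identical outputs.
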