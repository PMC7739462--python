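# Methods

## Problem and model

Obstructive apneas interrupt airflow for ten seconds or more; the
ensuing gas-exchange deficit appears in pulse oximetry as a transient
desaturation followed by resaturation when breathing resumes.
`oxisleep` classifies each minute of an overnight SpO2 trace as apneic
or normal from ten summary statistics of that minute, using a
soft-margin RBF-kernel SVM. The minute is the classification unit:
shorter epochs (e.g. 30 s) risk splitting single events, so they are
deliberately not supported.

The SVM solves the usual soft-margin problem
min ½‖w‖² + C Σᵢ ξᵢ subject to yᵢ(wᵀφ(xᵢ) + w₀) ≥ 1 − ξᵢ, ξᵢ ≥ 0,
in the feature space of k(x, z) = exp(−‖x−z‖²/(2σ²)). The decision
function is h(x) = Σᵢ αᵢyᵢ k(xᵢ, x) + w₀; h ≥ 0 predicts the larger
class label. Internally the classes are encoded +1 = normal,
−1 = apnea, so a tie at exactly h = 0 predicts normal; for all metrics
apnea is the positive class. The fit is delegated to
`sklearn.svm.SVC`; the fitted support vectors, dual coefficients and
intercept are extracted so the decision function is computed explicitly
— this makes the JSON-persisted model self-contained and its
round-trip bit-exact.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `C` | 1000 | slack penalty of the margin objective |
| `sigma` | 5 | RBF width; γ = 1/(2σ²) = 0.02 |
| `noise_threshold` | 50 % | saturation below this is sensor noise, masked |
| `max_invalid_fraction` | 0.2 | minutes with more masked seconds are discarded |
| `min_overlap_sec` | 10 s | cumulative event overlap that makes a minute apneic |
| `folds` | 10 | stratified cross-validation folds |

`C` and `sigma` are the established operating point of the method; no
hyperparameter search is performed. The σ→kernel mapping uses the
standard Gaussian form exp(−‖x−z‖²/(2σ²)) — the definition consistent
with calling the width parameter σ.

## Design choices where the design was open

- **Downsampling** to 1 Hz uses per-second block means over valid
  samples (robust to oximeter jitter) rather than decimation.
- **Noisy samples** are masked, not zeroed or deleted; a surviving
  minute's gaps are filled by linear interpolation between the nearest
  valid neighbours (edge gaps take the nearest valid value), then
  clipped into [50, 100]. Minutes with > 20% masked seconds are
  discarded — the threshold bounds interpolation error while keeping
  most of the night.
- **Epoch alignment** is to the recording start, not clock minutes.
- **Labeling** uses cumulative overlap of the event *union* with the
  minute, ≥ 10 s, mirroring the clinical apnea-duration floor. The rule
  is monotone: lengthening an event can never turn an apneic minute
  normal.
- **`CorreC`** correlates saturation against the time index (the
  natural companion of the regression-line features); lag
  autocorrelations were considered and rejected. **`AbSlope`** is
  |`SpSlope`| (the literal reading of "absolute slope"); the
  mean-absolute-first-difference alternative found elsewhere in the
  oximetry literature is intentionally not implemented. **`S_vari`** is
  the population (1/n) variance — a descriptive statistic of a fixed
  window. In `ZCount`, a deviation of exactly zero inherits the
  previous sign so plateaus at the mean are not double-counted.
- **Scaling** is min-max to [0, 1], fitted per training fold only —
  never on pooled data — so cross-validation is leakage-free (asserted
  by refitting in the tests). Constant columns map to 0; out-of-range
  test values extrapolate without clipping.
- **Pooled metrics**: the folds' confusion counts are summed into one
  2×2 table; per-fold metrics are reported alongside for transparency.
  Fold assignment is stratified with an explicit seed (optionally
  grouped per record via `--group-by-record`), making every report
  reproducible byte-for-byte.
- **Baselines**: AdaBoost uses 30 depth-1 stumps, the strongest
  operating point among ensembles of 10–40 stumps for this feature
  set. A deep-belief-network baseline is deliberately absent: with no
  fixed architecture to pin down, it would not be a reproducible
  comparison.

## The synthetic generator

`simulate_overnight` emulates the morphology of apneic oximetry:
baseline ≈ 97% with a slow random walk (0.1 %/√min) and Gaussian sensor
noise (0.5%); events arrive with Poisson count at `event_rate`
(default 20/h, a moderate-severity patient), each redrawn with bounded
retries until it fits without overlap (one resaturation time constant
of clearance), with duration uniform on 15–45 s and depth uniform on
6–14%. Within an event the saturation ramps down linearly over the
first half, holds at full depth, and recovers exponentially
(τ = 10 s) after the event ends. Optional artifacts replace samples
with sub-50 dropouts at `artifact_prob`. `simulate_labeled_dataset`
generates balanced one-minute segments directly (event centred in the
apnea class, event-free normal class), shuffled by seed.

What the simulator does **not** model: hypopneas with partial airflow,
movement artifact morphology, pulse-amplitude coupling, sleep-stage
structure, patient-level covariates, or inter-patient baseline
differences. Synthetic classes are therefore more separable than real
UCD-style records — the passing recovery tests demonstrate that the
pipeline is correct and leak-free, not that the headline performance
transfers to clinical data. Evaluating on real polysomnograms requires
downloading an annotated database and converting its annotations to
the package's CSV form (see README).

## Numerical choices and degenerate inputs

- Regression features use the centred closed-form OLS solution, which
  returns an exactly zero slope for constant minutes; `CorreC` of a
  zero-variance minute is 0 by convention.
- Metrics with a zero denominator return NaN (serialised as `null`),
  never an exception.
- Problem sizes in tests and in `scripts/acceptance.py` — 1000-segment
  study sets, five to ten 2 h synthetic nights — were chosen as the
  smallest sizes at which the binomial noise on recall and pooled
  metrics is well inside the asserted margins.
- Seeds: every stochastic component (generator, fold shuffling,
  AdaBoost) takes an explicit integer seed; identical seeds give
  byte-identical feature CSVs and report JSONs.

## Known limitations

- Single-channel SpO2 only; no airflow, ECG, EEG or snoring features,
  and no apnea/hypopnea subtype discrimination or severity grading.
- The per-segment CV default lets minutes of one patient span folds;
  use grouped folds for patient-level generalisation estimates.
- EDF writing exists only as a minimal fixture writer (16-bit, 0–100%
  physical range) for reader tests; it is not a general EDF exporter.
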