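# Methods

This note documents the models and procedures implemented in `stsmap`, the
parameter choices that matter, the numerical safeguards, and what the
synthetic validation does and does not establish.

## Signal model

Surface EMG envelopes are modeled as a nonnegative factorization
`V ≈ W·H`: `W` (muscles × N_syn) holds fixed synergy weight vectors with
unit Euclidean norm, `H` (N_syn × samples) the nonnegative activation
coefficients. The unit-norm convention pushes all amplitude into `H`, which
makes weight vectors comparable across subjects.

### Envelope extraction (`preprocess.compute_envelope`)

Raw EMG → 4th-order zero-phase Butterworth band-pass (20–450 Hz) →
full-wave rectification → 4th-order zero-phase Butterworth low-pass (5 Hz),
clipped at zero. The corners are standard practice for lower-limb
sit-to-stand work and are configurable; they are a declared recipe, not an
estimate of any particular laboratory's settings. Zero-phase filtering
preserves the timing of activation bursts relative to kinematics. Before
factorization each muscle's envelope is divided by its trial maximum
(configurable off), so weights reflect relative contributions rather than
electrode gain.

### Cycle segmentation (`preprocess.segment_upward_cycles`)

Only the upward (sit-to-stand) phase is analysed; the return phase is
partly gravity-driven and is discarded. Segmentation thresholds the
vertical CoM position at 10% and 90% of the subject's vertical excursion:
an interval starts at the last sample still at the seated threshold before
a rise and ends at the first sample at the standing threshold. Position
thresholds were chosen over velocity zero-crossings because position is far
less sensitive to differentiation noise. When the retained cycles exceed a
configurable total duration budget (default 10 s of upward-phase time,
modeling a 30-second-test-equivalent trial length), a seeded random subset
is kept.

### Time normalization

Every per-cycle series is linearly resampled onto 100 samples spanning the
cycle, endpoints preserved exactly. Velocities are always differentiated at
the original sampling rate *before* resampling (resampling first would
rescale velocity magnitudes by the cycle-duration ratio).

## Center of mass and phase spaces (`com`)

The CoM is a mass-fraction-weighted sum of segment CoMs, each placed a
fixed fraction of the way from the proximal to the distal marker. The
bundled default is a Winter-style 3-segment sagittal reduction (both
shanks+feet 0.122 of body mass, CoM 45% from knee; both thighs 0.200, 43.3%
from hip; head–arms–trunk 0.678, 62.6% from hip). These values are
configuration with a documented provenance style, not a claim about any
specific reference table; any table whose mass fractions sum to 1 can be
supplied.

Coordinates are expressed relative to the time-mean midpoint of the two
malleolus markers (the feet are assumed stationary, so the base-of-support
origin is constant per trial). The polar pair is
`mag = √(x² + y²)`, `ang = arctan2(x, y)` — angle measured from the
vertical, anterior lean positive, computed quadrant-safely; the origin maps
to magnitude 0 with an undefined (NaN) angle.

Per cycle, the 8 phase-space variables are `x, y, vx, vy, mag, ang, vmag,
vang`. On the normalized 100-sample grid the polar pair is recomputed from
the resampled `(x, y)` so `mag² = x² + y²` holds exactly; the polar
velocities are resampled from original-rate derivatives, consistent with
the derivatives-before-resampling rule. Summary parameters per variable:
per-cycle max, min and range, their across-cycle means and standard
deviations, and the *range variability* (sd of the cycle-specific range).
Sample sd (ddof = 1) is used; a single cycle, or bit-identical cycles,
report exactly zero spread.

## Synergy extraction and model order (`synergy`)

NNMF minimizes the Frobenius cost with Lee–Seung multiplicative updates,
best of 20 random restarts (max 1000 iterations, stop at 1e-6 relative cost
change). The cost trace is non-increasing by construction; an update that
would raise the cost by more than round-off terminates the restart as
converged. After fitting, W columns are unit-normalized (scale moved into
H) and ordered by ascending activation peak time, so "synergy 1" is always
the temporally first module. All-zero muscles are valid input (they simply
receive zero weights).

The number of synergies is selected by minimizing a Gaussian-residual
information criterion over candidate orders 1–6:

    IC(N) = n_obs · ln(RSS_N / n_obs) + λ · k_N,
    k_N = N · (M + T),  n_obs = M · T.

Two penalties are provided; the default is λ = ln(n_obs) (BIC-form). The
classic λ = 2 AIC is kept for comparison but is not the default: with only
M = 8 muscles, fitting one extra synergy to pure noise reduces the RSS by
roughly the leading noise-eigenvalue share (≈ (1+√(M/T))²/M), which beats a
2-per-parameter penalty essentially always — the criterion then runs away
to the maximum candidate order. The parameter count here grows with the
sample count, which is precisely the regime where AIC is known to be
inconsistent and a ln(n) penalty is required. The criterion function is
pluggable for sensitivity analyses.

Two supporting numerical choices:

* **RSS floor.** The RSS entering the criterion is floored at
  1e-6 · ‖V‖²_F. On exactly factorizable (noise-free) data every order at
  or above the true one converges to pure optimizer round-off, whose level
  is set by the iteration budget rather than the data; the floor converts
  those orders into exact ties, resolved to the smallest order.
* **Cycle averaging.** The pipeline runs order selection and weight
  extraction on the cycle-averaged (mean over the time-normalized selected
  cycles) envelope. Uncorrelated envelope noise averages down with the
  number of repetitions, while a genuine low-amplitude synergy — being
  cycle-coherent — survives averaging, which is what makes a
  small-contribution fourth module separable from noise at realistic SNRs.
  Reconstruction and mapping still use the per-cycle data.

Group analysis: subjects are grouped by selected N_syn; per group, synergy
columns are matched across subjects by exhaustive best-permutation cosine
similarity against the highest-VAF member's weights, averaged column-wise,
and renormalized. Activations are then re-derived for *every* subject with
each group's fixed average W by per-column nonnegative least squares (the
unique minimizer for full-column-rank W, hence deterministic);
reconstructions with a group order different from the subject's own are
kept as cross-reconstructions.

## State-to-synergy mapping (`mapping`)

Each kinematic sample inside an upward-phase cycle is labeled with the
index of the most active synergy. Activations are first rescaled row-wise
by their trial maximum: with unit-norm weights the raw rows carry arbitrary
relative scale, and rescaling makes the across-synergy argmax meaningful
(raw-H labeling is available for sensitivity analysis). Ties resolve to the
lowest index; an all-zero sample carries the previous label forward.

Features and labels are paired at the original kinematic sampling rate
within each cycle (before any time normalization or averaging): the EMG
envelope of the cycle is resampled onto the cycle's kinematic time base,
activations are NNLS-reconstructed there with the group-average W, and the
8 phase-space variables at the same instants provide the features.

The classifier is a Gaussian naive Bayes fitted by closed form: empirical
class priors, per-class per-feature means and variances. Variances are
floored at 1e-9 × (feature range)² (absolute floor 1e-12) so near-constant
features cannot produce degenerate likelihoods. Posteriors are evaluated in
log space and normalized with log-sum-exp. Mappings are fitted in the 8
two-variable spaces (4 cartesian, 4 polar combinations) and additionally in
the plane of the first two principal components of all 8 variables
(variables z-scored first — they carry heterogeneous units — eigenvectors
of the correlation matrix, deterministic sign convention: largest-magnitude
loading positive; zero-variance variables get zero loadings).

Accuracy is the fraction of correct argmax predictions on a held-out 20%
split, stratified by label (stratification preserves class balance in both
halves; the split seed is recorded). Samples are pooled across the group's
subjects and cycles before fitting — a per-subject-then-average variant
would weight subjects equally instead of samples; pooling was chosen and is
flagged as a genuinely open design point. Probability surfaces evaluate the
posterior on a 100 × 100 lattice spanning the data range padded by 5%.

## Statistics (`pipeline`)

Group differences in each phase-space summary parameter (per-subject means
of per-cycle max, min, range, plus range variability, per variable) are
tested with the tie-corrected Kruskal–Wallis H (chi-square p, α = 0.05,
via `scipy.stats.kruskal`). No multiple-testing correction is applied
across parameters (noted in the output). Subjects whose selected N_syn
falls outside the configured group orders {3, 4} form their own group and
are excluded from the two-group statistics with a warning.

The full study (`run_study`) is deterministic under one master seed;
per-subject and per-group seeds are derived by fixed affine rules and
recorded in the result.

## Synthetic cohorts (`synth`)

The generator emulates the study conditions stage by stage:

* **Synergies.** Per synergy-count group one ground-truth template: weight
  columns drawn from sparse gamma(0.8) variates, unit-normalized, redrawn
  until every column pair has cosine < 0.8; activations are Gaussian bumps
  (σ = 15% of the cycle) with centers staggered across the upward phase.
  Four-synergy structure is built by splitting the middle bump into an
  earlier, narrower "extension" burst (center 0.40, σ = 0.08) and a later,
  prolonged "flexion" burst (center 0.62, σ = 0.18) with independent
  well-separated weight columns, so the extra module is a genuinely
  low-energy, temporally overlapping component — the hard case for order
  selection. Subjects share their group's template with a small weight
  perturbation (sd 0.05), the premise that makes group-average weights
  meaningful.
* **Envelopes.** A tonic baseline (0.10 of bump peak — postural muscles do
  not fall silent) plus the bump activations during the rise and a 0.6-gain
  mirrored reactivation during descent, times W, plus rectified additive
  Gaussian noise. The noise sd is per channel (a fraction of that muscle's
  clean peak): envelope variability scales with activation level, and this
  keeps every channel at a comparable SNR so that per-muscle
  max-normalization does not amplify noise-dominated channels. At the
  default levels rectification clips well under 1% of samples, so the
  noiseless mean is essentially unchanged. `noise_sd_for_snr` converts a
  target global SNR (e.g. 20 dB) into the per-channel fraction.
* **Kinematics.** A sagittal 3-segment linkage (shank, thigh,
  head–arms–trunk; segment lengths as fixed fractions of body height)
  anchored at fixed malleoli, driven by a smoothstep sit–rise–stand–descend
  phase profile (15/35/20/30% of the cycle) with a transient forward trunk
  lean during the transition. The cycle duration is calibrated per subject
  so the vertical CoM velocity peak matches the subject's target: a finely
  sampled probe cycle pins the peak at a nominal duration, and velocities
  scale exactly inversely with time scaling. Four-synergy subjects draw
  their targets from a faster distribution (defaults 0.70 vs 0.50 m/s,
  between-subject sd 0.05 m/s) — the group-level kinematic effect the
  statistics stage is meant to detect. Its size is a free configuration
  parameter, not an estimate of the real effect, which is reported only
  qualitatively in the literature.
* **Cohort.** Defaults: 12 subjects split 7 (N_syn = 3) / 5 (N_syn = 4),
  5 cycles per subject, EMG at 1 kHz, markers at 100 Hz, anthropometrics
  drawn around 79 kg / 1.77 m. Everything is bit-reproducible under a
  single master seed with per-subject seeds derived by a fixed affine rule.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: raw (pre-envelope) EMG waveforms and
electrode artifacts; within-subject cycle-to-cycle variability of the
motion (cycles are identical by default, so range-variability parameters
are non-informative in synthetic runs unless jitter is configured);
out-of-plane motion and foot displacement; full-body marker sets; weight
structure that differs substantially across subjects within a group; and
any relationship between anthropometrics and synergy count. Validation on
synthetic cohorts demonstrates the *correctness of the pipeline under its
own model assumptions*, not the physiological claims themselves.

## Problem sizes used in validation

The test suite and acceptance script run at deliberately desk-scale sizes:
20-subject cohorts (5 cycles each) for order-selection recovery, the
12-subject default cohort for the end-to-end study, 100 random models for
the Bayes-posterior oracle, 1000 null simulations for Kruskal–Wallis
calibration, and 10 seeded cohort generations for the group-effect
detection rate. These sizes keep full validation in the minutes range on a
single CPU while leaving the statistical checks well-powered.

## Known limitations

* The information criterion's exact penalty is a design choice among
  defensible alternatives; the implementation makes it pluggable and the
  validation depends only on recovery behavior.
* NNLS reconstruction assumes the group-average W has full column rank;
  pathological rank-deficient averages would make H non-unique.
* The naive Bayes independence assumption is clearly wrong for smooth
  trajectories (adjacent samples are highly dependent); accuracy estimates
  are honest under the stratified split but samples are not independent, so
  they should not be read as generalization to new subjects.
* The 3-segment CoM model omits arms and head motion relative to the
  trunk; absolute CoM positions are approximate even though the pipeline's
  relative comparisons are internally consistent.
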