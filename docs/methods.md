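# Methods

## Model

Each subject is an N-channel time series sampled every TR seconds (default
TR = 2.0 s; the Nyquist frequency 0.25 Hz comfortably contains the band of
interest). The generative and estimation model is a vector autoregression
whose coefficients may drift over time:

    x(t) = Σ_{k=1..p} A_k(t) x(t−k) + e(t),   e(t) ~ N(0, Σ)

with model order fixed at p = 1 by default throughout the pipeline (higher
orders are supported by every routine but are not the default). Channels
are demeaned before estimation; the model carries no intercept.

### Dual extended Kalman filter

Two filters run forward once, in parallel:

* the **state filter** estimates the signal given the current coefficient
  matrix — a standard linear Kalman filter on the companion-form lag stack
  with innovation covariance Σ (taken from the stationary fit) and
  observation-noise variance `state_noise`;
* the **parameter filter** treats the vectorized coefficients as a
  random-walk state observed through the regression equation, using the
  state filter's filtered signal as its regressor.

The parameter filter's process-noise covariance is structured as
Σ ⊗ (q·I) and its observation noise as Σ. With that choice the exact
Kalman recursion factorizes: the full (N²p)² covariance stays of the form
Σ ⊗ Π(t) with Π only (Np)², and the update reduces to the classic
shared-regressor recursive-least-squares form — identical for every row of
A, invariant to the overall signal scale, and cheap enough to filter a
subject together with all of its bootstrap surrogates in one vectorized
pass. For unit innovation covariance this coincides with an isotropic
random walk. Coefficients are initialized at the stationary
ordinary-least-squares AR fit of the full series, with initial parameter
covariance `init_param_cov`·I.

Tuning constants (all exposed in `EKFConfig` and the YAML config):

| parameter        | default | meaning |
|------------------|---------|---------|
| `process_noise`  | 3e-7    | variance of the coefficient random walk per step |
| `init_param_cov` | 1e-4    | initial coefficient covariance around the OLS fit |
| `state_noise`    | 1e-2    | observation-noise variance assumed by the state filter |
| `n_freqs`        | 128     | uniform frequency bins over (0, Nyquist] (≥ 9 bins fall inside 0.009–0.08 Hz at TR = 2 s) |
| `burn_fraction`  | 0.1     | initial fraction of the estimation range excluded from time averages |

The defaults for `process_noise` and `init_param_cov` were calibrated once
against two closed-form properties: on long stationary data the
time-averaged pipeline TPDC must agree with the PDC of the true
coefficients (the magnitude-folding of coefficient fluctuation inflates
zero entries, so stiffer filtering is more faithful in the stationary
limit), and the tracking property (a coupling step at mid-series raises
the second-half coefficient estimate in every seeded run) must be
preserved. Users analysing strongly nonstationary dynamics should raise
`process_noise`; the stationary-limit bias this introduces is the price of
faster tracking. Divergence (parameter covariance trace above
`divergence_cap`) aborts with the offending time index.

### TPDC

From the coefficient trajectory, Ā(f,t) = I − Σ_k A_k(t)e^{−i2πfk·TR} and

    π_ij(f,t) = |Ā_ij(f,t)| / sqrt(Σ_m |Ā_mj(f,t)|²),

the standard column-normalized PDC magnitude, so Σ_i π_ij² = 1 per source
column at every (f,t) — the normalization that makes influences out of
different sources comparable. The identity subtraction in Ā is required
for the zero-coupling case to yield zero off-diagonal influence. The
band-averaged matrix is the arithmetic mean of π over the grid frequencies
inside [0.009, 0.08] Hz (the band where resting-state BOLD physiology
concentrates) and over time after the burn fraction. For p = 1 the
off-diagonal |Ā_ij| is frequency-independent, which the implementation
exploits in closed form; the fast path is tested to machine precision
against the explicit transfer-tensor route. The TPDC diagonal is reported
but carries no inferential meaning (self-influence dominates each column)
and is excluded from all thresholding.

## Significance

**Subject level.** Non-overlapping windows of `window_len` samples
(default 10 — long enough to retain local autocorrelation, short enough to
destroy cross-lag structure; the trailing remainder is dropped) are
permuted to build surrogates; the full TPDC pipeline is recomputed on each
(default 100), and the per-cell 99th percentile of the surrogate values is
the threshold. Observed values strictly above threshold become 1.
Blocks are permuted **independently per channel** by default: a joint
permutation (same block order in every channel) leaves within-block
cross-channel lag structure intact, so the surrogate distribution would
reproduce the very directed coupling being tested and the threshold would
have no power. Per-channel permutation destroys cross-channel lag
alignment while preserving each channel's local dynamics — exactly the
null hypothesis of "no directed coupling". The joint variant remains
available (`per_channel=False`) for nulls that only target slow
nonstationarity. The observed series is truncated to the surrogate length
so observed and surrogate estimates face identical conditions.

**Group level.** Binary matrices are summed into a frequency matrix. Each
of 1,000 permutations shuffles every subject's 42 off-diagonal cells
uniformly — preserving that subject's total edge count, which is the only
margin a flat shuffle of a flattened matrix can preserve — and
re-aggregates; the per-cell 99th percentile of the permuted frequencies is
the threshold, and strictly larger observed frequencies are
group-significant. A row-margin-preserving variant (shuffling within each
target row) is available behind `mode="margins"`. The diagonal is excluded
from shuffling and inference.

Strict `>` is used at both thresholds, so a degenerate null (all surrogate
values equal to the observed) never produces a detection.

## Classification and clinical statistics

Connectivity matrices are flattened row-major into named features
("SRC->TGT"), 49 per subject with the diagonal or 42 without (continuous
TPDC values by default; binary mode available — continuous features
subsume the binary information). A 100-tree random forest (other
hyperparameters at scikit-learn defaults, recorded in the report JSON) is
evaluated on a stratified 70:30 split plus stratified 10-fold
cross-validation; impurity importances rank the top-5 connections. ROC
curves use the positive-class probability (configurable; the earlier
disease stage by convention).

Correlations use Pearson for continuous scores and Spearman for ordinal
scales; a score-type registry (`hy_stage` is ordinal; `np3_total`, `bis`,
`barratt`, `conscientiousness` continuous; extensible via
`register_score`) enforces the choice and refuses Pearson on ordinal
scores. Group comparisons regress a connection's values on a 0/1 group
indicator: the slope is the mean difference, the t-test p equals the
two-sample equal-variance t-test p (verified against scipy in the tests),
and r² is the squared point-biserial correlation. The Friedman test takes
explicit equal-length matched groups (matching is the caller's choice; no
hidden subsampling); the fully-tied degenerate case returns statistic 0,
p = 1, where the tie-corrected statistic is undefined. Bonferroni
adjustment is applied over an explicit family of tests.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
stable VAR(1) dynamics on the seven canonical networks (fixed channel
order VIS, SMN, DAN, VAN, LIN, FPN, DMN), group-specific directed edge
sets, per-subject Gaussian jitter of nonzero couplings
(rejection-sampled to stability, at most 100 retries), i.i.d. Gaussian
innovations, optional additive observation noise, and a 50-sample burn-in.
Clinical scores are linear in a designated connection's true coupling plus
Gaussian noise, so correlation recovery has a closed-form target (with
noise SD equal to the coupling's across-subject SD, the population Pearson
r is 1/√2).

Four built-in templates encode qualitatively distinct population patterns:
young controls with bidirectional control↔somatomotor coupling plus
default-mode→control and attention→limbic influence; older controls that
lose the control↔somatomotor loop and gain attention/limbic→somatomotor
and control→default-mode edges; a prodromal disease stage whose
somatomotor network has no outgoing edges at all, with
attention→somatomotor/control compensation; and a manifest stage where
somatomotor output re-routes through the visual network. Edge magnitudes
are free parameters (default 0.3 off-diagonal, 0.5 self-coupling; all four
templates verified stable at construction) — the patterns, not the
magnitudes, are what the templates pin down.

What the generator does **not** model: hemodynamic convolution, scanner
drift, motion, physiological noise, spatial correlation of innovations.
Passing tests therefore demonstrate correctness of the estimation and
inference machinery under the model's own assumptions, not robustness to
real fMRI artefacts.

## Numerical and design choices

* Frequency grid: m·Nyquist/n_freqs for m = 1..n_freqs; band selection is
  inclusive on both edges; an empty band on the grid is an error, as is a
  zero-norm transfer column (degenerate normalization).
* Files: TSV with 17-significant-digit floats (lossless round trip),
  fixed '\n' endings, deterministic writers; matrix files carry kind and
  orientation in comment headers. TR is supplied by the caller — plain
  tables carry no time metadata.
* Determinism: every stochastic stage takes an explicit seed; the pipeline
  derives per-stage and per-subject seeds from one root seed via
  `SeedSequence` spawning, and rerunning a config reproduces byte-identical
  outputs.
* Filtering only, no smoothing: estimates at time t use data up to t, so a
  single forward pass suffices and the bootstrap stays affordable. A
  Kalman smoother would reduce the transient but is out of scope.
* Stage outputs are files (inspectable, resumable via `--resume-from`),
  not in-memory handoffs.

## Validation scales

The test suite and `scripts/acceptance.py` validate at these problem
sizes, chosen to make Monte-Carlo margins comfortable at desk scale:
normalization and zero-coupling identities on single runs (T = 250–400);
the white-noise floor on 6 runs of T = 400 (per-cell ensemble mean and
median per-run maximum — the maximum over 42 cells of a single run sits at
the irreducible small-sample OLS floor of roughly 0.12 and is not a
systematic quantity); the stationary limit on 20 runs of T = 2000 against
the closed-form PDC of the true couplings; edge recovery on cohorts of 20
subjects (T = 400, coupling 0.4) with full defaults — 100 bootstrap
shuffles, 1,000 permutations, 99th percentiles — over 20 seeds in the test
suite and 10 in the acceptance script; null calibration on 50 (script: 25)
independent-channel cohorts of 8 subjects at T = 200 plus 1,000 null
correlation tests; classifier checks on 50 subjects per class (T = 400)
with 10-fold CV, 20 label-permutation refits, and 10 planted-feature
seeds; clinical recovery at n = 500 subjects.

## Known limitations

* The stationary-limit agreement is bounded below by magnitude folding of
  finite-sample coefficient noise (≈ 0.8·σ per zero entry); longer series,
  not tuning, is the only way past it.
* The bootstrap assumes block permutation destroys the dependence of
  interest; couplings at lags much longer than `window_len` would survive
  in the surrogates and lose power.
* The flat group-level shuffle preserves per-subject totals only; if
  per-target in-degrees must be held fixed, use `mode="margins"`.
* With very small `process_noise` the "time-varying" coefficients are
  nearly stationary; raise it (and accept a higher noise floor) to study
  genuine dynamics.
* p > 1 estimation is implemented but the fast closed-form band average
  only applies to p = 1; higher orders use the explicit complex transfer
  path and are slower.
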