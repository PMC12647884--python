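# Methods

## Model

The transformation assumes that class membership of a series is
reflected in *locally stable linear structure*: short windows of a
class-`y` signal approximately satisfy linear recurrences that windows
of other classes do not. A window of length `r = s(2l-2)+1` starting at
`t` (1-based `t`; the API is 0-based) is arranged into the symmetric
delay embedding

    S[p,q] = x[t + (p+q-2)s],  p,q = 1..l,

built from `2l-1` evenly spaced samples. If the signal locally satisfies
a recurrence of order `d < l` at spacing `s`, the row space of `S` has
rank at most `d`, so `S` has a (near-)null eigenvector: the *shapelet
law* `v = argmin_{|lambda|}` eigenvector, equivalently the minimiser of
`||S v||` over unit vectors. The law is an annihilating filter whose
characteristic polynomial contains the signal's local roots; applied to
any same-spacing row of the same signal it returns (near) zero, while
rows of signals with different roots produce responses of the order of
the non-shared component's amplitude times the filter's gain there.
This asymmetry — near-zero within class, bounded away from zero across
classes — is what the pooled energy features expose.

Two-stage pooling of squared responses (per class: mean or q-quantile
across a dictionary's class columns within each window row, then a
population moment across rows) makes the representation independent of
the series length and of window positions, hence robust to local
misalignment: a phase shift permutes rows but leaves row statistics
unchanged.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `r` | window length (samples) | — | must satisfy `r = s(2l-2)+1`, `r <= min_i h_i` at training, `r <= H` at inference |
| `l` | embedding dimension | — | `>= 2`; laws can annihilate recurrences of order `< l`; eigendecomposition is `O(l^3)` per window |
| `k` | window stride (samples) | — | `>= 1`; divides window and row counts |
| `s` | derived spacing | `(r-1)/(2l-2)` | must be a positive integer |
| `rho` | LT ratio: fraction of training instances that build dictionaries | 0.25 | per class `max(1, floor(rho * n_class))`, stratified, seeded; `rho = 1` reuses the LT instances for classifier training (with a warning) |
| pooling pair | across-laws then across-windows statistic | `mean-mean` | quantiles use linear interpolation ("type 7"); moments are population moments |
| `k` (KNN) | neighbor count | 1 | benchmark protocol selects from {1, 3, 5} by seeded stratified CV |

## Numerical choices

- **Eigensolver**: dense symmetric (`scipy.linalg.eigh`); `l` is small
  in practice (<= ~140 in published schedules), so `O(l^3)` per window
  is the intended cost profile.
- **Eigenvalue tie-break**: the argmin over `|lambda|` is ill-posed for
  degenerate spectra (e.g. constant windows). Among eigenvalues within
  `1e-12 * max(1, ||S||)` of the minimal magnitude, the smallest signed
  eigenvalue is taken; residual degeneracy resolves to the first
  position in ascending eigenvalue order.
- **Sign convention**: `v` is flipped so its largest-magnitude entry
  (lowest index on ties) is positive. Responses are squared downstream,
  so this affects only the reproducibility of stored dictionaries.
- **Quantile convention**: linear interpolation between order
  statistics, the most common default; the choice is visible only
  through feature values, never through their ordering guarantees.
- **Excess kurtosis of a near-constant sequence** (`m2 <= 1e-24 *
  max(1, mean^2)`) is defined as 0 to avoid NaN features; exactly this
  case arises for noiseless in-class responses, which are ~0.
- **Squaring applies before both pooling stages and to every pooling
  pair**, including mean–mean.
- **Non-finite samples** inside any window are a hard error rather than
  being skipped: silent NaN propagation through eigendecompositions
  produces unusable dictionaries.
- **Windows are never padded**: a window whose tail would pass the end
  of the series is not formed, and an instance shorter than `r` is an
  error naming the triplet.
- **Channels are never mixed**: channel `j` is projected only onto
  dictionaries built from channel `j`.
- **Duplicate schedule triplets are rejected** — they would silently
  duplicate feature columns.
- A dictionary in which some class contributed zero laws is a
  configuration error (class-wise pooling would be undefined), not an
  empty feature block.

## Synthetic data

The generators produce the structure the method is designed to detect,
so every stage is testable without external datasets:

- `two_class_sinusoid_spec`: two classes of unit-channel sinusoids
  (angular frequencies 0.3 vs 0.9, length 100, 20 instances per class),
  uniformly random phase per instance so classes are not separable by
  alignment alone. Amplitude is 10, chosen once so that the integer
  noise grid `{0..20} x N(0,1)` spans near-noiseless (multiplier 1,
  SNR ~ 7) to noise-dominated (multiplier 20) conditions — the regime a
  noise-robustness protocol needs. A noiseless sinusoid satisfies a
  fixed order-2 recurrence at every spacing, so any `l >= 3` embedding
  is rank-deficient and in-class annihilation is exact.
- `noise_robustness_spec`: the sweep surrogate. The same two class
  tones are masked by a *shared* nuisance tone (frequency 1.7,
  amplitude 20, independent random phase). This emulates a dominant
  common rhythm — baseline wander, mains hum, gait periodicity — that
  dominates raw sample-space distances while carrying no class
  information. Classes still differ by the order-4 recurrence each
  satisfies, so `l >= 5` laws separate them exactly in the noiseless
  limit; raw-sample nearest neighbors hover near chance. Without the
  nuisance component a raw 1-NN is itself nearly perfect on pure
  sinusoid classes (some same-class training phase is always close),
  leaving no transformation advantage to measure.
- `ARClass`: stable autoregressions (stationarity checked through the
  characteristic roots) for recurrence classes with stochastic
  excitation.

What the generators do **not** emulate: non-stationary drift, variable
sampling rates, cross-channel coupling, heavy-tailed noise, label
noise. Passing tests demonstrate the annihilation mechanism and the
protocol machinery, not performance on any real archive.

Additive noise at level `M` adds i.i.d. `N(0, M^2)` to every sample of
both splits (level 0 is bit-exact identity). The level is accepted as
any non-negative float; the standard grid is the integers 0..20. Noise
is applied to train and test alike by default (switchable), since a
robustness protocol that trains clean and tests noisy answers a
different question.

## Experiment protocols

- **Noise sweep**: one seeded stratified 50/50 split held fixed;
  repetition randomness is the noise draw. Raw, single-scale and
  multiscale representations of repetition `r` at level `M` see
  byte-identical noisy data (child seeds derived from the master seed
  via a stable hash), which is what makes paired tests valid. Defaults:
  21 levels, 30 repetitions, built-in 1-NN.
- **Repeated benchmark**: R seeded stratified resamples (default 30);
  per repetition each representation is fitted on the same split;
  validation accuracy comes from seeded stratified cross-validation
  over a small deterministic neighbor grid {1, 3, 5} (a deliberate
  replacement of black-box hyperparameter optimisation — the
  representation, not the tuner, is under study). Wall-clock times are
  recorded and reported, never asserted.
- **Significance**: per dataset a two-sided paired Wilcoxon signed-rank
  test over repetitions. Zero differences are dropped (classical
  convention); all-zero difference vectors give p = 1 and no rejection.
  The exact null distribution is used for n <= 25 when the absolute
  differences are untied, otherwise the normal approximation with
  continuity correction. Holm step-down correction is applied across
  datasets at level 0.05.

## Problem sizes

The default test and acceptance runs use the synthetic specs above
(40-instance datasets, length 100, schedules with `l <= 5`), 10–30
repetitions for stochastic checks, and counting-identity sweeps of 500
random configurations — sizes chosen so the full suite documents the
method's properties in well under a minute of numerical work while
leaving every formula exercised at non-trivial scale. Larger problems
change only runtime: all counts are closed-form-checked, and the cost
model predicts scaling before a run is attempted.

## Known limitations

- Schedule selection is manual; there is no automatic discovery of
  `(r, l, k)` (explicitly out of scope).
- Dictionaries grow linearly with LT instances, window counts and
  schedule density; no pruning or redundancy removal is performed.
- Laws are extracted per channel; cross-channel dependencies are not
  modeled.
- The raw baseline requires equal-length instances; the law-based paths
  handle variable lengths natively.
- Pooling statistics are fixed, not learned.
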