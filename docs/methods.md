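# Methods

## Model overview

The pipeline predicts per-excerpt mean valence and arousal ratings (rescaled
from the [-1, 1] rating grid to [0, 1]) from two feature channels and
combines the channel experts at a meta level.

**Expert networks.** Each expert is a feedforward perceptron with one sigmoid
hidden layer of 3 units and a sigmoid output, trained by full-batch gradient
descent: per-example gradients of ½(y − t)² are accumulated over the epoch
(examples presented in a freshly randomized order each epoch — mathematically
inert for a summed update, retained for procedural fidelity) and applied once
at the epoch's end with learning rate 0.1. Weights start uniform in
(−0.05, 0.05). Training stops when the training-set mean squared error falls
below 0.045, or at `max_epochs` (default 50 000), in which case the best
weights seen are kept and a warning is issued — non-convergence is a reported
condition, not an error. Biases are included by default; a bias-free mode
(`use_bias: false`) reproduces the strictly minimal two-weight-matrix
architecture. Separate networks are trained per dimension, so valence
training never reads arousal targets.

**Cross-validation layout.** Of the 60 excerpts, 16 (4 per genre) are held
out for testing; 4 (1 per genre) are "always-train" excerpts; the remaining
40 form five genre-balanced folds of 8 (2 per genre). Each fold's network
trains on the other four folds plus the always-train excerpts — 36 excerpts,
9 per genre. Membership is drawn uniformly at random within genre strata from
a seeded stream. The five fold networks form an ensemble whose prediction is
their unweighted mean.

**Committee machines.** CMEA averages the perception and feeling ensemble
outputs with equal 0.5 weights. CMLR regresses the mean ratings (0–1 scale)
on the two ensemble outputs plus an intercept by OLS; by default the fit uses
all 60 excerpts (the train+test leakage this implies is deliberate, matching
the original procedure; `fit_scope: train` restricts the fit to the 44
training excerpts for a leakage-free variant). Channel salience is reported
as contribution percentages 100·|b|/(|b_perc|+|b_feel|), intercept ignored;
absolute values guard against sign flips on synthetic data. Reported
percentages are rounded half-up to one decimal. OLS optimality guarantees
CMLR's in-sample RMSE never exceeds CMEA's; the pipeline asserts this on
every run.

**Comparison arms.** Stepwise forward regression runs once per fold on its
36-excerpt training set with the conventional p-of-F thresholds (enter ≤
0.05, remove ≥ 0.10, both configurable; enter < remove is enforced to
prevent cycling). A fold in which no candidate meets the entry criterion
yields "no model"; the test-set ensemble averages only the fitted folds, and
an all-no-model arm is reported as a "no model" cell, not as 0. The random
forest (500 trees, ⌊p/3⌋ features per split, minimum leaf 5, bootstrap
resampling) is trained once on the 44 training excerpts without
cross-validation, since bagging already resamples; scikit-learn provides the
tree machinery behind this module's contract.

## Preprocessing

Feature reduction computes the Pearson correlation matrix of the 12 audio
features (and, separately, the 5 physiological features) and greedily removes
features while any pair exceeds |r| > 0.8 (strict inequality): the feature
with the most violating partners goes first, ties broken by larger mean |r|
to the remaining features, then by input order. This rule reproduces the
canonical outcome on the documented spectral pattern (centroid correlated
with spread, rolloff and brightness; spread with rolloff): centroid is
removed, then rolloff, retaining spread and brightness. Zero-variance columns
have undefined correlations; they are flagged and never counted as
violations.

Inputs are min–max scaled to [0, 1]. Scaling is fit on the full 60-excerpt
table by default, treating scaling as a dataset-level step; `scaling_scope:
train` fits on the 44 training excerpts only (values outside the fitted range
then map outside [0, 1]; they are not clipped). Constant features map to 0.5
with a warning. Mean ratings map affinely from [-1, 1] to [0, 1]. Physiology
enters as baseline-corrected values (excerpt minus white-noise baseline);
`baseline_subtract` refuses missing baselines rather than assuming zero, and
subtraction precedes scaling. Missing values are rejected at ingest, not
imputed. The initial analyses report feature–rating Pearson correlations with
df = n − 2 (58 at the default design) and two-sided t-based p-values.

## Synthetic-data generator

The generator emulates the listening study's design, not its raw signals:

* **Design.** 60 participants × 12 excerpts, every excerpt rated by 12
  unique participants, each participant hearing 3 excerpts per genre. The
  balanced incidence is built per genre from contiguous blocks of a seeded
  random excerpt ordering with cycling block starts, giving exact row and
  column sums; infeasible counts raise a configuration error.
* **Audio features.** Standard-normal latents mapped through a logistic
  squash onto plausible per-feature ranges (tempo 60–180 bpm, centroid
  500–3500 Hz, mode in [0, 1], …). The four spectral features share one
  latent factor with loading √0.9, so their pairwise correlations sit near
  0.9 (all above the 0.8 reduction threshold); genre offsets add mild
  between-genre structure. The default reduction therefore keeps one feature
  of the spectral block — an intended consequence of giving the whole block a
  single common factor.
* **Latent affect.** `latent = tanh(w_perc·g(audio) + w_feel·h(physio))`,
  with g and h fixed degree-2 polynomial maps on the standardized features
  (coefficients hard-coded in `synthetic_data.py`; signs follow the
  literature: event density and brightness raise arousal and lower valence,
  major mode raises valence, Zyg−Corr tracks valence, HR/SCL/Resp track
  arousal). Default mixing weights — valence (0.8, 0.2), arousal
  (0.45, 0.55) — encode the study's qualitative finding that valence
  judgments are perception-dominant and arousal judgments feeling-dominant.
  Setting a dimension's mixing to (1, 0) or (0, 1) makes its ground truth a
  function of one channel alone, which the parameter-recovery tests exploit.
* **Physiology.** Felt-affect drivers blend the audio-driven affect
  (coupling 0.5) with an independent component; each channel loads on its
  driver (Zyg +, Corr −, HR/SCL/Resp +) plus noise, then maps onto plausible
  baseline-corrected delta ranges. Plausible absolute baselines are generated
  alongside so baseline subtraction can be exercised.
* **Ratings.** Per (participant, excerpt) rating = latent + N(0, 0.3) noise
  (the noise scale is a free choice, exposed in config — no empirical value
  exists to match), clipped to the [-1, 1] grid, mimicking its bounds;
  excerpt means average the 12 raters, shrinking noise ≈ √12-fold.

What the generator does **not** emulate: raw waveforms or signal filtering,
continuous bar-by-bar rating trajectories, per-participant rating biases or
genre-specific response styles, and any guarantee that the audio→affect maps
match real music. Passing tests therefore demonstrate that the pipeline
recovers structure that is present by construction — they validate the
machinery, not the psychological claims, which would require real data.

## Numerical and design choices

* All randomness flows from one pipeline seed through named SHA-256-derived
  substreams (design, excerpts, ratings, partition, one per network, one per
  forest), so runs are bit-reproducible and stages are independently
  re-runnable; artifacts are files, not in-memory hand-offs.
* CSV artifacts are written at full float precision and read back with
  round-trip parsing, so a write/read cycle is bit-exact.
* The epoch MSE is evaluated with the weights the epoch started from (the
  update applies at the epoch's end); convergence compares that MSE to the
  0.045 target.
* Stepwise entry uses the partial-F p-value of the added coefficient (equal
  to its two-sided t-test p), the standard single-degree-of-freedom identity
  F = t².
* Rank-deficient CMLR designs (exactly collinear ensemble outputs) raise an
  explicit error rather than silently pseudo-inverting.
* Fold indices are 0-based throughout.
* Default problem sizes run the whole pipeline in a few seconds on one CPU;
  all 20 networks converge well inside the default 50 000-epoch cap (audio
  networks within a few hundred epochs, physiology networks within a few
  thousand at default settings).

## Known limitations

* Committee-machine inputs are consumed on the 0–1 scale (consistent with
  the printed intercepts of the published stacking equations); no option is
  provided to stack on the [-1, 1] scale.
* The generator's affect maps are smooth and low-order by design; MLP
  advantages over linear baselines on real data may be understated or
  overstated on such targets.
* PCA-style projection reduction and nonlinear meta-learners are out of
  scope by design.
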