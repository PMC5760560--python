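# musemo

Hybrid perception/feeling ("cognitivist"/"emotivist") modeling of music
emotion judgments, built as a reusable, fully seeded pipeline.

## The problem

When listeners judge the emotion of a piece of music on the two-dimensional
valence–arousal (VA) grid, is that judgment driven by what they *perceive* in
the music (a cognitivist account, modelable from audio features) or by what
they *feel* while listening (an emotivist account, modelable from
psychophysiology — facial EMG, skin conductance, heart rate, respiration)?
A hybrid account treats the judgment as a meta-level combination of both.

`musemo` implements that hybrid account as a **committee machine**:

* a *perception* expert — an ensemble of five multilayer perceptrons
  (10 inputs → 3 sigmoid hidden units → 1 sigmoid output) trained on audio
  features from five genre-balanced cross-validation folds;
* a *feeling* expert — the same architecture (5 inputs) trained on
  baseline-corrected physiological features;
* two committee machines on top: **CMEA**, the equal-weight average
  `y = 0.5·x₁ + 0.5·x₂` of the two ensemble outputs, and **CMLR**, a linear
  stack `y = b₁·x₁ + b₂·x₂ + c` with coefficients fit by ordinary least
  squares of the mean ratings on the ensemble outputs.

The salience of each channel is read off the CMLR coefficients as
contribution percentages `100·|bᵢ| / (|b₁|+|b₂|)` (intercept ignored).
Stepwise forward regression (p-of-F entry ≤ 0.05, removal ≥ 0.10) and random
forests serve as lower- and higher-flexibility comparison arms.

Because the original listening-study data were never deposited, the package
ships a first-class synthetic-data generator that emulates the study design:
60 excerpts in 4 genres (15 each), 60 participants each rating 12 excerpts
with every excerpt rated by 12 unique listeners, a collinear spectral-feature
block (|r| > 0.8 among centroid/spread/rolloff/brightness), physiological
features coupled to latent affect, and a configurable perception-vs-feeling
mixture generating the latent VA signal — so the whole analysis runs with no
downloads and every finding can be checked against known ground truth.

## Worked example

```bash
musemo run-all --seed 1 --out run1
```

prints the summary grid (test RMSE on the 16 held-out excerpts, 0–1 rating
scale) and the fitted CMLR contribution percentages:

```
             method  feature_set dimension  test_rmse  n_models
     neural_network        audio   valence   0.228335       5.0
     neural_network        audio   arousal   0.248403       5.0
     neural_network       physio   valence   0.259396       5.0
     neural_network       physio   arousal   0.229888       5.0
stepwise_regression        audio   valence   0.115132       5.0
...
               CMLR audio+physio   valence   0.122827       NaN
               CMLR audio+physio   arousal   0.071620       NaN
valence: perception 87.5% / feeling 12.5%
arousal: perception 23.5% / feeling 76.5%
```

At the default generator settings the valence signal is mostly carried by the
audio channel and the arousal signal mostly by the physiology channel, and the
fitted committee machine recovers exactly that asymmetry: perception dominates
valence, feeling dominates arousal. CMLR beats the equal-weight committee
in-sample by construction (OLS optimality) and here also on the test set.

Each stage is independently re-runnable (`musemo simulate|preprocess|
partition|train|committee|baselines|report`, each with `--config/--seed/--out`)
and leaves its artifacts (`excerpts.csv`, `feature_reduction.json`,
`partition.json`, per-fold network JSON, `committee.json`, `report.csv`, …)
in the output directory. A fixed (config, seed) pair reproduces every
artifact byte for byte.

The library surface mirrors the pipeline: `musemo.generate_dataset`,
`musemo.reduce_features`, `musemo.train`, `musemo.fit_cmlr`,
`musemo.contributions`, `musemo.stepwise_forward`, `musemo.fit_forest`, …
— see `docs/methods.md` for the modeling details.

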