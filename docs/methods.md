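# Methods

This note records the modeling assumptions, default parameters and numerical
choices behind `beernir`. Problem sizes and budgets are the package's own
defaults, chosen to run on one CPU in minutes; the `--full` budgets restore
protocol-scale settings.

## Signal model and simulator

The working signal is base-10 absorbance A = −log10(I/I₀) on a 228-point
grid over 900–1700 nm. The simulator writes each clean spectrum as a linear
mixture of Gaussian component bands:

* **ethanol** — C–H/O–H overtone bands at 1180, 1400 and 1660 nm, amplitude
  proportional to alcohol (%vol);
* **sugars** (1170/1420/1680 nm) and **organic acids** (1430 nm) — scale
  with original wort concentration (°P);
* **protein/amino acids** — one band at 1500 nm whose strength carries the
  class signature: craft (all-malt) factor 1.0, industrial (adjunct) 0.45,
  non-fermented blend 0.0;
* **water** — a broad 1440 nm background; **additives** — a broad weak
  1300 nm band present only in the blended product.

Per-spectrum noise: multiplicative scatter (sd 0.02), baseline offset
(sd 0.01 AU), linear drift (sd 1e-5 AU/nm) and additive white noise
(sd 0.002 AU). `NoiseModel.silent()` disables all four for oracle tests.

The default inventory mirrors a three-arm study design: 23 craft styles × 2
batches × 3 bottles (138), 13 industrial styles × 2 × 3 (78), and a
non-fermented formulation cross of 4 alcohol × 5 wort levels × 6 replicates
(120) — 336 spectra. Commercial declared values are drawn per style
(seeded) and snapped to 0.1, emulating label precision.

**Scope and limits.** The simulator reproduces the *statistical structure*
the pipeline assumes (linear Beer–Lambert mixing, class-specific protein
signal, instrument-like noise), not real beer spectra: band positions and
strengths are stylized, and matrix effects beyond multiplicative scatter are
absent. Conclusions about *relative* method performance transfer; absolute
error magnitudes do not.

## Preprocessing

Operators: Savitzky–Golay smoothing (window 11, polyorder 2), MSC (per-row
affine fit to a reference, default the column mean — pass the calibration
mean to avoid leakage), SNV (row-wise ddof-1 standardization), wavelet
denoising (db4, level 3, soft universal threshold with the MAD/0.6745 noise
estimate from the finest detail level), and Fourier denoising (zero all
rFFT bins above ceil(0.1 · n_bins)). Chains are ranked by seeded 10-fold
CV on calibration rows only (PLSR RMSECV for regression, PLS-DA ACCCV for
classification). Shipped per-task defaults: WD (alcohol), SNV (wort),
WD+FT (classification).

## Partitioning

2:1:1 calibration:validation:test. The external test quarter is a uniform
seeded random holdout (optionally stratified by class); the remainder is
split 2:1 by SPXY — greedy Kennard–Stone max-min selection under the joint
distance d = d_x/max d_x + d_y/max d_y. Ties break toward the smallest
index, making the split a pure function of (X, y, n_cal). Classification
uses the one-hot class indicator as the y-block.

## Wavelength selection

**CARS.** Each iteration subsamples 80% of calibration rows, fits PLS and
weights variables by |coefficient|. An exponentially decreasing schedule
r_i = a·e^(−k·i) (calibrated so iteration 1 keeps all p and iteration N
keeps 2) forces the top-k variables, followed by adaptive reweighted
sampling (k weighted draws with replacement; the unique draw survives). The
best iteration minimizes RMSECV (or maximizes ACCCV). Because single runs
are stochastic, the frequency variant repeats the run (default 50×), counts
best-subset membership per wavelength, and sweeps occupied count thresholds,
scoring each thresholded subset by 10-fold CV; ties prefer smaller subsets.

**SPA.** Column-standardized orthogonal projection chains from every start
column (y-independent), candidate (start, m) sets scored by cross-validated
MLR PRESS, then backward elimination in relevance order
(|coefficient| · column sd) while PRESS does not worsen by more than 0.1%
relative. Rank-deficient designs fall back to a small ridge with a warning.

## Deep feature extractors

Three architectures map a spectrum to a d-dimensional feature vector read
off the penultimate fully-connected layer (d = `numResponses`):

* `cnn`: two 1-D conv modules (He init, same padding, ELU, average pool 2;
  the second doubles the channels) → flatten → FC(d) → head;
* `lstm`: the spectrum as a sequence → LSTM (final state) → FC(d) → head;
* `cnn_lstm`: conv modules → LSTM (full sequence) → 4-head self-attention
  (40-dimensional key/value space, 10 per head) → temporal mean pool →
  FC(d) → head.

Training: Adam on shuffled **mini-batches of 8 rows**, step-decay learning
rate (factor `LearnRateDropFactor` every `LearnRateDropPeriod` epochs), L2
penalty on weight matrices, global-norm gradient clipping at 5, MSE loss for
regression (targets standardized) and cross-entropy for classification. The
objective for hyperparameter search is RMSECV/ACCCV pooled over k
calibration folds (default 5; 3 at desk scale); the returned model is refit
on all calibration rows.

Two numerical choices matter and are deliberate:

* **Mini-batches rather than one full-batch update per epoch.** At the
  desk-scale epoch cap (≤ 60) a full-batch schedule yields at most 60
  optimizer steps and the CNN-LSTM badly underfits (RMSECV ≈ 1.3 vs. a
  target sd of 1.8 on the default alcohol task); 21 updates/epoch closes
  the gap within the same cap.
* **Scalar input standardization.** Inputs are standardized by a single
  mean/sd over all calibration absorbances. Per-wavelength z-scoring
  whitens away relative band amplitudes and amplifies noise-dominated
  channels, which defeats weight-shared convolutions — it caps
  SVR-on-features test R² near 0.95 where scalar scaling reaches ≈ 0.998.

Hyperparameters are tuned by Bayesian optimization: a Gaussian-process
surrogate (Matérn 5/2, constant amplitude) with expected-improvement
acquisition (ξ = 0.01, 256 random candidates per step) over bounds
numResponses [16,128], FiltSize [3,15], numChannels [8,64], numHiddenUnits
[16,128], MaxEpochs [50,400], InitialLearnRate [1e-4,1e-2] (log),
LearnRateDropPeriod [50,150], LearnRateDropFactor [0.4,0.95], L2
[1e-10,1e-2] (log). Failed (non-finite) evaluations are recorded and
excluded from the surrogate. Desk-scale budgets shrink MaxEpochs (≤ 60),
numChannels (≤ 16) and numHiddenUnits (≤ 48) and use 8–20 total
evaluations; `Budgets.full()` restores 200 iterations × 400 epochs.

## Models and evaluation

* **PLSR** — NIPALS (scikit-learn), latent variables by minimum 10-fold CV
  PRESS; at full rank it reproduces OLS.
* **PLS-DA** — one-hot PLS regression with argmax decoding; LVs by maximum
  CV accuracy, ties to fewer components; stratified folds.
* **SVR** — RBF kernel, features standardized; grid C ∈ 2^{−5..15},
  γ ∈ 2^{−15..3} (step 2²), ε ∈ {0.01, 0.05, 0.1} by 5-fold CV RMSE.
* **ELM** — uniform random input weights (nested across hidden-unit
  counts so the grid reuses one basis), sigmoid hidden layer, pseudo-inverse
  readout; width and ranges by CV.

Metrics: R² = 1 − SSres/SStot, RMSE, rRMSE = 100·RMSE/mean(reference of the
subset), RPD = sd(reference)/RMSE, each computed strictly per subset;
classification reports ACC, macro precision/recall, macro and weighted F1
(percent) plus the confusion matrix. Prediction–reference agreement is also
checked by a two-tailed paired t-test (α = 0.05), whose type-I error is
verified at ≈ 5% under the null in the test suite.

## Leakage policy

Preprocessing selection, partition statistics, wavelength selection, BOA
objectives and all model grids see calibration rows only. Validation tunes
nothing; the test quarter is touched exactly once per experiment, at final
evaluation.
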