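# Methods

## Model and procedure

FS-PLS is greedy forward selection in which the feature matrix, not the
outcome, is orthogonalised between steps. Let X be the centred m × p matrix
(per-feature means μⱼ recorded at centring) and y an outcome of family
gaussian, binomial or multinomial. With Xᵏ the matrix of the k selected
columns and U an orthonormal basis of its column space (thin SVD, singular
directions below 1e-10 × σ_max dropped), the deflated matrix is
Rᵏ = X − UUᵀX. Every column of Rᵏ is orthogonal to the selected set, so the
selected columns themselves (and anything collinear with them) have ~zero
variance and leave candidacy; columns whose deflated variance falls below
1e-12 are excluded each round.

Each step fits, for every candidate column d of Rᵏ, the GLM

    η = η_{k−1} + a + b·d

where η_{k−1} is the accumulated linear predictor held fixed as an offset
(η₀ is the intercept-only fit). The candidate with maximal log-likelihood
wins (ties to the lowest column index); its coefficient is then re-fitted
with an L2 penalty λ·β_std² (the feature standardised to unit variance
inside the penalty only), and the step's significance is a χ² test of
2·(ℓ_step − ℓ_offset-only) on df = 1 (C−1 for multinomial). Selection stops
at p ≥ threshold, at `max_features`, or when no candidate column retains
variance. Coefficients are frozen once estimated.

Fitting the step *with the accumulated predictor as offset* (rather than a
fresh intercept-only univariate fit of y) is a deliberate choice among the
two readings the stopping rule admits. It makes the recorded per-step
cumulative log-likelihoods non-decreasing by construction — the nested-model
property a likelihood-ratio test presumes — and at step 1 the two readings
coincide exactly, so the null calibration of the stopping rule is identical
either way. The practical difference appears only for binomial/multinomial
outcomes from step 2 on, where a fresh univariate fit would ignore the
probability mass already explained.

### Families

* gaussian — least squares with the profile (MLE) error variance in the
  log-likelihood, so LRT statistics are self-contained; the profile variance
  is floored at 1e-12 to keep exact fits finite.
* binomial — logistic IRLS/Newton, vectorised across all candidate columns
  at once (each column is an independent 2-parameter problem with a closed
  2×2 Newton solve).
* multinomial — exact multinomial likelihood with class 0 as reference,
  damped Newton on the 2(C−1) parameters of each candidate column. A
  single-hidden-layer approximation of this likelihood exists in other
  software; the exact likelihood is better defined and directly testable,
  and is what ships here.

Separation (binomial/multinomial) is handled by capping the slope at 30 on
the standardised scale and flagging the fit `converged=False`; selection
then remains well defined on separable data. Iterative fits converge on
relative log-likelihood change 1e-8, max 100 iterations. Sample weights, if
given, multiply the per-sample log-likelihood terms everywhere (univariate
fits, refits, null model); inverse-class-proportion weights
w_i = n/(C·n_c) are provided as the built-in weighting.

### Ridge refit strength

The penalty convention is penalised log-likelihood ℓ − λβ_std², with
default λ = 0.01 (user-configurable). No selection procedure for λ is
prescribed by the method itself; the default is small enough to leave the
gaussian/orthonormal identities intact at λ = 0 (tests exercise that limit)
while giving near-separable logistic refits a proper optimum.

### Prediction replay

Prediction must work for one sample in isolation — no batch statistics.
Each step stores its unit basis direction u_k (the normalised deflated
selected column) and the loading row u_kᵀX over features. A new sample's
centred selected-feature values are deflated recursively:

    t_k = z_{j_k} / (u_kᵀ x_{j_k}),   z_j ← z_j − t_k · (u_kᵀ x_j)

where the denominator — the selected feature's own loading — equals the norm
of its deflated column. Only *selected* features are ever read, so the
serialized model (JSON, versioned) prunes loadings and means to the
selected set by default: the minimal measured panel is exactly
selected ∪ normalising features. Replaying the training matrix reproduces
the fit-time linear predictor to ≤1e-10 and single-sample predictions equal
batch predictions to ≤1e-12 (tested).

## Library-size surrogates and normalisation

Library sizes are natural logs of per-sample total counts computed on the
unfiltered matrix. The surrogate model is a gaussian FS-PLS fit of log
library size on log(count + 1), candidates pre-filtered to the most
(0.05-trimmed-mean) expressed features, capped at two surrogates, with the
shipped size chosen by the one-standard-error rule on per-size training MSE
(SE = sd of per-sample squared errors / √m; the 1se threshold uses the SE of
the minimising size, the glmnet convention).

* faux: log counts minus the *predicted* log library size. The method's
  description fixes neither scale nor operation; subtraction in log space
  is the analogue of count-per-total and keeps single-sample capability.
* ratio: column (j, g) = log x_j − log x_g for each feature j and surrogate
  g, giving p·q columns with composite ids "j/g" (q = 2 by default, hence
  n × 2p). Self-ratio columns are kept as constant zeros so the dimension
  statement holds exactly; zero-variance columns never enter selection
  anyway. The construction is invariant to any per-sample scaling by
  design, which is the point.
* ordinary (the baseline arm): log counts minus the *true* log library
  size — the simplest member of the class of library-size normalisations,
  needing the full assay.

The log transform uses natural log with pseudocount 1 (configurable):
ratios are base-invariant and the library-size R² is unaffected by base, so
only the pseudocount is a real choice, and +1 is the count-data default.

## Cross-validated benchmark

`run_benchmark` splits samples once into stratified folds (seeded,
reused across the normalisation and discrimination tasks so held-out
samples are unseen by both models) and per fold: computes candidate pools
from training data only (top-k variance for discrimination, top-k
trimmed-mean expression for normalisation), fits the surrogate model and
the discrimination model on training folds, and scores the held-out fold
sample by sample. Library size is a per-sample quantity, so the test fold's
own totals leak nothing. Binary performance is AUC (Mann–Whitney, ties ½);
multinomial reporting is one-vs-rest AUC per class (macro-averaged),
sensitivity and specificity with argmax ties to the lowest class index, and
the Wasserstein-1 distance between case and control predicted-probability
distributions (larger = more confident separation); continuous outcomes get
MSE and adjusted R² (prediction treated as a single regressor). Fold means
carry 95% t-intervals (4 df at 5 folds); pooled metrics concatenate
held-out predictions. Multinomial training loss is the deviance (−2ℓ);
external selectors (lasso-style or otherwise) can be benchmarked through
the `fit_fn` adapter, which needs only fit/predict/feature-count.

## Synthetic data

The generator draws counts NB(mean = s_i · base_g · exp(effect + latent),
dispersion 0.3 by default), with log-normal size factors s_i (sd 0.5),
log-normal baseline abundances, class effects on a log-fold-change scale,
and optional correlated blocks driven by shared latent factors. Two
structures matter for what the tests can show:

* Housekeeping features scale with the *realized* library total (a fixed,
  large share of the background counts, log-noise sd 0.02, abundance ~30×
  a typical feature). This matters because the realized total of an
  over-dispersed assay is noticeably noisier than the latent size factor —
  the summed noise of abundant features — and a surrogate that only tracked
  the latent factor would be beaten, correctly, by dominant background
  genes. Real surrogate candidates sit at the top of the expression
  distribution for the same reason.
* A "twin block" option adds features correlated with a marker *and*
  carrying its class effect: marginal rankings love such redundant twins,
  deflation suppresses them, which is the behaviour the correlation
  comparisons measure.

The marker effect size 0.6 (log-fold change) used in the recovery runs is
calibrated so a single marker's AUC on normalised log counts is ≈ 0.75
under the default dispersion. Problem sizes in the shipped checks
(300 × 1000 recovery runs, 150–200-sample normalisation runs, 5-fold
benchmarks at 200 × 300) were chosen as the smallest sizes at which the
measured properties are stable across seeds.

What the generator does **not** emulate: cross-platform/batch shifts in
feature location (the known failure mode of mean-centred signatures on
external cohorts), rRNA-depletion-style distortions of the library
composition, zero-inflation beyond NB, and missing values. Passing tests
therefore demonstrate algorithmic correctness and within-distribution
behaviour, not cross-cohort generalisation.

## Numerical choices and degenerate inputs

Centering rejects non-finite entries naming the offending feature; outcomes
with a single realised class (or a weighted-empty class, or near-constant
gaussian y) raise `DegenerateOutcomeError`; zero-variance predictors yield
the null fit (slope 0) rather than failing; `deflate` with an empty
selection is the identity; `select_next` with no viable candidates signals
the degenerate stop, which `fit` records as `stop_reason="loglik_degenerate"`.
Argmax and sort tie-breaks are to the lowest index throughout and are
deterministic; the algorithm has no internal randomness at all — seeds only
enter simulation and fold assignment.

## Known limitations

* The χ² stopping test is asymptotic: at small m it is mildly
  anti-conservative (the pure-noise no-selection rate sits below the
  idealised independent-test calculation), which the calibration check
  accounts for by comparing against enumerated LRT p-values rather than a
  nominal rate.
* With `force_to_max` off and heavy class imbalance, multinomial training
  can stall after one feature; inverse-class weights or forcing to a cap
  are the provided workarounds, with opposite trade-offs.
* No LARS-style acceleration: each multinomial step fits every candidate
  column. Vectorisation keeps binomial/gaussian fast, but very large C with
  large p is slow by design.
* Ordinal outcomes and cross-fold-error stopping are out of scope.
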