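# Methods

`fctransfer` implements transfer learning for whole-brain functional-connectome
classification: a stacked sparse autoencoder (SSAE) prototype is learned
unsupervised on a corpus of healthy connectomes ("offline learning"), then
copied to initialize a small-sample disease classifier that is fine-tuned end
to end. This note records the model, the numerical choices, what the synthetic
cohorts do and do not emulate, and the known limitations.

## Features and harmonization

A subject's connectome is the 90×90 (by default) matrix of Pearson
correlations between region-of-interest BOLD time series; the strict upper
triangle in row-major order gives n(n−1)/2 features (4,005 for 90 regions).
Entries are correlations in [−1, 1] and are fed to the network unscaled by
default (`feature_scaling: none`; a `unit_interval` switch maps [−1,1]→[0,1]).

Multi-site cohorts are harmonized per feature by ordinary least squares on
site (dummy-coded, reference = first site alphabetically), age (numeric,
centered), sex, and handedness (dummy-coded): the corrected value is
`intercept + residual`, followed by a per-site mean adjustment (subtracting
each site's deviation from the grand mean — a no-op whenever site entered the
regression, kept for fidelity to the two-step description and for idempotence).
Missing covariate cells are imputed with the cohort mode (categorical) or mean
(numeric), with logged counts; collinear design columns (e.g. a single-sex
cohort's sex dummy) are dropped with a warning. The correction is fit on the
union of offline and target subjects before any split (`fit_on: all`), the
site-level reading of the procedure; leakage-sensitive users can restrict the
fit to training data. Note that dummy coding centers corrected features at the
reference-site level; only differences between subjects matter downstream.

## Sparse autoencoder

Each AE has one sigmoid hidden layer of width k and reconstructs its input
through a linear decoder (a sigmoid decoder cannot reproduce correlation-valued
inputs; `decoder_activation: sigmoid` restores the symmetric reading). The cost
is

    E = (1/p) Σ_j Σ_i (x̂_ij − x_ij)² + λ·½ Σ W1² + β·Σ_i KL(ρ ‖ ρ′_i)

with p samples, L2 penalty λ on *encoding* weights only (never biases), and a
Bernoulli KL divergence (natural log) pulling each hidden unit's mean
activation ρ′_i toward the sparsity target ρ. Gradients are exact analytic
backpropagation, verified against central finite differences (≤1e−6 relative
error) in the test suite.

Parameters are initialized uniformly, one seeded generator per training call,
drawing W1, b1, W2, b2 in that order. The default half-width is 1/√fan_in
(`init_scale: auto`): with thousands of inputs a unit-range uniform draw
saturates every sigmoid unit (pre-activation sd in the tens) and gradient
descent cannot move the first layer, so the fan-in scale is the package's
default; `init_scale: unit` gives the literal ±1 range. All initial values lie
in [−1, 1] either way.

## Optimizer

All training stages use scaled conjugate gradient (SCG): conjugate directions
with a one-sided finite-difference curvature estimate (σ₀ = 1e−4), an adaptive
Levenberg–Marquardt scale (λ₀ = 1e−6), and step acceptance by the comparison
parameter Δ. One "epoch" is one SCG iteration (accepted or rejected) — the
optimizer is batch, with no minibatches. Training stops at the cost goal
(default 1e−5), when the gradient infinity-norm falls below 1e−8 (prevents
spinning at flat optima), or at `max_epochs`. A fixed-step gradient-descent
fallback (step 0.01) is provided for the constant-learning-rate reading of the
fine-tuning procedure; SCG is the default everywhere. The optimizer is
deterministic: identical inputs give bit-identical traces.

## Stacking, transfer, and the two training paths

An L-layer SSAE is built greedily: AE 1 trains on the input features, AE l on
the hidden activations of the first l−1 encoders; decoders are discarded after
each stage. All stages share one hyperparameter set, with per-stage
initialization seeds derived from the master seed. Offline learning receives a
feature matrix only — it cannot see task labels or target subjects by
construction, and the pipeline additionally refuses offline corpora that
overlap the target cohort by subject id.

The classifier couples the stack to a softmax regression head (explicit
per-class intercepts by default; for two classes this is exactly the logistic
model in (θ₁−θ₂)ᵀz, an equivalence asserted in tests). The head is fit by SCG
on the frozen deep features, then the whole network — every encoder layer plus
the head — is fine-tuned jointly against the two-term binary cross-entropy

    E = −(1/m) Σ_i Σ_j [y_ij ln h_j + (1−y_ij) ln(1−h_j)]

with predicted probabilities h inside the logarithms and no L2/sparsity
penalties (regularization acts only during unsupervised pretraining).
Probabilities are clamped to [1e−12, 1−1e−12] before logs. A tie probability
of exactly 0.5 is assigned to the positive (disease) class.

Two paths share identical architecture and hyperparameters so any performance
difference is attributable to initialization:

* **transfer** — the encoder stack is a copy of the offline prototype;
* **baseline** — the stack is greedily pretrained on the target training
  features only.

Provenance tags (`offline` / `target-pretrained`) are carried by every model
and checked at assembly, so wiring a baseline stack into the transfer path is
an error, not a silent degradation.

## Evaluation and saliency

Stratified k-fold cross-validation (default k = 5; each class's fold counts
differ by at most one) trains on k−1 folds and tests on the held-out fold;
accuracy, sensitivity, specificity (percent) and AUC are computed on the
*concatenation* of the k test folds, never averaged per fold. AUC is the
pairwise-counting probability with ties at ½. Model comparisons across
units use the classical paired t-test (df = n−1, two-sided p).

Saliency of input feature j is the column sum of absolute values of the
chained encoder weight product W⁽ᴸ⁾···W⁽¹⁾ — the exact input-output Jacobian
for a linear network, and an activation-derivative-free approximation
otherwise. The head coefficients are excluded by default (`include_head`
enables them for sensitivity analyses). Per-fold scores are accumulated by
summation across CV folds; ranks are descending with ties broken by ascending
edge index, and reports use 1-based ROI indices.

## Synthetic cohorts

The generator emulates a multi-site resting-state FC study on the Fisher-z
scale, mapped through tanh so features are correlations in (−1, 1):

* healthy structure: per-edge baseline means (N(0.1, 0.2²) z) plus a shared
  10-dimensional latent factor model (loading sd 0.08 z per edge, so the
  structured between-subject sd is ≈0.25 z — the premise that healthy
  connectomes carry reusable low-rank structure, and the thing offline
  learning is supposed to capture);
* disease: an additive shift of `effect_size` (default 0.6 z) on a planted
  set of 10 edges. The planted edges also carry one shared healthy-population
  factor (loading 0.2 z): connections implicated in disease also vary in
  health. This makes the disease-relevant direction statistically visible to
  reconstruction-driven learning at corpus scale (aggregate variance 0.4,
  above the n=400 Marchenko–Pastur noise edge ≈0.17) while remaining invisible
  to target-only pretraining at n≈50 (noise edge ≈1.0) — the sample-size
  asymmetry that transfer exploits;
* unstructured noise: sd 0.1 z per edge, the magnitude of Fisher-z
  measurement error for a typical scan length (≈1/√(T−3));
* confounds: per-site per-edge offsets (sd 0.1 z), small global age/sex/
  handedness effects, and covariate missingness (default 5%);
* namespaces: the offline corpus (default 400 healthy subjects over 4 sites)
  uses disjoint subject ids and site names, so corpus/target disjointness
  holds by construction.

What the generator does **not** emulate: network topology (small-world
structure, module organization), hemodynamics, scanner-specific covariance
structure, heavy-tailed motion artifacts, or diffuse many-edge disease
effects. Passing the synthetic benchmarks therefore demonstrates that the
machinery behaves as designed under the stated statistical assumptions, not
that any particular clinical accuracy is attainable on real data.

## Desk-scale benchmark sizes

The shipped transfer benchmark (`fctransfer.experiments`) uses one target site
with 30 subjects per group (≈24 training subjects per class under stratified
5-fold CV), an offline corpus of 400, architecture 4005-30-30-30-2, λ = 0.001,
β = 1, ρ = 0.1, 150 SCG iterations for the supervised stages and 400 for the
offline phase. The widths keep one repetition near half a minute on a single
CPU; the regularization pair was selected by pilot discrimination performance,
mirroring the per-site empirical hyperparameter selection the methodology
prescribes — the harsher ρ = 0.01 presets pin every top-layer activation at
the sparsity target on this data, handing the classifier a constant
representation. The offline phase gets the longer, published-range epoch
budget because prototype quality is the quantity under study; the supervised
budgets are identical across the two paths so the comparison isolates
initialization.

## Known limitations

* The greedy sparse stack attenuates feature amplitude layer by layer
  (sigmoid units operating near the sparsity target); discriminative signal
  survives but fine-tuning carries most of the classification work.
* The saliency product ignores activation derivatives and the head, exactly
  as defined; it is a linearization, strongest for comparing edges within one
  model.
* Harmonization assumes linear, additive confound effects; scanner-by-disease
  interactions are out of scope.
* The two-term binary cross-entropy doubles the usual single-term value for
  Π = 2 (both class columns contribute); this rescales the objective without
  changing its minimizers.
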