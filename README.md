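# fctransfer

Transfer learning for whole-brain functional-connectome classification.

Small neuroimaging studies — rare disorders especially — rarely have enough
subjects to train deep classifiers on functional connectivity (FC) patterns,
while resting-state fMRI of *healthy* subjects is abundant in public
repositories. `fctransfer` exploits that asymmetry: a stacked sparse
autoencoder (SSAE) prototype learns healthy FC structure from a large corpus
in an unsupervised "offline" phase, and that prototype then initializes a
small-sample disease classifier, which is fine-tuned end to end. The package
is aimed at researchers who have per-subject FC matrices (or ROI time series)
plus a phenotype table and want a reproducible transfer-learning pipeline with
site harmonization, cross-validated evaluation, and feature-level saliency.

## The model

Each sparse autoencoder minimizes

    E(W, b) = (1/p) Σⱼ Σᵢ (x̂ᵢⱼ − xᵢⱼ)² + λ·½ Σ w² + β·Σᵢ KL(ρ ‖ ρ′ᵢ)

where `ρ′ᵢ` is hidden unit i's mean activation over the p subjects and
KL(ρ‖ρ′) = ρ ln(ρ/ρ′) + (1−ρ) ln((1−ρ)/(1−ρ′)) pulls activations toward the
sparsity target ρ. L encoders stacked greedily form the SSAE; a softmax head
h(z)ⱼ ∝ exp(θⱼᵀz) tops the network, and all parameters are fine-tuned jointly
against binary cross-entropy. Every stage is optimized by scaled conjugate
gradient (deterministic, batch, no learning rate). Two training paths share
one configuration:

* **transfer (DTL-NN)** — encoder stack copied from the offline prototype;
* **baseline (DNN)** — encoder stack greedily pretrained on the target
  training data only;

so any performance difference isolates the initialization. Discriminative FC
links are ranked by weight-product saliency |W⁽ᴸ⁾···W⁽¹⁾|, accumulated across
cross-validation folds. Multi-site confounds (site, age, sex, handedness) are
removed per feature by OLS residualization plus site-mean adjustment.

See `docs/methods.md` for assumptions, numerical choices, and limitations.

## Worked example

A complete synthetic round trip on a small 12-ROI cohort (10+10 subjects per
site, two sites, offline corpus of 30, planted 10-edge effect):

```bash
fctransfer simulate --out demo --seed 3 --n-rois 12 --per-group 10 \
    --sites 2 --offline 30 --effect-size 0.8

cat > demo/config.yaml <<EOF
architecture: 66-6-6-2
beta: 1.0
rho: 0.1
lambda_l2: 0.001
max_epochs: 30
k_folds: 4
seed: 5
EOF

fctransfer correct  --features demo/target_features.tsv  --phenotype demo/target_phenotype.tsv  --out demo/target_corrected.tsv
fctransfer correct  --features demo/offline_features.tsv --phenotype demo/offline_phenotype.tsv --out demo/offline_corrected.tsv
fctransfer pretrain --features demo/offline_corrected.tsv --phenotype demo/offline_phenotype.tsv \
    --target-phenotype demo/target_phenotype.tsv --config demo/config.yaml --out demo/prototype.h5
fctransfer evaluate --features demo/target_corrected.tsv --phenotype demo/target_phenotype.tsv \
    --prototype demo/prototype.h5 --config demo/config.yaml --out demo/cv
```

The `evaluate` step prints the pooled 4-fold cross-validation metrics:

```json
{
  "accuracy": 95.0,
  "sensitivity": 95.0,
  "specificity": 95.0,
  "auc": 0.99
}
```

accuracy/sensitivity/specificity are percentages over the concatenated test
folds (sensitivity = detected patients, specificity = detected healthy
subjects); AUC is the probability a random patient outscores a random healthy
subject. `demo/cv/saliency.tsv` ranks all 66 FC links by accumulated saliency:

```
roi_a   roi_b   score               rank
ROI9    ROI12   24.185252494978770  1
ROI3    ROI9    23.358138611370710  2
ROI1    ROI12   23.060279304269738  3
```

The top two links (ROI9–ROI12, ROI3–ROI9) are among the ten planted
discriminative edges recorded in `demo/ground_truth.json` — the ranking
recovers the simulated disease circuit. `demo/cv/predictions.tsv` holds
per-subject fold assignments, truths, predictions and scores, and every
command writes a `run_log_*.json` (seed, config hash, versions, timings) from
which the run can be reproduced bit-identically.

The same subcommands accept real data: delimited n×n FC matrix files or a
feature TSV (first column `subject_id`, then upper-triangle FC columns) plus a
phenotype TSV (`subject_id`, `site`, `group`, `age`, `sex`, `handedness`).
`fctransfer fc` builds the feature table from ROI time-series files. Shipped
presets `UM`, `UCLA`, `USM`, `LEUVEN` (e.g. `--preset USM` =
4005-30-30-30-2, β=2, ρ=0.01, 400 epochs) cover the four benchmark-site
configurations.

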