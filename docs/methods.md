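# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the places where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Outcome definition and labeling

PFS is time from the start of second-line paclitaxel-based chemotherapy to
progression or death; OS is time to death from any cause. Labels are derived
from PFS with two strict thresholds (`t_resistant = 3`, `t_sensitive = 6`
months, both configurable):

| observation | label |
|---|---|
| PFS > 6 (event **or** censored) | sensitive — survival past the threshold is observed either way |
| PFS < 3 with event | resistant |
| PFS < 3 censored | excluded — outcome indeterminate |
| 3 ≤ PFS ≤ 6 (any flag) | excluded |

Boundary values are excluded ("more than"/"less than" read strictly). A
patient censored after the sensitive threshold is provably sensitive, which
is the only labeling of censored observations that never contradicts the
eventual outcome. The positive class is *sensitive* throughout.

The labeled patients are split 80:20 by an outcome-stratified random
partition: validation size is `ceil(n · fraction)`; per-class validation
counts are allocated by largest remainder of `class_count · fraction`, ties
toward the larger class. This preserves the class mix to within one patient
(property-tested exhaustively for n ≤ 12) and sends a 288-patient labeled
cohort to exactly 230 train / 58 validation.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis needs, not any
real dataset.

* **Clinical covariates.** Bernoulli draws with marginals fixed to the
  pooled baseline table of the motivating study population (65.6% male,
  16.7% prior trastuzumab, 64.2% intestinal histology, 25.3% / 36.8% short /
  long first-line duration, 4.5% young-onset, 30.6% age ≥ 70). Age itself is
  piecewise-uniform over 25–39 / 40–69 / 70–91 with the configured band
  masses; only the < 40 indicator enters the models, so the within-band
  shape is inert.
* **Variant panel.** `n_snv + n_cnv` variants (default 73 + 29) assigned
  round-robin to `n_genes` genes (default 87), so the first 15 genes carry
  both an SNV and a CNV, as hot genes do in real panels. Default carrier
  prevalences decay geometrically from 0.40 to 0.01 — the skewed shape of
  real pathogenic-variant frequencies — giving a mean burden of ~11
  variants/patient. Variants are drawn independently per patient.
* **Benefit score.** `score = β₀ + β_clin·x + Σ_{v∈S} β_v + Σ_{(j,k)⊆S} γ_jk`.
  The interaction terms exist so a non-additive signal can be planted that a
  main-effects model cannot represent. An all-zero spec makes outcomes
  independent of all covariates.
* **Survival.** PFS ~ Exponential with median `2.70 · exp(score)` months
  (accelerated-time form: multiplicative on the median, sign-stable). OS is
  PFS plus an independent exponential post-progression time. Because the
  median of a hypoexponential sum is not the sum of the medians, the
  post-progression baseline median is calibrated numerically (Brent root
  find on the hypoexponential survival function) so the marginal OS median
  of a baseline patient equals `13.28` months exactly; `exp(score_os)`
  scales it. Acceptance recomputes both medians on a 10,000-patient null
  cohort (bands [2.4, 3.0] and [12.0, 14.6] months, 3-SE around the
  anchors).
* **Censoring.** A single administrative censoring time C ~ Uniform(0, c_max)
  truncates both endpoints consistently (C before progression censors both;
  C between progression and death censors OS only). `c_max` is solved from
  the target censoring probability of a baseline patient,
  `P(OS > C) = (1 − e^{−λc})/(λc)`. Default censoring rate 0.2.
* **Determinism.** One `numpy` Generator seeded from the config drives every
  draw, and each patient consumes a fixed number of stream values regardless
  of coefficients — so raising a single `β_v` rescales carrier survival
  times patient-by-patient without perturbing anyone else (the basis of the
  monotonicity test).

What the generator does **not** emulate: real per-gene variant frequencies
or co-occurrence, treatment assignment (paclitaxel ± ramucirumab),
laboratory values, performance status, or correlated clinical covariates.
Passing tests therefore demonstrate correctness and calibration of the
machinery and the *relative* behaviour of the model classes under controlled
signals — not clinical performance on real cohorts.

### Canonical planted-signal scenarios

* `interaction_effect_config`: eight signal variants at prevalence 0.5,
  joined in a cycle of eight pairs with alternating interaction coefficients
  ±γ (default 1.5). Each signal variant sits in exactly one positive and one
  negative pair with equal-prevalence partners, so all single-variant
  marginals cancel and a logistic model sees pure noise, while the
  full-score oracle discriminates strongly. All additive terms are zero.
* `additive_effect_config`: ten variants at prevalence 0.5 with alternating
  main effects ±β (default 0.8), no interactions — the matched control where
  a linear model is well specified.

Effect sizes were chosen once so that the oracle (true-score) AUROC is
clearly away from chance at n = 2,000 while labels remain realistically
noisy; they are part of the scenario definition, not tuning knobs.

## The embedding network

Architecture: embedding table `E (V×20)` → per-patient aggregate over the
variant set → concatenation with the 6 binary clinical features → one
20-unit ReLU hidden layer → sigmoid output. Loss is mean binary
cross-entropy; training is Adam (lr 1e-3, β = 0.9/0.999), minibatch 32,
max 500 epochs. Embeddings initialize from N(0, 0.1²), weights He-scaled;
everything is seeded and exactly reproducible. Analytic gradients for all
five parameter blocks are verified against central finite differences to
< 1e-4 relative error. Rows of `E` for variants never seen in training
receive no gradient (and Adam state stays zero), so they remain bit-for-bit
at initialization.

Two design points deserve justification:

* **Aggregation is `sum` by default (`mean` available).** With sum, the
  genetic vector is linear in the binary presence vector, and a ReLU hidden
  layer can represent pairwise co-occurrence (`relu(e_j + e_k − 1)`-style
  detectors). Mean pooling divides by the patient-specific mutation burden,
  which destroys that representation; empirically the mean-pooled network
  memorizes the training set (resubstitution AUROC 1.0) yet stays near
  chance out of sample on the epistatic scenario, while the summed version
  generalizes. The burden-scale dependence that mean pooling would remove is
  handled by the trained weights instead.
* **Early stopping monitors inner-validation AUROC, not loss.** 10% of the
  training data is held out (stratified, seeded); training returns the
  parameters with the best held-out AUROC, stopping after 20 epochs without
  improvement. Held-out cross-entropy starts rising as soon as the network
  grows overconfident — long before its *ranking* stops improving — so a
  loss monitor halts near initialization. With early stopping disabled the
  parameters with the best training loss are returned, which makes "more
  epochs never hurt" a theorem rather than a hope.

Baselines delegate to scikit-learn behind the same contract: RF (500 trees,
unlimited depth), LR (L2, C = 1/λ with λ = 1), MLP (one hidden layer of 20).
All honor the spec seed; all consume the k+V binary design.

## Evaluation

* **AUROC** is computed via midranks, which equals the pair-counting
  statistic `(concordant + 0.5·tied)/(n₊·n₋)`; tests verify equality against
  an O(n²) brute-force oracle on random tied instances.
* **ROC curves** have one point per distinct threshold plus endpoints; the
  trapezoidal area matches the pair-counting AUROC to 1e-12.
* **Bootstrap CIs** are stratified percentile intervals (resampling within
  class, B = 2,000 default) — class counts are fixed, so no resample can
  degenerate. Coverage of the null value 0.5 on label-independent data is
  checked to sit in [93%, 97%] over 500 datasets.
* **Threshold metrics** predict positive at score ≥ 0.5 (configurable); the
  threshold is a reporting choice, not part of the fitted models.

## Survival machinery

Implemented from first principles (lifelines appears only as an independent
oracle in the tests):

* **Kaplan–Meier**: product-limit over distinct event times; at ties,
  events precede censorings (censored subjects count as at risk at their
  censoring time). Without censoring the estimator collapses to
  1 − empirical CDF, checked exactly.
* **Median**: earliest event time with S(t) ≤ 0.5 (a 1e-12 slack absorbs
  floating-point on exact halves); undefined if the curve never reaches 0.5.
* **Log-rank**: hypergeometric moments per distinct event time, statistic
  `(ΣO−E)²/ΣV`, no continuity correction, p from χ²₁. Zero total variance
  returns NaN and is flagged rather than raised, since degenerate predicted
  strata are a legitimate runtime outcome. Type-I error at nominal 0.05 is
  verified to lie in [0.03, 0.07] over 1,000 null simulations (n = 100 per
  group, exponential times, 20% censoring).
* **Predicted-strata comparison** uses the raw times and event flags of the
  chosen endpoint — not the discretized labels — so the survival validation
  is not circular with the classification target definition (a patient can
  be labeled by a censored PFS but still contributes its censored time
  here).

## Pipeline hygiene and determinism

The variant vocabulary is built from training patients only by default
(`vocabulary_policy="train_only"`); validation-only variants are dropped at
featurization, which corresponds to untouched embedding rows / absent
columns. The alternative `"all_patients"` policy (vocabulary over the whole
cohort, as a leaky-but-simpler convention) is supported and recorded in the
report's provenance block. Train and validation index sets are asserted
disjoint before any fit.

One global seed fans out to per-stage seeds via
`SeedSequence([global_seed, stage_offset])` with a fixed offset registry, so
stages are independently reproducible and two runs with the same config
produce byte-identical artifacts (tested file-by-file).

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
complete in well under a minute on a single CPU: signal recovery uses
5 seeds × 2,000 patients, generator calibration 10,000 patients, log-rank
calibration 1,000 simulations of 200 subjects, bootstrap coverage 500
datasets × 2,000 resamples (vectorized over resamples). All sizes are
ordinary function arguments and scale up without code changes.

## Known limitations

* Exponential survival has a constant hazard; real PFS hazards in AGC are
  typically non-monotone. The calibration anchors only pin the medians.
* Variants are independent within patient; linkage between alterations of
  the same gene or pathway is not modeled.
* The censoring process is administrative and outcome-independent —
  informative censoring is out of scope.
* The embedding network's advantage is demonstrated under planted epistasis
  at n = 2,000; nothing here implies a similar margin at a 288-patient
  scale, where variance dominates.
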