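# taxbenefit

Integrated clinical + genomic prediction of **second-line paclitaxel benefit
in advanced gastric cancer (AGC)**, built as a reusable, fully tested Python
pipeline. The package is aimed at biostatisticians and translational
oncology researchers who want to study — on controllable synthetic cohorts —
how much a *learned variant-set embedding* adds over conventional
classifiers when predicting which patients stay progression-free on
second-line taxane chemotherapy.

## The problem and the models

Patients failing first-line fluoropyrimidine/platinum chemotherapy face a
hard decision about second-line paclitaxel: some progress within weeks,
others stay progression-free for many months. The pipeline frames this as a
binary classification problem derived from progression-free survival (PFS):

* **paclitaxel-sensitive** — PFS > 6 months (observed or censored past the
  threshold),
* **paclitaxel-resistant** — observed progression at PFS < 3 months,
* everything in between (or censored too early to tell) is excluded.

Each patient contributes six binary clinical features (young onset < 40 y,
male sex, intestinal histology, prior trastuzumab, first-line duration < 3
months, ≥ 6 months) and a *set* of pathogenic variants
$S_i \subseteq \{1,\dots,V\}$ from an NGS panel (default 73 SNVs + 29 CNVs
across 87 genes). Four classifiers share one fit/predict contract:

* **RF**, **LR**, **ANN** — random forest, L2 logistic regression and a
  single-hidden-layer perceptron on the concatenated binary vector
  $[x^{clin}, x^{var}] \in \{0,1\}^{k+V}$ (scikit-learn back-ends);
* **ANN with GE** — the variant-embedding network, implemented from scratch:
  every variant $v$ owns a learned embedding row $E_v \in \mathbb{R}^{d}$
  ($d = 20$), a patient's genetic representation is the permutation-invariant
  aggregate $g_i = \sum_{v \in S_i} E_v$, and

  $$p_i = \sigma\!\big(w_2^\top \mathrm{relu}(W_1^\top [x_i^{clin}, g_i] + b_1) + b_2\big)$$

  with a 20-unit hidden layer, trained end to end (embeddings included) by
  Adam on binary cross-entropy.

Discrimination is measured by AUROC (Mann–Whitney pair counting, ties
half-credited) with stratified percentile-bootstrap 95% CIs, plus
sensitivity/specificity/accuracy/F1 at a fixed threshold. Validation goes
beyond the discretized labels: predicted-sensitive vs predicted-resistant
strata are compared on the *raw* PFS and OS times with the package's own
Kaplan–Meier estimator and two-group log-rank test.

Because the motivating clinical dataset is not public, the package ships a
first-class **synthetic cohort generator**: exponential PFS plus calibrated
exponential post-progression time (baseline KM medians 2.70 / 13.28 months),
administrative censoring, and a planted benefit score that acts
multiplicatively on the survival medians. The score can be purely additive
in variant presence, or purely *epistatic* (pairwise interaction terms whose
single-variant marginals cancel) — the regime where the embedding network
demonstrably beats logistic regression.

## Worked example

`examples/03_train_and_evaluate.py` plants a purely pairwise variant-
interaction signal in a 2,000-patient cohort and fits all four models:

```
1345 training / 337 validation patients
random_forest        AUROC 0.663 (95% CI 0.601-0.717)  sens 0.027  spec 0.991
logistic_regression  AUROC 0.514 (95% CI 0.456-0.577)  sens 0.106  spec 0.897
ann                  AUROC 0.615 (95% CI 0.551-0.682)  sens 0.416  spec 0.759
ann_with_ge          AUROC 0.597 (95% CI 0.535-0.661)  sens 0.389  spec 0.790
```

Logistic regression sits at chance (0.514): with zero additive effects the
planted signal is invisible to a main-effects model, while the tree ensemble
and both networks recover part of the co-occurrence structure. The other
example scripts cover cohort simulation (`01`), labeling/splitting and
Table-1-style baseline summaries (`02`), survival validation of predicted
strata (`04` — e.g. predicted-sensitive median PFS 10.37 vs 1.23 months,
log-rank P < 10⁻⁴), and the full orchestrated experiment with on-disk
artifacts (`05`).

The same pipeline is scriptable from a shell:

```bash
taxbenefit simulate --config cfg.yaml --out cohort/
taxbenefit train --config cfg.yaml --patients cohort/patients.csv \
    --variants cohort/variants.csv --model ann_ge --seed 1 --out bundle/
taxbenefit run-all --config cfg.yaml --seed 42 --out run/
```

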