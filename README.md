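# voiceicpr

Feature selection and classifier evaluation for dysphonic-voice pattern
analysis, built around the **interclass probability risk (ICPR)** — a
class-overlap statistic computed from Parzen-window density estimates.

## The problem

Sustained-vowel recordings from patients with idiopathic Parkinson's
disease (IPD) differ from healthy-control (CO) recordings in pitch
perturbation (jitter), amplitude perturbation (shimmer), noise ratios and
nonlinear dynamics measures — 22 standard acoustic features per recording.
Many of these features are nearly collinear (pairwise Pearson r > 0.9
within the jitter, shimmer and DFA/PPE blocks), and a screening statistic
is needed to decide which carry discriminative information before any
classifier is trained. This package is for researchers analysing such
two-class voice-feature tables (the UCI "Parkinsons" CSV dialect, 195
recordings, 48 CO / 147 IPD in the original cohort) or simulated cohorts
with the same correlation structure.

## The method

For each feature, the class-conditional densities are estimated by a
Gaussian-kernel Parzen window,

    f̂(x) = (1 / N h) Σᵢ φ((x − xᵢ) / h),     h = 1.06 · SD · N^(−1/5),

and two divergence statistics compare the IPD and CO curves:

* **ICPR** = ∫ min(f̂_IPD(x), f̂_CO(x)) dx — the overlap (class-confusion)
  probability mass. 1 for identical densities, 0 for disjoint ones, and
  2/3 at the "random-guess" level where the overlap equals the total
  non-overlap mass. Features with ICPR < 0.6 are selected.
* **MKLD** = KL(f̂_IPD‖f̂_CO) + KL(f̂_CO‖f̂_IPD) — the symmetric
  Kullback–Leibler divergence. Features with MKLD > 1 are selected.

Before selection, each strongly correlated block (|r| > 0.8) is collapsed
to one scalar via the two-class Fisher discriminant direction
w ∝ S_W⁻¹(μ₊ − μ₋), giving the combined features MDVP-LDA, Shimmer-LDA
and Nonlinear-LDA. Selected features feed three classifiers — logistic
regression (IRLS), an RBF-kernel SVM (σ = 1), and a 50-tree bagged
ensemble — evaluated by stratified 5-fold cross-validation with pooled
confusion matrices, sensitivity/specificity, Matthews correlation
coefficient (MCC), ROC/AUC, the Youden-index cutoff, and Wilcoxon
signed-rank comparisons between classifiers.

## Worked example

Simulate a cohort with the real data's block structure (48 CO / 147 IPD,
three correlated blocks at r = 0.95) in which exactly one feature per
block carries a 3-SD class shift, then select and classify:

```python
from voiceicpr import *
from voiceicpr.data import SyntheticSpec

spec = SyntheticSpec(
    class_shift={"MDVP:Jitter(%)": 3.0, "MDVP:Shimmer": 3.0, "DFA": 3.0},
    seed=5,
)
cohort = generate_synthetic_cohort(spec)
report = rank_and_select(cohort)          # ICPR < 0.6, MKLD > 1
print(report.to_dataframe().head(4).to_string(index=False))
```

```
       feature     icpr      mkld  selected_icpr  selected_mkld
  MDVP:Shimmer 0.133757 11.645900           True           True
           DFA 0.187695 10.135710           True           True
MDVP:Jitter(%) 0.190784 11.852548           True           True
  Shimmer:APQ5 0.875879  0.078284          False          False
```

The three designed features are recovered — their empirical ICPR ≈ 0.13–0.19
brackets the true-density overlap 2Φ(−1.5) ≈ 0.13 of a 3-SD shift — and
every null feature stays far above both thresholds. Cross-validating the
bagged ensemble on the selected features:

```python
plan = build_cv_plan(cohort, n_folds=5, seed=1)
result = k_fold_cv(cohort, plan,
                   ClassifierSpec("bagging", {"n_trees": 50}),
                   report.selected_by_icpr)
print(evaluation_summary(result))
```

```
{'confusion': {'tp': 146, 'fp': 2, 'tn': 46, 'fn': 1},
 'accuracy': 0.9846, 'sensitivity': 0.9932, 'specificity': 0.9583,
 'mcc': 0.9583, 'auc': 0.9996,
 'youden_threshold': 0.6, 'youden_index': 0.9864}
```

i.e. pooled over the five held-out folds the ensemble recovers 146 of the
147 patient recordings (sensitivity 0.9932) and 46 of the 48 controls,
and thresholding its positive-vote fraction at 0.6 maximises Youden's
J = sensitivity + specificity − 1.

The same pipeline is available from the shell:

```sh
voiceicpr simulate --seed 5 --out cohort.csv
voiceicpr select --input cohort.csv --out report.csv
voiceicpr classify --input cohort.csv --model bagging --features auto --seed 1
```

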