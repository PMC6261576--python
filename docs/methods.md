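# Methods

This note documents the models and numerical conventions behind
`arstrat`: what the synthetic cohort generator does and does not
emulate, how each severity labeling and each evaluation statistic is
defined, and the design choices made where more than one reasonable
convention exists.

## Data model

A cohort is a table of patients with 17 physician-rated symptom items on
a 0–4 Likert scale (0 absent … 4 very severe), a patient-reported VAS
stored on the 0–100 scale, and covariates: age (years), sex, rural
residence, disease onset (years before visit), episode duration (days),
five history flags (asthma, conjunctivitis, atopic dermatitis, food
allergy, hives), skin-prick-test and specific-IgE positivity, allergen
immunotherapy, and a 7-level region code. Missing values are NaN in
memory and empty cells (or `NA`) in the CSV interchange format; booleans
serialize as 0/1, sex as `F`/`M`. A *complete case* has no missing value
in a configurable required-field set, defaulting to the 17 items plus
VAS — whether a missing VAS alone should exclude a patient is genuinely
ambiguous, hence the configurability.

## The synthetic cohort generator

The generator produces the statistical structure the downstream
analysis presupposes, from a single-factor ordinal model:

1. each patient draws a latent severity class (mild/moderate/severe)
   with mixing weights (⅓, ⅓, ⅓) and a latent severity
   $z \sim \mathcal N(\mu_c, \sigma^2)$ with class means
   $(-1.2, 0, 1.2)$ and within-class SD $\sigma = 0.35$ (total variance
   ≈ 1);
2. item $j$ has propensity $\lambda_j z + \sqrt{1-\lambda_j^2}\,\epsilon$
   (default loading $\lambda_j = 0.58$ for all items), discretized into
   0–4 by four increasing thresholds; the per-item thresholds are solved
   at configuration time so each item's marginal mean matches a
   realistic seasonal-AR profile (nasal/ocular items frequent — e.g.
   rhinorrhea mean ≈ 2.5 — systemic items like earache rare, ≈ 0.24);
3. VAS couples to the latent severity, *not* to the item sum:
   $\mathrm{VAS} = \mathrm{clip}(50 + 20 z + \eta,\ 0,\ 100)$ with
   $\eta \sim \mathcal N(0, 25^2)$. The deliberately large noise makes
   patient self-assessment agree only loosely with the physician items,
   reproducing the qualitative finding that VAS is the outlier method;
4. binary covariate prevalences are class-specific triples (e.g.
   conjunctivitis history 0.60/0.72/0.83 from mild to severe; sex flat
   at ≈ 52% female), continuous covariates have class-specific means
   (age decreasing, onset increasing with severity), and region is
   drawn once, independent of class — region gradients are not part of
   what the analysis tests;
5. each symptom/VAS cell is independently blanked with probability
   0.0143, chosen so that $(1-r)^{18} \approx 0.772$ — the fraction a
   36,397-patient registry retains when 28,109 complete cases survive.

Everything is deterministic given the seed (missingness uses seed + 1).

**Calibration trade-off.** The loading, class separation and within-SD
were fixed once, at design time, against four goals: Cronbach's alpha
of the 17-item score clearly above the 5-item score, tercile-of-ARPhyS
recovery of the true class above 2/3, kappa(VAS, physician scales) well
below kappa among physician-based methods, and ARPhyS tercile
boundaries near scores 8 and 11. A single-factor model cannot push the
5-item alpha down to ≈ 0.63 while keeping class recovery above 2/3
(lower loadings destroy both alphas and recovery together), so the
defaults favor recovery and land at α₅ ≈ 0.70–0.72 and α₁₇ ≈ 0.88: the
published ordering and qualitative bands ("acceptable" vs "excellent")
are preserved, the exact alpha values are not targets.

**What passing tests do not show.** The generator is
missing-completely-at-random, single-factor, and class-conditionally
Gaussian in the latent; real questionnaire data have informative
missingness, multidimensional symptom structure (nasal vs ocular vs
systemic factors), and rater effects. Results on synthetic cohorts
demonstrate that the pipeline's machinery is correct and that its
qualitative orderings follow from the assumed structure — not that the
published error rates or kappas would be recovered on the real
registry. Two consequences worth naming: k-means labels are nearly
optimally discriminable in the very feature space the discriminators
use (they are constructed there), and the 17-item sum is close to a
sufficient statistic for a single latent factor, so TSS-17 terciles
discriminate at least as well as ARPhyS terciles here, whereas the real
data ranked ARPhyS first overall. The enforced regression direction is
therefore the robust one: physician-score terciles beat VAS terciles,
and VAS is worst everywhere.

## Severity labelings

- **Tercile rule.** Group $= \lfloor 3r/(n+1)\rfloor$ on 1-based ranks
  with ties assigned the lowest rank of their block — the convention of
  the statistical package whose default tie option produced the unequal
  published group sizes. All-identical scores degenerate to everyone
  mild (warning logged). VAS terciles are computed on the raw values,
  unrounded.
- **Clustering.** Both methods run on the 17 standardized items only
  (z-scores with the sample $n-1$ SD) — not VAS, not covariates: the
  comparison is between symptom-profile clusters and symptom-derived
  scales, and mixing the self-assessment into the features would blur
  exactly the contrast being measured. k-means is Lloyd's algorithm
  with 10 seeded restarts keeping the best inertia (via scikit-learn;
  empty clusters are re-seeded from the farthest points). AHC is Ward's
  minimum-variance linkage (scipy); with Ward merge height $h$, the
  merge cost is $h^2/2$, so semipartial $R^2$ decrements and the
  cumulative $R^2$ of the 3-cluster solution are read directly off the
  tree against total sum of squares.
- **Severity ordering.** Clusters are relabeled mild/moderate/severe by
  ascending mean reference score (default TSS-17); mean ties break
  toward the larger cluster, then the lower original index.
- **Repeatability.** "Leave-one-out repeatability" is implemented as
  hold-one-patient-out re-clustering: each of 10 runs drops one random
  patient (k-means also re-seeds), clusters the rest, severity-orders,
  and the mean pairwise label agreement over shared patients is
  reported as a percentage. Agreement is computed after severity
  ordering to avoid label-permutation artifacts. On the shipped
  conditions k-means is highly stable (> 99% at n = 3,000) while Ward is
  more boundary-sensitive (≈ 84–96% depending on n and seed); the
  published 95.6/94.8% figures are not treated as reproduction targets.

## Discriminant evaluation

Features are the same standardized 17-item matrix. Conventions:

- priors equal across the three classes (the analysis software's
  documented default; proportional priors available);
- pooled within-class covariance uses the $n-g$ denominator;
- a ridge $\varepsilon = 10^{-6}\,\mathrm{tr}(\Sigma)/p$ is added
  whenever a covariance is numerically singular (condition number
  > 10⁸) — Likert items are heavily collinear;
- argmax ties resolve toward the more severe class (deterministic and
  clinically conservative);
- the kernel classifiers use a Gaussian kernel whose metric is the
  pooled within-class covariance ("equal bandwidth") or each class's
  own covariance ("unequal bandwidth"), bandwidth default 0.8 with a
  0.4–1.0 sensitivity grid. With one training point per class the
  within-class metric is undefined and the kernel falls back to
  Euclidean.

Leave-one-out CV refits without each observation: the Gaussian
discriminants use exact rank-one downdates of the class mean and
scatter (identical to a literal refit, verified against a brute-force
oracle through the public fit API), and the kernel classifiers exclude
the held-out point's own kernel term while keeping the full-sample
metric — the natural reading of "exclude i from the kernel sums", and
the reason kernel CV error can never beat kernel resubstitution error.
Canonical variance proportions are the eigenvalue shares of the
between-class scatter in the within-class metric (at most $g-1 = 2$
components for three classes).

## Agreement, reliability, cut-offs

Cohen's kappa is unweighted (a linear-weighted option exists for the
ordered three-class case); two identical constant labelings return
κ = 1 by convention ($p_e = 1$). Cronbach's alpha is computed on the
raw 0–4 ratings in covariance form. Cut-off derivation searches all
integer pairs $0 \le c_1 < c_2 < 20$ exhaustively, minimizing plain
misclassification against the tercile labels (an ordinal-weighted
option exists), ties broken toward smaller $c_1$ then $c_2$. Because
terciles of an integer score are themselves a threshold function of the
score, the achieved agreement is exactly 1 and the derived pair equals
the tercile boundaries; on shipped conditions it lands within ±1 of
(8, 11).

## Report tables and group comparisons

The distribution table prints counts, percentages (2 decimals) and
cumulated frequencies per method. Group comparisons across the three
ARPhyS classes use the tie-corrected Kruskal–Wallis test for continuous
and ordinal variables (reporting group means with standard errors of
the mean) and the Pearson χ² test for categorical variables (counts and
percentages); p-values are asymptotic. The retained-vs-excluded
comparison after complete-case filtering uses the two-sample
Mann–Whitney rank-sum test for continuous variables and χ² for
categorical ones.

## Problem sizes and known limitations

The default test suite runs at desk scale (cohorts of 400–10,000;
about 10 s total); the acceptance script uses n = 36,397 for the
complete-case accounting and n = 3,000 for the analysis grid (< 1 min).
The shipped full-scale configuration (n = 28,109) is supported but
slow on the leave-one-out kernel grid and memory-hungry in the Ward
linkage (O(n²)); treat it as an optional long run. Other limitations:
no model-based clustering or silhouette diagnostics, no ROC-based
cut-point selection, no bootstrap intervals, and the generator makes no
attempt to match the real registry beyond the qualitative structure
described above.
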