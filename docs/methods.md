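# Methods

## The AT(N) classification model

The package implements the three-axis biomarker scheme for Alzheimer's
disease: A (β-amyloid deposition), T (pathologic phosphorylated tau) and
N (neurodegeneration), each dichotomized positive/negative from CSF
analytes. The eight resulting profiles collapse into three categories —
*normal* (A−T−(N−)), *AD-continuum* (any A+ profile) and *non-AD
pathologic change* (A− with T+ and/or N+) — and four named subtypes
within the AD-continuum ("AD pathologic change" A+T−(N−), "AD" A+T+,
"AD and non-AD pathologic change" A+T−(N+)).

All three axes are measured in CSF only: A by Aβ1-42 (positive strictly
below 660 pg/ml) or alternatively by the p-tau/Aβ1-42 ratio (positive
strictly above 0.09), T by p-tau (> 61 pg/ml) and N by t-tau
(> 500 pg/ml). Imaging-based N markers (tau-PET, FDG-PET, volumetric
MRI) are out of scope. Values exactly at a cutoff are **negative** on
that axis; the dichotomization rules are strict inequalities throughout,
including the GM-mean SUVR rule (> 1.11 positive, ≤ 1.11 negative).
Subjects with a missing analyte are excluded with a logged reason rather
than imputed — the analysis is complete-case by design.

## Threshold derivation

CSF positivity thresholds are derived against amyloid-PET visual-read
status on a subcohort whose LP-to-PET interval does not exceed 365 days
(configurable; violating subjects are excluded with a log entry).

For each marker (Aβ1-42 with *lower is positive*; p-tau, t-tau and both
tau/Aβ ratios with *higher is positive*):

* **AUC** is the empirical, direction-oriented Mann-Whitney statistic:
  the fraction of (positive, negative) pairs ranked concordantly, ties
  counting 0.5. This is exact, not binormal-smoothed.
* **Confidence interval**: DeLong's placement-value variance with normal
  quantiles, deliberately *not clipped* to [0, 1] (a CI bound above 1 is
  reported as such). Hanley–McNeil variance is available as
  `ci_method="hanley"`.
* **p-value**: two-sided normal approximation of the Mann-Whitney U with
  tie correction, testing AUC ≠ 0.5.
* **Cutoff**: the candidate maximizing the Youden index
  J = sensitivity + specificity − 1, where sensitivity is the CSF
  positivity rate among PET-positives and specificity the negativity
  rate among PET-negatives. Candidates are midpoints between consecutive
  distinct observed values plus ±∞ sentinels, which makes the selection
  invariant to which side tied observations fall on. Ties in J are
  broken by higher sensitivity (favouring case-finding), then by the
  candidate nearer the pooled median (determinism).
* Markers whose AUC p-value is ≥ 0.05 are flagged *insufficient
  accuracy* and their cutoff is withdrawn. The conventional tau cutoffs
  (p-tau > 61, t-tau > 500 pg/ml) are configuration defaults carried by
  `ThresholdSet`, not derived quantities.

## PET quantification

SUV = AC / (dose / BW) with AC the regional activity concentration
(kBq/ml), dose the residual-corrected injected dose (MBq) and BW the
body weight (kg). SUVR divides a region's SUV by the whole-cerebellum
SUV, so dose and weight cancel. The GM mean is the **unweighted**
arithmetic mean of the six grey-matter target regions (anterior
cingulate, frontal, parietal, posterior cingulate, precuneus, temporal);
a scan is positive when GM-mean SUVR is strictly above 1.11. The module
consumes region-level tabulated values only — voxel-level co-registration
and partial-volume correction are out of scope — and can flag
disagreement between the quantitative rule and a visual read
(`SuvrProfile.agrees_with_visual`).

## Cohort statistics

Prevalence tables count subjects per (syndrome × profile) cell, with the
three category columns as sums of their constituent profiles and
within-row percentages rounded to one decimal, **half away from zero**.
An MCI-split variant stratifies amnestic vs non-amnestic MCI.
Chi-square tests use the Pearson statistic without continuity
correction; Mann-Whitney p-values the tie-corrected normal
approximation; Spearman correlations average ranks with the two-sided
t-approximation p-value; α = 0.05 throughout, with no multiple-testing
correction. CSF-PET concordance is (n_pp + n_nn) / n over the four
visual-read × dichotomized-CSF cells, reported together with the
per-cell subject lists; algebraically it equals
(sensitivity·n⁺ + specificity·n⁻) / n for any threshold, a property the
tests verify exactly.

## Synthetic cohorts

No patient-level data are public, so two generators supply test inputs.

**Exact-count fixture** (`generate_fixture`): realises a
(syndrome × profile) count grid — by default the published 628-subject
memory-clinic grid (row totals AD 229, FTD 107, LBD 37, PSP/CBS 12,
PD 5, VaD/mixed 67, other 30, MCI 132, CU 9) — by drawing each analyte
uniformly on the required side of its cutoff, offset by a fractional
`value_margin` (default 0.1, i.e. A+ Aβ1-42 ≤ 0.9 × 660 pg/ml) and
bounded by physiological caps (Aβ1-42 ≤ 2000, t-tau ≤ 2500,
p-tau ≤ 300 pg/ml; floors 100/50/5). Classification of the output is an
exact identity on the grid. Ages (truncated normal) and sexes
(Bernoulli) come from per-syndrome summaries as realistic filler; the
aMCI/naMCI assignment apportions the MCI row 99:33 by largest
remainder. Nothing beyond the grid identity is claimed for these
subjects: their within-cell value distributions are uniform, not
clinical.

**Distributional subcohort** (`generate_distributional`): emulates the
44-subject PET-LP subcohort (aP+ prevalence 37/44). Within each PET
status group, Aβ1-42, t-tau, p-tau and GM-mean SUVR follow truncated
normal marginals (truncated strictly above 0) with the published group
means/SDs (aP+: 542.2 ± 119.2, 700.5 ± 493.3, 83.9 ± 38.5, 1.47 ± 0.21;
aP−: 842.3 ± 341.9, 681.3 ± 593.1, 67 ± 31.8, 0.98 ± 0.10), coupled by
a Gaussian copula so that the marginals stay exact while Aβ1-42 and
SUVR are negatively rank-correlated (default copula correlation −0.4)
and the two tau analytes positively (default 0.7). The recorded visual
read follows the quantitative rule (positive iff SUVR > 1.11), so a
drawn aP− subject in the upper SUVR tail is read positive — mirroring
the perfect visual/quantitative agreement reported for the study
subcohort. Note that the *pooled* Aβ–SUVR correlation reflects both the
copula and the group-mean separation; the copula controls only the
within-group dependence, which is how the zero-coupling independence
property is stated and tested.

What passing tests show — and do not show — about real data: the exact
grid reproduction validates the classification and tabulation
arithmetic, and parameter recovery shows the ROC machinery finds a known
generative boundary; neither says anything about assay variability,
non-normal clinical marker distributions, or the nonlinear CSF-PET
relationship reported in the literature.

## Numerical choices and degenerate inputs

* Ratio fields supplied explicitly must match the analyte quotient to a
  relative tolerance of 1e-9.
* Single-class reference labels raise a "degenerate reference" error;
  all-tied marker values yield J = 0 with a "non-discriminative" flag.
* Contingency tables with an all-zero row or column are rejected;
  Spearman on a constant vector is rejected as undefined.
* Profile labels are ASCII (`A-T+(N-)`) in machine output; Unicode minus
  forms are accepted on input and canonicalised.
* All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give byte-identical CSV output.

## Problem sizes

The default pipeline (628-subject fixture plus a 44-subject PET
subcohort) runs in well under a minute. The reproduction script uses
n = 2000 for threshold derivation and correlation — large enough for
stable parameter recovery at desk scale — and the study-sized n = 44
subcohort for concordance.

## Known limitations

Empirical ROC only (no binormal smoothing); no Aβ42/40 ratio (the study
lacked it); no longitudinal modelling, covariates, or imaging pipeline;
percentages use one printing convention, whereas a few published table
cells appear to follow a different rounding of the same counts.
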