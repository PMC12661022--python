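# Methods

`fairpul` implements a semi-supervised positive-unlabeled (PU) learning
pipeline for identifying undiagnosed disease cases in EHR-style data, with
pre- and post-processing bias mitigation across self-reported race/ethnicity
groups, and a synthetic cohort generator that makes the whole system testable
without access to patient data. The concrete disease setting is Alzheimer's
disease (AD): labeled positives carry a G30 diagnosis code, and phecode 290.11
is the disease phenotype.

## Problem setting and assumptions

Only some true cases are labeled (diagnosed); everyone else is unlabeled — a
mixture of undiagnosed cases and true negatives. The pipeline assumes the
*selected at random* (SAR) labeling mechanism: labeled cases are a biased
sample of all cases, with label propensity increasing in how "case-like" a
patient's features are. Under SAR, a classifier trained on labeled-vs-unlabeled
data yields a *probabilistic gap* ΔPr(x) = Pr(y=1|x) − Pr(y=0|x) = 2p − 1 that
separates confident negatives (very negative gap) from plausible cases.
Because diagnosis rates differ systematically by group (underdiagnosis is
deeper in some groups), both the pseudo-labeling and the decision thresholds
are group-aware.

## Pipeline

**Step 0 — preparation.** Patients are eligible when aged 65–90 at last
visit, with ≥ 5 years of records, ≥ 1 encounter/year on average, and complete
demographics (no imputation; exclusion mirrors the data-integrity argument
that imputation quality would contaminate the fairness evaluation). Diagnosis
codes from the pregnancy (O), perinatal (P), congenital (Q) and external-cause
chapters (V/X/Y, keeping W for falls) are removed, as is F02.80, a concurrent
code of the disease diagnosis itself. Remaining ICD-10-CM codes map to
phecodes at maximum granularity: exact match first, then truncation of
trailing characters until a parent code matches (standard phecode practice;
resolves the one-to-many question by construction since our map is
one-to-one). Only the first encounter per (patient, phecode) is kept;
same-day ties are broken by lexicographic ICD order, which cannot change the
retained event. Patients are labeled LP iff they carry ≥ 1 raw G30 code.
Splits are 80/10/10 train/validation/test, stratified by LP status (floor
allocation for train and validation, remainder to test, so the LP fraction
matches across partitions to within one patient).

**Features.** Binary phecode indicators (never 290.11) plus five continuous
utilization covariates — age at last visit, record length, record density,
encounter count, diagnosis count — min-max scaled with bounds fit on the
training partition only, out-of-range validation/test values clipped to
[0, 1] (the scaling contract is silent on out-of-range values; clipping keeps
the matrix in the unit box). Sex and one-hot group indicators are appended.
Candidate phecodes pass an enrichment screen: per phecode, an unpenalized
logistic regression of LP-vs-U on the phecode plus all scaled covariates, sex
and group indicators (Newton, tol 1e-8, max 100 iterations); keep phecodes
with Wald p < 0.05/K (K = phecodes tested in the split — the published 1,638
is dataset-specific) and prevalence ≥ 1% over all eligible patients ("all
patients", not the training split). Non-convergent fits (separation) are
excluded and logged. The Bonferroni guarantee is verified empirically: on
null data the family-wise selection rate stays at ≤ 0.05 within Monte-Carlo
error.

**Step 1 — reliable negatives (RN).** A linear-logistic classifier separates
LP from U (minority class oversampled to parity by seeded sampling with
replacement). The RN threshold is a robustified minimum LP gap: the mean of
the minima of 1000 subsamples of 500 LP gaps, damping outlier influence; when
fewer than 500 LPs exist the subsample is the whole set (without replacement),
reducing to the plain minimum. RNs are unlabeled patients with gap strictly
below the threshold, age ≥ 70 at last visit, and no phecode in the dementia
exclusion range 290–292.99.

**Step 2 — group-aware pseudo-labeling (AP/AN).** A random forest separates
LP from RN. Per group g, thresholds are the robustified minimum LP gap
(subsample min(500, |LP_g|)) and the maximum RN gap, both from this step-2
classifier. Remaining unlabeled patients with gap above the group's LP
threshold are AP candidates, taken in decreasing gap order (ties resolved by
a seeded random order; the count taken is invariant to the resolution) until
the group's positive prevalence (|LP_g| + |AP_g|)/N_g reaches the population
target π_g — round(π_g·N_g) − |LP_g| patients, never overshooting by more
than one; zero APs when the target is already met. Default targets:
π = 10% (NH-white), 18.6% (NH-AfAm), 14% (HL), 7.4% (EA), the
census-adjusted cohort-study and meta-analysis estimates. Every remaining
unlabeled patient with gap below the group's RN maximum becomes AN (no cap);
the rest are excluded from step-3 training.

**Step 3 — final classifier.** Gradient-boosted trees on LP∪AP (positive) vs
RN∪AN (negative), oversampled minority. This is the scorer for validation and
test. The vanilla two-step PU comparator stops after step 2 and scores with
the step-2 classifier (bit-identical to the pipeline's for the same seed);
supervised baselines treat all unlabeled patients as noisy negatives, either
on the full selected feature set or on demographics plus a curated
risk-factor phecode list (249, 250.2, 250.22, 250.24, 250.25, 272.1, 401,
401.1).

**Step 4 — group benefit equality (GBE) cutoffs.** For each group, GBE is
operationalized as (|LP| + predicted positives among unlabeled) / (|LP| +
proxy-validated positives) — labeled positives anchor both sides; the pure
unlabeled-only ratio is available behind a flag. On validation, the cutoff
minimizing |GBE − 1| is found by Nelder–Mead from 0.5 followed by exhaustive
refinement over all observed probabilities plus {0, 1}: GBE is a
right-continuous step function of the cutoff, so the refinement provably
attains the global optimum that a simplex search can miss on plateaus. Ties
resolve to the largest (most conservative) cutoff. The decision rule is
prob ≥ cutoff; LPs are never re-thresholded. Groups with undefined GBE (no
observed or proxy positives) fall back to the global MCC cutoff. The MCC
comparator maximizes the Matthews correlation coefficient against proxy
labels over midpoints between consecutive sorted unique probabilities plus
{0, 1}, ties to the smallest cutoff.

## Validation and metrics

Unlabeled patients are validated against silver-standard proxies computed
from the *raw* (pre-filtering) diagnosis and medication tables: dementia-
spectrum ICD codes (F01*, F02*, F03*, G31.0/.01/.09/.1/.83/.84/.85,
R41.1–R41.3) with descendant-aware prefix matching, and disease-specific
medications (donepezil, rivastigmine, galantamine, memantine,
memantine/donepezil, aducanumab, lecanemab) matched case-insensitively
including combination formulations. Patients without any proxy are controls.

Metrics per group and overall: sensitivity, specificity, precision (reported
as missing — never 0 — when there are no predicted positives), balanced
accuracy, rank-based AUC with tie correction, step-integrated AUCPR,
class-stratified Brier scores Brier⁺ = Σ_{y=1}(y−ŷ)²/N₊ and
Brier⁻ = Σ_{y=0}(y−ŷ)²/N₋ with balanced Brier = Brier⁺ + Brier⁻ ∈ [0, 2],
and ECE over 10 equal-width bins (the equal-width reading of the binning
description; empty bins contribute 0). Fairness: signed differences
M_unprivileged − M_privileged for M ∈ {specificity, precision, balanced
accuracy, sensitivity (the equal-opportunity gap), GBE}; per-metric parity
loss Σ_g |M_difference|; cumulative parity loss as their sum. Missing
differences are excluded with a warning and flagged rather than zero-filled.

## Robustness procedures

*Group recoding*: rewrite the group indicators of each group's test patients
to every other group, re-score with the final classifier, apply the original
group's cutoff, and report the sensitivity change; a group-blind model shows
exactly zero change. *Proxy shift*: re-validate, re-optimize GBE cutoffs and
re-evaluate under reduced proxy definitions (each ICD dropped in turn, each
mapped-phecode group dropped, 5 random ICDs dropped, all medications
dropped); validated-positive sets under any subset are contained in the full
set. *Attribution tests*: for a per-patient signed feature-attribution table
(source pluggable; any tree-model attribution routine can populate it), a
permutation test on the absolute between-group difference of Pearson
correlations between feature value and attribution (labels shuffled only
between the two compared groups, 1000 permutations; the p-value is the plain
proportion of null statistics ≥ observed, which can be exactly 0 — an
add-one-corrected p is emitted alongside), and a two-sided Mann–Whitney U
test on absolute attribution magnitudes with caller-applied Bonferroni.

## Synthetic cohort generator

Defaults encode the target study conditions: four groups (NH-white 66%,
NH-AfAm 8%, HL 16%, EA 10%), true prevalences 10/18.6/14/7.4%, and labeling
sensitivities 0.430/0.312/0.307/0.527 chosen so labeled prevalence lands at
the underdiagnosed EHR rates 4.3/5.8/4.3/3.9%. Label propensity is
sensitivity_g · 2σ(w·z) clipped to [0, 1], where z is the z-score of the
patient's informative-feature burden among true cases and w (default 1)
controls the SAR bias; w = 0 recovers selection completely at random, and
for symmetric burden distributions the expected labeled prevalence equals
prevalence × sensitivity exactly. Binary diagnosis features are
class-conditional Bernoulli draws: neurological codes near-absent in controls
(e.g. memory loss 35% vs 1%), risk factors mildly enriched, background codes
uninformative, plus codes that exercise the record filters and the unmapped
path. Utilization covariates are offset-gamma (record length, density) and
Poisson (diagnosis count) with additive case shifts; ages are uniform on
[65, 90] so everyone passes eligibility unless an ineligible fraction is
injected deliberately. Unlabeled true cases carry ≥ 1 proxy ICD or medication
with probability 0.85. Every event gets one synthetic encounter date uniform
over the record span. All randomness flows from a single seed.

What the generator does *not* emulate: longitudinal disease progression,
realistic ICD co-occurrence structure, code-frequency heterogeneity within a
phenotype, or genetic data. Passing tests therefore demonstrate the
correctness and calibration of the machinery under SAR-style label bias, not
clinical performance on real EHR data.

A second configuration (`surplus_candidate_config`) keeps the labeled
prevalences at the EHR rates but deepens the latent prevalence
(13/24/18/11%). Under the defaults the number of latent unlabeled cases per
group equals the prevalence gap exactly, so the prevalence-matched
pseudo-labeling has zero slack for classifier error; the surplus conditions
are used when the analysis requires the target to be attainable with
certainty (the prevalence-matching checks).

## Numerical choices and problem sizes

Stage classifiers are fixed, documented defaults rather than an automated
model search: logistic regression (lbfgs, C = 1), random forest (100 trees,
depth ≤ 12, min leaf 5, √p features), gradient-boosted trees (150 rounds,
depth 4, learning rate 0.1, hist method), all single-threaded and seeded; all
stage seeds derive from one master seed through a fixed spawn order, so every
run is replayable. Oversampling duplicates the minority class to exact
parity. The repeated-splits analyses use 20,000-patient cohorts and 50
splits (≈ 1.7 s/split end to end including the enrichment screen); the null
calibration of the feature screen uses 250 replicates of 40 phecodes at
n = 400. These sizes give Monte-Carlo error comfortably inside the
tolerances they are checked against.

Observed behavior under the default conditions (recomputed by the test suite
and acceptance script, not asserted as constants): mean per-group test-set
GBE within ±0.05 of 1 over 50 splits; pseudo-label (LP+AP)/N within one
patient of round(π_g·N_g) under surplus conditions; RN/AN false-omission
rate an order of magnitude below the noisy-negative rate; and higher overall
test sensitivity for the pipeline with GBE cutoffs than for the supervised
full baseline with the MCC cutoff.

## Known limitations

GBE cutoffs for small groups sit on a coarse step function (denominators of
a few dozen on a 2,000-patient validation partition), so single-split
test-set GBE is noisy (sd ≈ 0.1–0.2) even though the mean over splits is
well inside ±0.05. The proxy definition is treated as ground truth for
evaluation; proxy false positives inflate the estimated class prior, which
is exactly the sensitivity probed by the proxy-shift analysis. The enrichment
screen drops separated phecodes instead of falling back to a penalized fit.
The synthetic generator's independence assumptions make the classification
problem easier than real EHR data; directional comparisons between models
are meaningful, absolute metric levels are not.
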