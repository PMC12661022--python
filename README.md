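# fairpul

Fairness-aware semi-supervised positive-unlabeled learning for EHR
phenotyping.

## The problem

Diseases like Alzheimer's are heavily underdiagnosed in routine care, and
unevenly so: population studies put prevalence over age 65 at roughly 10%
for non-Hispanic white, 18.6% for non-Hispanic African American, 14% for
Hispanic/Latino and 7.4% for East Asian patients, while diagnosis-code rates
in health-system records sit around 4–6% for every group. A classifier
trained to find undiagnosed cases from such records faces two coupled
problems: the negatives are not negatives (they are a mix of true controls
and missed cases — a *positive-unlabeled* problem), and the missingness is
group-biased, so a naive model inherits the diagnostic disparity.

`fairpul` is for biostatisticians and clinical-informatics researchers who
want to phenotype under-diagnosed conditions from positive-unlabeled EHR
tables while controlling group fairness, and to test such pipelines without
any access to patient data: the package ships a seeded synthetic cohort
generator that reproduces the statistical structure of the problem
(group-specific prevalence, biased labeling, proxy codes).

## The method

For a scorer p(x) define the probabilistic gap ΔPr(x) = Pr(y=1|x) −
Pr(y=0|x) = 2p(x) − 1. The pipeline runs in four steps on each
train/validation/test split:

1. **Reliable negatives.** Logistic regression on labeled-positive (LP) vs
   unlabeled (U); unlabeled patients become reliable negatives (RN) when
   their gap falls below a robustified minimum LP gap (mean of minima over
   1000 subsamples of 500 LP gaps), they are ≥ 70 at last visit, and they
   carry no phecode in the dementia range 290–292.99.
2. **Group-aware pseudo-labels.** A random forest on LP vs RN re-scores
   everyone. Per group g, unlabeled patients with gaps above the group's
   robustified minimum LP gap become additional positives (AP), taken
   largest-gap first until (|LP_g|+|AP_g|)/N_g reaches the population
   prevalence π_g; those below the group's maximum RN gap become additional
   negatives (AN).
3. **Final classifier.** Gradient-boosted trees on LP∪AP vs RN∪AN.
4. **Group benefit equality (GBE) cutoffs.** Per group, the classification
   cutoff minimizes |GBE − 1| on the validation set, where
   GBE = P(Ŷ=1|A=g) / P(Y=1|A=g) is estimated as
   (|LP| + predicted positives) / (|LP| + proxy-validated positives), via
   Nelder–Mead plus exhaustive refinement over the observed probabilities.

Evaluation validates unlabeled patients against silver-standard proxies
(alternative dementia ICD codes, disease-specific medications) and reports
discrimination (AUC, AUCPR, sensitivity, specificity, precision, balanced
accuracy), calibration (balanced Brier = Brier⁺ + Brier⁻, ECE), and fairness
(per-metric parity losses and their cumulative sum over specificity,
precision, balanced accuracy, equal opportunity and GBE). Supervised
noisy-negative baselines, the vanilla two-step PU learner, an MCC-maximizing
cutoff comparator, and three robustness analyses (group recoding, proxy
shifts, attribution permutation tests) are included. See
[docs/methods.md](docs/methods.md) for the full model account.

## Worked example

```python
import fairpul as fp

config = fp.default_sim_config(n_patients=20_000, seed=7)
tables = fp.generate_cohort(config)                     # synthetic EHR tables
prepared = fp.prepare_cohort(tables, fp.default_phecode_map())
result = fp.run_split(prepared, seed=1)                 # one 80/10/10 split

print("cutoffs:", {g: round(c, 3) for g, c in result.cutoffs.cutoffs.items()})
print("training composition:", result.pipeline.composition["overall"])
cols = ["group", "n", "sensitivity", "precision", "balanced_accuracy",
        "auc", "aucpr", "balanced_brier", "gbe"]
print(result.test_report[cols].round(3).to_string(index=False))
print("RN/AN false omission rate:",
      round(fp.false_omission_rate(result.pipeline.labels, tables.truth), 4))
```

prints

```
cutoffs: {'EA': 0.999, 'HL': 0.968, 'NH-AfAm': 0.998, 'NH-white': 0.998}
training composition: {'RN': 7751, 'excluded': 3600, 'AN': 2874, 'AP': 1075, 'LP': 700}
   group    n  sensitivity  precision  balanced_accuracy   auc  aucpr  balanced_brier   gbe
      EA  209        0.643      0.900              0.819 0.963  0.788           0.173 0.833
      HL  312        0.828      0.533              0.877 0.971  0.800           0.134 1.372
 NH-AfAm  160        0.846      0.688              0.906 0.981  0.880           0.131 1.130
NH-white 1232        0.648      0.655              0.811 0.929  0.717           0.241 0.993
 overall 1913        0.701      0.639              0.835 0.946  0.750           0.203   NaN
RN/AN false omission rate: 0.0033
```

Reading this: of the 16,000 training patients, 700 were labeled positives
and the pipeline pseudo-labeled 1,075 additional positives — lifting the
positive-label prevalence to each group's population target — plus 7,751
reliable and 2,874 additional negatives, of which only 0.33% are actually
cases by the generator's ground truth (a supervised model calling every
unlabeled patient negative would carry ~7% false negatives). Single-split
test GBE per group is noisy (small denominators); its mean over repeated
splits is what the cutoff optimization controls, and
`fp.evaluate_over_splits(prepared, n_splits=50, master_seed=7)` shows it
landing within ±0.02 of the ideal value 1 for every group.

The same stages are scriptable from the shell:

```bash
fairpul simulate --out cohort/ --n-patients 20000 --seed 7
fairpul prepare  --in cohort/ --map cohort/phecode_map.tsv --seed 1 --out prep/
fairpul run      --in cohort/ --map cohort/phecode_map.tsv --seed 1 --out run/
```

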