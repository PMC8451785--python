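# cllburden

Tumor mutational burden (TMB) and reduced gene-panel analysis of
treatment-free survival (TFS) in chronic lymphocytic leukemia (CLL).

Targeted resequencing of a large gene panel yields, per patient, a count
of retained pathogenic somatic mutations — the TMB — which is prognostic
for how soon an untreated CLL patient will need therapy. Sequencing many
genes is expensive, so a natural question is whether a *small* subset of
genes carries the same prognostic information. This package implements
that workflow end to end for biostatisticians and hematology labs:

1. **Variant retention** — raw annotated calls are reduced to plausibly
   pathogenic, acquired, exonic mutations by a fixed rule cascade
   (depth ≥ 100×, ≥ 5 alternate reads, VAF ≥ 2%, population MAF < 0.01,
   hotspot membership or SIFT/CADD evidence), with a complete per-record
   audit trail and an explicit manual-review policy.
2. **Burden** — TMB as the per-patient count of retained mutations,
   dichotomised at ≥ 2 mutations, plus the *eight-gene estimator*: the
   indicator of ≥ 1 retained mutation in
   {ATM, SF3B1, NOTCH1, BIRC3, XPO1, MYD88, TNFAIP3, TP53}.
3. **Informativeness** — Harrell's concordance index *c* of a binary
   marker x against right-censored TFS, implemented from first
   principles with exact pair accounting. A pair (i, j) is usable when
   its time ordering is determinable under censoring; it is concordant
   when x_i < x_j and T_i < T_j; marker ties count ½. With deleterious
   coding (x = 1 for mutated), c < 0.5 means shorter TFS, and the
   farther from 0.5 the more informative the marker.
4. **Panel derivation** — exhaustive (or greedy, for large candidate
   sets) search for the gene subset whose ≥ 1-mutation indicator
   *minimises* c.
5. **Survival modelling** — Kaplan-Meier, logrank, Cox proportional
   hazards (Efron ties), and the multivariate protocol: univariate
   screen at p < 0.20, backward stepwise elimination by likelihood-ratio
   test, and bootstrap refitting to measure per-covariate selection
   stability.
6. **Synthetic cohorts** — a generator that emulates the statistical
   structure of a two-centre CLL study (series of 80 + 70 patients,
   ~52% IGHV-mutated, ATM/SF3B1/NOTCH1/BIRC3 atop the mutation spectrum,
   per-gene hazard ratios, IGHV-coupled mutation odds, independent
   administrative censoring), so the entire chain is testable without
   patient data.

## Worked example

```python
import pandas as pd
import cllburden as cb
from cllburden.cohort import clinical_to_frame

spec = cb.default_spec(seed=1)                      # 150-patient synthetic cohort
records, truth = cb.generate_cohort(spec)
calls = cb.generate_variant_calls(truth, spec, noise_seed=2)

matrix, decisions = cb.run_filter_pipeline(
    calls, patients=truth.patients, genes=truth.genes)
# 297 raw records -> 291 retained (6 injected noise records each fail one rule)

clin = clinical_to_frame(records)
u = clin[~clin.previously_treated].reset_index(drop=True)
surv = cb.SurvivalData.from_frame(u)
sub = cb.MutationMatrix(matrix.counts.loc[u.patient_id])

res = cb.harrell_c_index(cb.estimator_status(sub).to_numpy(int), surv)
stat, p = cb.logrank_test(cb.estimator_status(sub).to_numpy(bool), surv)
print(res.c, res.n_usable)        # 0.333  6426
print(stat, p)                    # 41.96  9.3e-11

sel = cb.PanelSelector(max_size=3, mode="exhaustive").fit(sub, surv)
print(sel.best_panel_, sel.best_c_)
# ('BIRC3', 'NOTCH1', 'SF3B1')  0.334

X = pd.DataFrame({
    "estimator": cb.estimator_status(sub).to_numpy(int),
    "ighv_unmutated": (u.ighv_status == "unmutated").astype(int).to_numpy(),
    "trisomy12": (u.cytogenetic_class == "trisomy12").astype(int).to_numpy(),
    "del11q": (u.cytogenetic_class == "del11q").astype(int).to_numpy(),
})
model = cb.StepwiseCoxPH(n_bootstrap=200, random_state=1).fit(X, surv)
print(model.selected_)                          # ('estimator',)
print(model.result_.summary.loc["estimator", ["hr", "ci_low", "ci_high"]])
# hr 3.938, 95% CI [2.534, 6.120]
print(model.selection_frequencies_["estimator"])  # 1.0
```

Reading the output: among the 111 untreated patients, carrying any
mutation in the eight-gene estimator has c = 0.333 — far below 0.5, a
strongly deleterious marker — and the mutated group's survival curve
separates from the unmutated group at logrank p ≈ 1e-10. The
c-minimising three-gene subset on this cohort is SF3B1+NOTCH1+BIRC3
(c = 0.334), and after screening and backward elimination the estimator
is the only independent covariate (HR ≈ 3.9), selected in 100% of
bootstrap refits.

The same chain is available from the shell:

```sh
cllburden simulate --seed 1 --out sim/
cllburden filter sim/variants.tsv --out filt/
cllburden tmb filt/matrix.csv --clinical sim/clinical.csv --out tmb.csv
cllburden select-panel filt/matrix.csv sim/clinical.csv --mode greedy --out panel.csv
cllburden run-all --seed 1 --out study/          # full report directory
```

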