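# Methods

## The analysis in one paragraph

Per patient, targeted resequencing calls are filtered down to retained
pathogenic somatic mutations; their count is the tumor mutational
burden (TMB). The endpoint is treatment-free survival (TFS): time from
diagnosis to first treatment, right-censored for patients never
treated. Each binary marker (a mutated gene, a gene-set indicator,
TMB ≥ 2, IGHV status, a cytogenetic class) is scored by Harrell's
concordance index against TFS, and the reduced panel is the gene subset
whose ≥ 1-mutation indicator minimises the index. Survival contrasts
use Kaplan-Meier/logrank; independence of markers is assessed by a Cox
model built with a fixed protocol (univariate screen, backward
likelihood-ratio elimination, bootstrap stability).

## Concordance index

For patients i, j with times T_i, T_j, events e_i, e_j and marker
values x_i, x_j ∈ {0, 1}:

* a pair with distinct times is **usable** iff the shorter time ends in
  an event; a pair with tied times is usable iff exactly one is an
  event (the event is taken to precede the censored follow-up); tied
  times with two events, and pairs whose shorter time is censored, are
  unusable. This matches the classical Harrell accounting.
* a usable pair is **concordant** iff the patient failing first has the
  smaller marker value (x_i < x_j and T_i < T_j), **discordant** if the
  larger, and **tied** if x_i = x_j; ties are credited 0.5. The half
  credit is required so that a constant marker scores exactly 0.5
  (uninformative) rather than being undefined.
* c = (concordant + 0.5 · tied) / usable. Under deleterious coding
  (x = 1 for mutation present) c < 0.5 indicates shorter TFS.

Degenerate inputs: no usable pair raises an explicit error; a constant
marker returns 0.5 with a warning. The implementation is vectorised
over the pair matrix; the test suite checks it for exact equality
(value *and* all four pair counts) against a brute-force enumeration
oracle on ~1000 random censored datasets with injected ties.

## Variant retention

Rule order: exonic gate → quality (depth ≥ 100×, ≥ 5 alternate reads,
VAF ≥ 2%, all inclusive) → population frequency (MAF ≥ 0.01 rejected
as polymorphism, inclusive; any database entry with MAF < 0.01 or no
MAF goes to manual review) → pathogenicity (hotspots retained
unconditionally; otherwise deleterious SIFT or CADD PHRED ≥ cutoff
retains; both scores missing goes to manual review; tolerated calls
below the CADD cutoff are rejected). The rules are conjunctive, so
verdicts are order-independent per record; the order only affects which
rules appear in the audit trace of multiply-failing records.

Numerical/policy choices:

* **CADD cutoff** defaults to PHRED 20, the common pathogenicity
  convention; it is configurable because no single value is canonical.
* **Manual review** cannot be automated; the policy enum is
  {exclude (default), include, defer-to-file}, and all review records
  are persisted in the audit table either way.
* **VAF** is recomputed as alt_reads/depth when absent; a stated VAF
  disagreeing with the recomputed one by more than 0.005 sends the
  record to manual review rather than trusting either number.
* **Hotspot lists** are an input (gene/locus/allele), not a baked-in
  database: hotspot catalogues are version-dependent.
* Duplicate (patient, chrom, pos, ref, alt) records are collapsed to
  the first occurrence with a warning.

TMB counts retained *variants* by default (two distinct retained
variants in one gene count twice); a genes-hit mode is provided since
either reading of "accumulated mutations" is defensible.

## Panel search

The objective is minimise c (deleterious coding), not |c − 0.5|;
protective markers (c > 0.5) are reported in the per-marker table but
are not search targets. Exhaustive search evaluates every subset of
sizes 1..max_size under an explicit evaluation budget; ties in c within
1e-12 are broken by smaller subset, then lexicographic gene names, so
results are deterministic and independent of candidate ordering. Greedy
forward selection (default above 20 candidates) starts from the best
single gene and adds the gene with the largest c decrease, stopping
when no addition decreases c; its trace is strictly decreasing by
construction. Exhaustive search is the ground truth; tests verify it
against an independent subset-by-subset re-evaluation and check greedy
agreement rates on planted fixtures.

## Cox protocol

Fits use the partial likelihood with the Efron tie approximation.
The multivariate protocol: (1) univariate Wald screen at p < 0.20;
(2) joint model on the survivors, with exactly collinear columns
reduced to the one with the larger univariate |z|; (3) backward
elimination removing, one per iteration, the covariate whose
likelihood-ratio removal p is largest, until all removal p-values are
below the stay threshold (0.05 — the protocol's screening constant is
given, the stay threshold is our choice of the conventional level);
(4) bootstrap: the whole screen-plus-elimination procedure is refit on
patient resamples (unstratified, with replacement) and the fraction of
resamples in which each candidate lands in the final model is its
selection frequency. If nothing passes the screen the result is an
empty model, not an error.

The reported final model comes from lifelines; the screening,
elimination and bootstrap inner loop uses a lean Newton-Raphson
partial-likelihood fitter written for this package (same Efron
convention), which the tests pin to lifelines' coefficients, standard
errors and log-likelihood to ~1e-6 on tied and untied data.

## Synthetic cohort generator

What it emulates: two series (80 + 70 patients); ~23% previously
treated; ~52% IGHV-mutated; a 20-gene panel with ATM, SF3B1, NOTCH1 and
BIRC3 the most frequently mutated; median TMB ≈ 2 (calibrated to land
in 1.5-2.0 averaged over seeds); median TFS ≈ 4.4 years for
IGHV-mutated vs ≈ 1.7 years for unmutated patients; shorter TFS for
TMB-high patients.

Model: per-gene mutation indicators are Bernoulli. `mutation_freq[g]`
is the *marginal* probability of carrying ≥ 1 mutation in g among
untreated patients; it is split into IGHV-conditional probabilities
such that odds(unmutated IGHV) = enrichment × odds(mutated IGHV)
(default enrichment 4) while preserving the marginal — so observed
per-gene rates recover `mutation_freq` regardless of the coupling.
Previously treated patients get a burden odds multiplier (default 2)
to emulate their higher TMB; they carry no TFS (NaN) and are excluded
from survival analyses. Per-cell counts are 1 + Poisson(0.12) extra
variants given a mutation, leaving the binary rate untouched. TFS is
exponential (Weibull optional) with hazard h_i = h0 · Π_g HR_g^{x_ig},
h0 = ln 2 / baseline median (default 7 years, chosen so the
IGHV-stratified medians land in the ranges above given the default
frequencies and hazard ratios). Censoring is administrative:
C ~ Uniform(0, w), with w solved numerically so the expected censored
fraction at the baseline hazard equals `censoring_rate` (default 0.25).
Default per-gene hazard ratios concentrate the prognostic signal in the
eight estimator genes (2.5-3.2 for ATM/SF3B1/NOTCH1/BIRC3, smaller for
the rest, 1.0 for non-estimator genes).

Default gene frequencies and hazard ratios were fixed once by a
Monte-Carlo calibration run against the summary targets above and then
frozen; they are deliberately config-overridable because per-gene
frequencies vary across real cohorts.

What it does *not* emulate — and what passing tests therefore do not
show about real data: read-level sequencing noise, clonal evolution,
correlation between cytogenetic class and mutation burden (cytogenetic
classes are drawn independently), between-centre batch effects, and
non-proportional hazards. The generator exists to verify the analysis
machinery (filtering, counting, ranking, model building), not to be a
disease model.

`generate_variant_calls` expands a mutation matrix into raw calls that
pass every retention rule, plus configurable noise records each failing
exactly one rule (low depth, few alt reads, low VAF, common
polymorphism, tolerated non-hotspot, unannotated non-hotspot), at
coordinates disjoint from the clean calls — which is what makes the
exact filter round trip a meaningful invariant.

## Statistical conventions

* Logrank: unstratified two-group form; stratified reports are loops
  over subgroups.
* Contingency tables: chi-square without continuity correction;
  Fisher's exact test replaces it for 2×2 tables with any expected
  count below 5.
* Mann-Whitney: exact null for tie-free samples with both n ≤ 20;
  otherwise the normal approximation with tie-corrected variance and
  no continuity correction.
* Kaplan-Meier median: first time at which S(t) ≤ 0.5, undefined (NaN)
  when never reached.
* Short/long TFS dichotomy at 2 years: short = event before the cut,
  long = follow-up reaching the cut; patients censored before the cut
  are indeterminate and excluded (their count is logged).
* "TFS > 6 months" subset: any patient, event or censored, whose
  recorded time exceeds 0.5 years — either way they are known to have
  been untreated for at least 6 months.

## Problem sizes used in tests and the acceptance script

Oracle equivalence uses ~1000 datasets of n ≤ 50; null calibration
1000 cohorts of n = 100; type-I error 2000 simulations per test; Cox
recovery n = 5000 and coverage over 500 cohorts of n = 200; the round
trip 100 seeds of a 40-patient, 4-gene cohort (the property is
size-independent); planted-panel recovery 50 seeds of a 300-patient,
5-gene cohort; direction checks 50 default cohorts and a 300-500
resample bootstrap. These sizes give Monte-Carlo error comfortably
inside each check's tolerance.

## Known limitations

* The concordance-index censoring conventions at tied times follow the
  classical accounting; other implementations differ on corner cases
  (tied times with two events, for example), so cross-library
  comparisons should fix the convention first.
* Backward stepwise selection inherits the usual instability of
  stepwise procedures; the bootstrap selection frequency is reported
  precisely because the selected set alone is fragile.
* No multiple-testing correction is applied over gene subsets in the
  panel search: the c-ranking is exploratory, and the logrank p-values
  in the ranked table are descriptive.
* Manual-review variants default to exclusion; on real data this is a
  conservative choice and the audit trail exists so a reviewer can
  overturn it.
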