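# Methods

## Scope and data model

The package analyses one-row-per-patient cohorts of children with suspected
appendicitis. A record carries demographics (age, sex), symptoms (anorexia,
nausea/vomiting, diarrhea, pain migration, pain duration), physical findings
(RLQ tenderness, cough/percussion/hopping tenderness, psoas, obturator,
Rovsing, heel drop), labs (WBC /µL, neutrophil %, CRP mg/dL, temperature ℃)
and a three-class outcome: `none`, `uncomplicated`, `complicated`
(complicated = perforation, periappendicular abscess or peritonitis on
imaging). "Diseased" means outcome ≠ none.

Binary lab features are inclusive threshold comparisons, configurable via
YAML but defaulting to the derivation study's definitions: leukocytosis
WBC ≥ 10,000/µL, shift-to-left neutrophils ≥ 75%, CRP ≥ 1 mg/dL (the CHANSE
component) and ≥ 5 mg/dL (the univariate cut), fever ≥ 38.0 ℃. CRP is fixed
in mg/dL; no unit conversion layer exists.

Missing data are handled by complete-case analysis **per variable**: a
record missing a field is excluded only from computations needing that
field, and every output row reports the n it used. A record missing any
component of a score has that score missing. The derivation study never
mentions missingness; complete-case is this package's choice, made because
it is transparent and keeps every published quantity a pure function of
counts.

## Scores

CHANSE = number of true components among {CRP ≥ 1 mg/dL, heel drop,
anorexia, nausea/vomiting, shift-to-left, leukocytosis}; range 0–6, default
high-risk cutoff ≥ 3. PAS uses the original Samuel weighting (tenderness
items 2 points, all others 1; range 0–10, cutoff ≥ 7). Two PAS choices are
deliberate:

* **Weights.** The derivation study states only the PAS range and cutoff;
  the weights here follow the score's original publication, which the
  study's 0–10 range and 6/7/8 threshold table are consistent with.
* **Pyrexia threshold.** Set to ≥ 38.0 ℃, the fever definition the
  derivation cohort itself analysed.

Classification at a cutoff is inclusive (`score ≥ cutoff`).

## Diagnostic-accuracy statistics

All 2×2 statistics are exact functions of (TP, FP, FN, TN). Interval
methods, chosen because the derivation study does not state its own:

* **Proportions** (sens/spec/PPV/NPV): Clopper–Pearson exact. This choice
  reproduces the published sensitivity/specificity intervals (e.g. heel drop
  66/84 → 0.68–0.87, where Wilson gives 0.69–0.86).
* **Likelihood ratios**: Simel's log method,
  exp(ln LR ± z·SE) with SE² = 1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN) for the
  PLR (analogously for the NLR). Validated against the published LR
  intervals to ±0.02 — a validation, not ground truth, since the study's
  method is unstated.
* **Odds ratios**: Woolf's log method, SE² = 1/TP + 1/FP + 1/FN + 1/TN.
  Reproduces every published OR interval (e.g. nausea/vomiting
  3.354–18.794). A zero cell triggers a 0.5 continuity correction on all
  four cells, flagged on the result.
* **Predictive-value intervals**: the published PPV/NPV intervals match none
  of Clopper–Pearson, Wilson, Wald or logit; the reproduction ledger
  therefore compares PPV/NPV **point estimates only** and records the
  exclusion reason. This package reports Clopper–Pearson intervals for them.

Undefined metrics (PPV with no test-positives, PLR at specificity 1, ...)
are returned as absent, never fabricated; a perfect test yields NLR exactly
0 with no interval.

Group comparisons: Pearson chi-square for binary variables, switching to
Fisher's exact test when any expected cell count is < 5 (strict); Welch's
t-test for continuous variables. The derivation study does not state its
test variants, and several of its printed p-values are not reproducible from
its own counts under either plain or continuity-corrected chi-square, so
p-values are computed but never compared against the published ones; the
test used is recorded in output metadata.

## ROC analysis

Scores are small integers, so ties dominate; the AUC is the Mann–Whitney
statistic with half credit for tied pairs, equal to the trapezoidal area
under the empirical staircase. Operating points are the rules "score ≥ c"
for every integer c spanning the observed range plus sentinels at both ends,
so the curve always reaches (sens 1, spec 0) and (sens 0, spec 1).

AUC variance and the paired comparison use DeLong's structural components
(placement values), computed by the rank-based O(N log N) formulation; the
two-score test statistic is z = (AUC_a − AUC_b)/√(var_a + var_b − 2 cov)
with a two-sided normal p. AUC confidence intervals are normal-approximate
with the DeLong SE, clipped to [0, 1]. Degenerate zero-variance differences
return p = 1 when the AUCs are equal and raise otherwise. The implementation
is cross-checked in the tests against a brute-force pair-counting oracle,
a paired bootstrap (2,000 resamples), and R's pROC `roc.test`.

Youden cutoff: the c maximizing J = sens + spec − 1, ties broken toward the
lowest cutoff (favoring sensitivity, the usual screening preference; the
derivation study is silent). Tie detection uses a 1e-12 tolerance so that
mathematically tied J values are not split by 1-ulp float noise.

## Synthetic cohort generator

What it emulates: the derivation cohort's exact group sizes (84/58 disease
split; 52/32 uncomplicated/complicated), every published group-conditional
binary prevalence, and group-conditional lab means/SDs. The CRP ≥ 1 mg/dL
prevalences, which the univariate table omits, are reconstructed from the
per-parameter table's CRP row (52/84 and 22/58; every printed cell of that
row confirms the reconstruction) and marked "inferred" in the fixture.

Mechanism:

* Each binary feature arises from a latent standard normal thresholded at
  Φ⁻¹(p), so marginals are exact by construction. Dependence enters through
  an exchangeable latent correlation ρ (default 0 → independent Bernoulli)
  or a full latent correlation matrix. The published tables identify only
  marginals, so ρ is an explicit user knob, never silently non-zero.
* CRP uses one latent with two cutpoints, making the ≥ 1 and ≥ 5 mg/dL flags
  jointly consistent while both match their marginals.
* In the default `match_marginals` mode, flag-linked labs (WBC,
  neutrophil %, CRP, temperature) are drawn from the group normal truncated
  to the side of the threshold the flag dictates (labs truncated at zero;
  neutrophil % confined to [0, 100]; temperature untruncated below). Derived
  flags then reproduce the drawn flags exactly, and flag marginals match the
  published prevalences — which is what the reproduction-style checks need.
  The alternative `from_labs` mode draws unconditional labs and lets flags
  fall where the normal tails put them (e.g. a Normal(13,700, 5,300) puts
  ~76% of WBC above 10,000 vs the published 72.6%).
* One master seed; independent sub-streams per (group, variable) keyed by a
  stable hash, so adding a variable never perturbs another's draws. Same
  seed → byte-identical cohort.

Known departures from real data: features are conditionally independent by
default (real symptoms/labs are correlated); labs are truncated normals even
where the published mean ± SD implies strong skew (CRP 4.3 ± 9.1); outcome
subgroups differ only through the CHANSE-component shift. Passing tests on
synthetic cohorts therefore validate the *statistical machinery*, not the
clinical performance claims — in particular the published AUC pair
(0.794 vs 0.763) depends on the unpublished joint distribution and is
deliberately not an expected output.

### Severity calibration

The study reports mean CHANSE 3.0 ± 1.5 (uncomplicated) vs 4.6 ± 1.5
(complicated). `calibrate_severity_shift` fits one logit shift per diseased
subgroup, applied uniformly to the six CHANSE component prevalences
(baseline: the pooled diseased prevalences), by bisection on the closed-form
mean Σ expit(logit(p_j) + δ). The closed form is exact for any copula ρ
because the expectation of a sum of Bernoullis is independent of their
dependence; simulation at 20,000 per class recovers the targets within
±0.15. A single shift is fitted per subgroup because one global shift cannot
hit both targets (the pooled baseline mean is ≈ 3.98). Unreachable targets
(outside the open interval attainable by shifting) raise.

## Reproduction ledger

`reproduce_printed_tables()` recomputes every count-derivable published cell
(odds ratios and Woolf bounds; sensitivity/specificity points and
Clopper–Pearson bounds; PPV/NPV points; PLR/NLR points and Simel bounds) and
compares at printed precision — tolerance one unit in the last printed digit
for interval bounds (±0.02 for LR bounds), exact rounding for 2-decimal
point estimates, ±0.001 for 3-decimal odds ratios. Cells that arithmetic
shows to be internally inconsistent in the publication (the fever row of the
per-parameter table; the migration sensitivity/PLR/NLR; the
cough/percussion/hopping PLR/NLR and OR CI lower bound) are catalogued with
the recomputed value and reported as skipped-with-reason. Result on the
current fixture: 163 matches, 0 mismatches, 42 documented skips.

## Problem sizes

Defaults chosen as the package's own test conditions: study scale (142) for
end-to-end reports; 5,000–50,000 per group for marginal-fidelity checks
(3 Monte-Carlo SEs); 20,000 per class for calibration recovery (±0.15);
2,000 bootstrap resamples at n = 200 for DeLong validation; 10,000
replicates per proportion at n = 30 for Clopper–Pearson coverage.

## Known limitations

* No multivariable modelling, no external validation, no partial AUC or
  binormal ROC — the analysis mirrors a single-cohort univariate derivation.
* Published continuous-variable odds ratios (e.g. WBC 1.001) have an
  unstated per-unit scaling and are not reproduced.
* PPV/NPV are prevalence-dependent; synthetic cohorts inherit the 59.2%
  study prevalence unless the spec is changed.
* The generator's copula correlation is a knob, not an estimate; nothing in
  the published tables identifies the true joint structure.
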