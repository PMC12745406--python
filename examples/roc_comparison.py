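"""Compare CHANSE and PAS ROC curves on one synthetic cohort.

Both scores are computed on the same children, so their AUCs are correlated;
the paired DeLong z-test accounts for that.  The Youden index picks the
cutoff maximizing sensitivity + specificity - 1.
"""

from chanse import (
    calibrate_severity_shift,
    default_spec,
    delong_paired_test,
    empirical_roc,
    generate_cohort,
    score_cohort,
    threshold_table,
    youden_cutoff,
)

spec = calibrate_severity_shift(default_spec(), (3.0, 4.6))
scored = score_cohort(generate_cohort(spec, seed=1))
chanse = scored["chanse"].to_numpy(int)
pas = scored["pas"].to_numpy(int)
diseased = scored["diseased"].to_numpy(bool)

for name, s in [("CHANSE", chanse), ("PAS", pas)]:
    r = empirical_roc(s, diseased)
    cut, j = youden_cutoff(r)
    print(f"{name:6s} AUC {r.auc:.3f} (95% CI {r.auc_ci[0]:.3f}-{r.auc_ci[1]:.3f}), "
          f"Youden cutoff >= {cut} (J = {j:.2f})")

cmp_ = delong_paired_test(chanse, pas, diseased)
print(f"paired DeLong test: delta AUC = {cmp_.delta:+.3f}, "
      f"z = {cmp_.z:.2f}, two-sided p = {cmp_.p_value:.3f}")
print()

print("operating characteristics at the clinical cutoffs:")
for label, s, cuts in [("CHANSE", chanse, (2, 3, 4)), ("PAS", pas, (6, 7, 8))]:
    for cut, m in threshold_table(s, diseased, cuts):
        print(f"  {label} >= {cut}: sens {m.sensitivity.value:.2f}, "
              f"spec {m.specificity.value:.2f}, PLR "
              f"{m.plr.value:.2f}, NLR {m.nlr.value:.2f}")
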