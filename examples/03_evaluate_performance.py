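"""Evaluate a recalibrated model with the full metric battery.

AUROC (discrimination), Brier / scaled Brier (overall accuracy), the
modified Hosmer-Lemeshow test and calibration slope/intercept
(calibration), AIC (fit), and the bootstrap optimism-corrected AUROC
(internal validation).
"""

from icurecal import (
    GeneratorConfig,
    fit_logistic_recal,
    generate_cohort,
    optimism_corrected_auroc,
    original_model,
    performance_report,
)

cohort = generate_cohort(GeneratorConfig(n_patients=10000, seed=1))
model = fit_logistic_recal(cohort)

for name, m in (("before recalibration", original_model()),
                ("after (model 2)", model)):
    rep = performance_report(m, cohort, seed=1)
    print(f"--- {name} ---")
    print(f"AUROC          {rep.auroc:.3f}")
    print(f"Brier          {rep.brier:.3f}   scaled {rep.scaled_brier:.2f}")
    print(f"HL p value     {rep.hl_p:.3g}")
    print(f"calibration    intercept {rep.cal_intercept:+.2f}  "
          f"slope {rep.cal_slope:.2f}")
    print(f"SMR            {rep.smr:.2f}")
    print()

val = optimism_corrected_auroc(fit_logistic_recal, cohort, n_boot=200, seed=1)
print(f"optimism-corrected AUROC: {val.corrected:.3f} "
      f"(apparent {val.apparent:.3f}, optimism {val.optimism:+.4f})")
print()
print("Recalibration leaves discrimination unchanged (same ranking of")
print("patients) but repairs calibration: slope/intercept move to 1/0 and")
print("the SMR to 1. The near-zero optimism shows the 2-parameter update")
print("barely overfits.")
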