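"""Apply a recalibrated model to SMR funnel plots and EWMA charts.

The funnel plot compares each ICU's SMR against control limits that
narrow with expected deaths; overdispersion factor phi > 1 signals
variation beyond binomial noise. The EWMA chart tracks smoothed
mortality over sequential admissions against risk-derived limits
(weight 0.005 on the newest admission).
"""

from icurecal import (
    GeneratorConfig,
    ewma,
    fit_hierarchical_gam,
    fit_logistic_recal,
    funnel,
    generate_cohort,
    summarize_units,
)
from icurecal.plots import ewma_plot, funnel_plot

cohort = generate_cohort(GeneratorConfig(n_patients=10000, sigma_u=0.3, seed=2))
m2 = fit_logistic_recal(cohort)
m3 = fit_hierarchical_gam(cohort)

for name, model in (("model 2", m2), ("model 3", m3)):
    chart = funnel(summarize_units(cohort, model))
    print(f"{name}: phi = {chart.phi:.2f}, "
          f"outliers beyond 3 SD: {chart.outliers}")

chart3 = funnel(summarize_units(cohort, m3))
funnel_plot(chart3, "funnel_model3.png", title="model 3")

series = ewma(cohort, m3, lam=0.005)
ewma_plot(series, "ewma_model3.png", title="model 3")
print(f"EWMA chart: {series.n} admissions, "
      f"excursions beyond 3 SD: {series.excursions}")
print()
print("Model 2 ignores ICU-level heterogeneity, so phi exceeds 1: unit SMRs")
print("scatter more widely than binomial noise allows. Model 3 absorbs unit")
print("effects through its random intercepts, pulling phi back below 1.")
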