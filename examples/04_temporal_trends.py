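"""Inverse-sample-size-weighted temporal trend of the PFAS sum.

Each donor's log10 summed concentration is regressed on collection year,
with every observation weighted by 1/(samples that year) so heavily sampled
years do not dominate.  The fitted line converts to modeled geometric means
and a percent reduction over the study window.
"""

import logging

from liverpfas import (
    CohortTable,
    default_panel,
    default_params,
    fit_weighted_trend,
    generate_cohort,
    generate_true_concentrations,
    geometric_mean_at,
    percent_reduction,
    sum_pfas,
    table_from_truth,
)

logging.disable(logging.WARNING)

params = default_params(seed=17)
cohort = generate_cohort(params)
truth = generate_true_concentrations(cohort, params)
table = table_from_truth(truth, cohort, {n: a.idl for n, a in params.analytes.items()})

sums = sum_pfas(table, mode="detected_only")
years = table.donors.set_index("donor_id")["year"].reindex(sums.index)
exact = table.donors.set_index("donor_id")["year_exact"].reindex(sums.index)
ok = exact.fillna(False).astype(bool) & (sums > 0)
fit = fit_weighted_trend(sums[ok].to_numpy(), years[ok].to_numpy())

print(f"n = {fit.n_obs} donors with exact collection years")
print(f"slope beta1 = {fit.beta1:+.4f} log10 units/year "
      f"({fit.pct_change_per_decade:+.1f}% per decade), p = {fit.p_value:.2e}")
print(f"modeled geometric mean: {geometric_mean_at(fit, 2000):.1f} ng/g in 2000 "
      f"-> {geometric_mean_at(fit, 2024):.2f} ng/g in 2024")
print(f"percent reduction 2000-2024: {percent_reduction(fit, 2000, 2024):.0f}%")
print("\nA negative slope means liver burdens fell over the sampling period;")
print("the weighting keeps single heavily-sampled years from driving the fit.")
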