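"""Median-stratified survival analysis.

Simulates a 300-subject cohort in which subjects at or above the
covariate median carry a 3x hazard, splits at the median, fits
Kaplan-Meier curves and runs the log-rank test.
"""

import immunosift as ims
from immunosift.io import SurvivalTable

cohort, truth = ims.generate_survival_cohort(n=300, hazard_ratio=3.0, censor_rate=0.2, seed=6)
labels = ims.stratify_by_median(cohort.df["covariate"])
high = SurvivalTable(cohort.df[labels == "high"])
low = SurvivalTable(cohort.df[labels == "low"])

km_high = ims.km_estimate(high, "high")
km_low = ims.km_estimate(low, "low")
res = ims.logrank_test(high, low)

t_ref = float(km_low.event_times[len(km_low.event_times) // 2])
print(f"n high / low:        {len(high.df)} / {len(low.df)}")
print(f"events high / low:   {km_high.events.sum()} / {km_low.events.sum()}")
print(f"S(t={t_ref:.1f}) high:     {km_high.survival_at(t_ref):.3f}")
print(f"S(t={t_ref:.1f}) low:      {km_low.survival_at(t_ref):.3f}")
print(f"log-rank chi-square: {res['chi_square']:.2f}")
print(f"log-rank p:          {res['p_value']:.3g}")
print()
print("High-covariate subjects (planted hazard ratio 3) die faster; the")
print("log-rank test rejects equality of the two survival curves decisively.")
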