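"""Agreement tables: week discrepancy, GA-bin concordance and prevalence.

The discrepancy table rounds |predicted - ultrasound| half-up to whole weeks
(capped at >=4) and reports cumulative percentages; GA bins are on completed
weeks, so the <=34 and 35-36 bins together are the preterm (<37 wk) share.
"""

import metaga as m
from metaga.agreement import GA_BINS

cohort, _ = m.generate_cohort(m.SimConfig(n=4000, seed=20))
build, validation = m.split_cohort(cohort, 0.5, 7)
spec = m.select_terms(m.screen_all(build, 0.01), build, 0.05)
preds = m.predict_ga(validation, m.fit_model(build, spec.with_birthweight()))

disc = m.discrepancy_table(preds)
print("weeks discrepant   n     %     cumulative %")
for cat in disc.counts:
    print(f"{cat:>6}        {disc.counts[cat]:>6} {disc.percentages[cat]:>6.1f} {disc.cumulative[cat]:>8.1f}")

conc = m.concordance_table(preds)
print("\nconcordance diagonal (per ultrasound GA bin):")
for b in GA_BINS:
    d = conc.diagonal_pct[b]
    print(f"  {b:>6}: {'-' if d is None else f'{d:.1f}%'}  (row n={conc.row_totals[list(GA_BINS).index(b)]})")

prev = m.prevalence_table(preds)
print(f"\npreterm prevalence: predicted {prev.predicted_preterm_pct:.1f}% "
      f"vs ultrasound {prev.ultrasound_preterm_pct:.1f}%")

print("\nby region:")
for name, sm_ in m.subgroup_metrics(preds, by="region").items():
    print(f"  {name}: n={sm_.n}, RMSE {sm_.rmse:.2f}, within 1 wk {sm_.discrepancy.within(1):.1f}%")
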