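"""Generate a synthetic newborn-screening cohort and inspect its marginals.

The generator draws gestational age from a term/preterm mixture, birthweight
from a linear-in-GA sex-offset Normal, and 44 analyte concentrations whose
means are low-degree polynomials in GA.  SGA is flagged against the
generator's own analytic 10th-percentile birthweight standard.
"""

import numpy as np

import metaga as m

cohort, truth = m.generate_cohort(m.SimConfig(n=5000, seed=20))

ga = np.array([r.ga_ultrasound for r in cohort.records])
bw = np.array([r.birthweight for r in cohort.records])
print(f"n = {len(cohort)}")
print(f"preterm (<37 wk): {100 * np.mean(ga < 37):.1f}%   (target 11.4%)")
print(f"SGA:              {100 * np.mean([r.sga for r in cohort.records]):.1f}%   (10% by construction)")
print(f"low birthweight:  {100 * np.mean(bw < 2500):.1f}%")
print(f"GA mean +/- sd:   {ga.mean():.1f} +/- {ga.std():.1f} wk")
print(f"birthweight:      {bw.mean():.0f} +/- {bw.std():.0f} g")

# the analytic SGA threshold is the 10th percentile of the conditional Normal
print(f"SGA threshold, 40-wk male: {m.sga_threshold(40.0, 'male', m.SimConfig(n=1, seed=0)):.0f} g")
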