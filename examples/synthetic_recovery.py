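"""Recover injected age/period/cohort truth from noisy synthetic cells.

Generates cell-mean records with a known additive structure, a +5
g/4,186 kJ/day interaction on the 1940s birth cohort, and Gaussian cell
noise, then runs the full pipeline and compares recovered effects with
the truth.
"""

import numpy as np

from apcpolish import RunConfig, SynthSpec, make_cell_table, run_apc

truth = SynthSpec(
    grand=100.0,
    age_effects=(0.0, -3.3, -9.3, -13.5, -22.2),
    period_effects=(0.0, 9.4, 17.6),
    cohort_effects={1940: 5.0},
    noise_sd=1.0,
    seed=20140408,
    genders=("men",),
    foods=("meat",),
)

out = make_cell_table(truth)
results, _ = run_apc(out.records, RunConfig(harmonize=False))
res = results[("men", "meat")]

print("injected anchored age effects :", truth.age_effects)
print("recovered anchored age effects:",
      np.round(res.anchored.age_effects_vs_ref, 2))
print("recovered period effects      :",
      np.round(res.anchored.period_effects_vs_ref, 2))
print("recovered cohort effects      :",
      {k: round(v, 2) for k, v in res.cohorts.reported_values().items()})
print()
print("The 1940-1949 cohort shows the largest residual average: part of the")
print("+5 interaction is absorbed into age and period effects (the additive")
print("fit is a projection), the rest sits on that cohort's diagonal.")
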