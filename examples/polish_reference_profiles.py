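"""Polish a zero-residual table built from published meat effect rows.

Constructs the men's meat age x period table as grand + age effects +
period effects (no interaction), runs the mean polish and prints the
re-anchored effects: the round trip must return the rows it was built
from, and every cohort residual average must be zero.
"""

import numpy as np

from apcpolish import (APCTable, anchor, build_additive_table, cohort_effects,
                       food_group, mean_polish)
from apcpolish.published import AGE_EFFECTS, PERIOD_EFFECTS

age_row = AGE_EFFECTS["meat"]["men"]
period_row = PERIOD_EFFECTS["meat"]["men"]

table = APCTable(build_additive_table(100.0, age_row, period_row),
                 "men", food_group("meat"))
decomp = mean_polish(table)
anc = anchor(decomp)  # reference: age 20-29, year 1989

print("men's meat, zero-residual fixture (g/4,186 kJ/day)")
print("  anchored age effects   :", np.round(anc.age_effects_vs_ref, 1))
print("  anchored period effects:", np.round(anc.period_effects_vs_ref, 1))
print("  max |residual|         :", float(np.max(np.abs(decomp.residuals))))
print("  cohort residual means  :",
      {e.label: round(e.c_value, 10) for e in cohort_effects(decomp).effects
       if e.reported})
print()
print("The anchored age row reads: a 60-69 year-old man eats 22.2 g less")
print("meat per 4,186 kJ than a 20-29 year-old, at any survey year; the")
print("zero cohort values say the table carries no age x time interaction.")
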