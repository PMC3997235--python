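"""Marginal age profiles from the published year-averaged reference table.

Loads the packaged transcription of the year-averaged survey marginals
(which collapse the three survey years, so they cannot be polished) and
prints the meat and fruits age profiles for both genders.
"""

from apcpolish import marginal_age_summary, nhns_year_averaged_fixture

records = nhns_year_averaged_fixture()
summary = marginal_age_summary(records, weights="none")

for food in ("meat", "fruits"):
    print(f"{food} (g/4,186 kJ/day, year-averaged):")
    for gender in ("men", "women"):
        sel = summary[(summary["food"] == food) & (summary["gender"] == gender)]
        profile = sel.sort_values("age_group")["mean_intake"].round(1).tolist()
        print(f"  {gender:6s} 20-29..60-69: {profile}")
print()
print("Meat falls and fruit rises with age in both genders — but these raw")
print("marginals mix age with period and cohort; the polish separates them.")
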