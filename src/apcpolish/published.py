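"""Published NHNS-J reference values used as fixtures and worked examples.

Two kinds of numbers are transcribed here, both at the one-decimal
precision they were printed at:

* ``YEAR_AVERAGED_INTAKE`` and companions — the gender- and
  age-stratified food and energy intakes of the National Health and
  Nutrition Survey in Japan (1989, 1999 and 2009 waves), averaged over
  the three survey years, with per-wave subject counts.  These are
  year-averaged marginals: the per-year 5 x 3 cell tables behind them
  were never published, so they support marginal summaries but not the
  polish itself.

* ``AGE_EFFECTS`` / ``PERIOD_EFFECTS`` / ``COHORT_EFFECTS`` — published
  mean-polish effect estimates for the same data (age effects anchored
  to the 20-29 group, period effects anchored to 1989, cohort effects
  for the 1930-1979 birth decades).  They serve as injected truth when
  building zero-residual fixture tables and as cross-checks in tests
  and examples.

Intakes and effects are in g per 4,186 kJ per day; energy in kJ/day.
Age columns run 20-29 ... 60-69; period columns 1989, 1999, 2009;
cohort columns 1930-39 ... 1970-79.
"""

from __future__ import annotations

GENDERS = ("men", "women")
AGE_LABELS = ("20-29", "30-39", "40-49", "50-59", "60-69")
PERIOD_YEARS = (1989, 1999, 2009)
COHORT_STARTS = (1930, 1940, 1950, 1960, 1970)

# Mean energy intake, kJ/day, by gender and age group (year-averaged).
ENERGY_KJ: dict[str, tuple[float, ...]] = {
    "men": (8941.2, 9295.5, 9497.7, 9430.7, 9140.6),
    "women": (7309.4, 7695.8, 7638.6, 7875.7, 7500.5),
}

# Subjects per survey wave, by gender and age group.
N_SUBJECTS: dict[int, dict[str, tuple[int, ...]]] = {
    1989: {"men": (129, 46, 36, 35, 25), "women": (36, 23, 41, 82, 122)},
    1999: {"men": (693, 736, 794, 942, 787), "women": (838, 808, 876, 1011, 946)},
    2009: {"men": (297, 500, 539, 603, 690), "women": (362, 579, 596, 651, 815)},
}

# Year-averaged energy-adjusted intake, g/4,186 kJ/day: food -> gender -> 5 ages.
YEAR_AVERAGED_INTAKE: dict[str, dict[str, tuple[float, ...]]] = {
    "rice": {"men": (206.2, 205.5, 211.1, 215.8, 207.7),
             "women": (136.4, 146.6, 147.8, 157.0, 154.4)},
    "wheat": {"men": (113.1, 112.7, 115.1, 105.6, 101.7),
              "women": (110.0, 108.2, 97.0, 93.2, 83.0)},
    "potatoes": {"men": (50.3, 49.6, 50.3, 52.8, 60.0),
                 "women": (47.8, 50.2, 53.9, 62.6, 65.7)},
    "green yellow vegetables": {"men": (69.7, 86.3, 77.8, 91.0, 101.9),
                                "women": (72.0, 87.0, 93.3, 104.7, 113.2)},
    "other vegetables": {"men": (152.9, 162.8, 170.0, 190.5, 206.0),
                         "women": (143.4, 159.9, 174.6, 183.9, 183.6)},
    "fruits": {"men": (67.2, 62.3, 78.8, 105.3, 133.1),
               "women": (76.5, 90.1, 135.0, 178.9, 183.6)},
    "milk and dairy products": {"men": (95.1, 83.0, 99.0, 82.8, 121.3),
                                "women": (107.6, 118.5, 112.9, 125.5, 125.1)},
    "meat": {"men": (109.9, 106.5, 94.7, 84.9, 63.4),
             "women": (80.4, 80.1, 73.2, 60.4, 51.7)},
    "fish": {"men": (70.4, 84.8, 100.1, 112.9, 117.5),
             "women": (62.4, 65.7, 84.8, 94.3, 94.7)},
    "egg": {"men": (41.5, 42.6, 42.1, 43.0, 42.1),
            "women": (40.0, 40.3, 38.6, 35.9, 33.9)},
    "beans": {"men": (49.6, 56.7, 63.8, 85.5, 85.2),
              "women": (46.7, 55.1, 58.9, 73.9, 78.9)},
    "confectionery": {"men": (15.2, 12.4, 14.9, 10.8, 17.0),
                      "women": (29.9, 22.6, 25.1, 26.4, 25.7)},
    "sugar": {"men": (8.0, 9.6, 9.2, 9.2, 9.4),
              "women": (7.7, 8.3, 9.6, 10.6, 10.2)},
    "fats and oils": {"men": (19.6, 19.7, 17.9, 16.7, 12.7),
                      "women": (17.2, 16.7, 16.1, 15.1, 11.7)},
}

# Published polish age effects anchored to the 20-29 group (g/4,186 kJ/day).
AGE_EFFECTS: dict[str, dict[str, tuple[float, ...]]] = {
    "rice": {"men": (0.0, -4.0, -3.6, -0.9, -1.6),
             "women": (0.0, 1.2, 3.5, 6.3, 17.6)},
    "wheat": {"men": (0.0, -2.3, -2.2, -6.2, -6.4),
              "women": (0.0, -5.6, -9.3, -12.6, -14.8)},
    "potatoes": {"men": (0.0, -1.0, -1.1, 0.1, 4.1),
                 "women": (0.0, 2.0, 5.8, 9.1, 11.8)},
    "green yellow vegetables": {"men": (0.0, 6.5, 2.0, 8.1, 14.3),
                                "women": (0.0, 3.8, 8.6, 16.1, 16.3)},
    "other vegetables": {"men": (0.0, 2.2, 3.9, 13.4, 23.2),
                         "women": (0.0, 8.3, 10.8, 15.6, 14.4)},
    "fruits": {"men": (0.0, -3.4, 3.2, 15.3, 29.5),
               "women": (0.0, 24.5, 45.6, 53.7, 47.5)},
    "milk and dairy products": {"men": (0.0, -6.9, -0.9, -7.6, 11.2),
                                "women": (0.0, -2.6, 2.0, 5.4, -3.3)},
    "meat": {"men": (0.0, -3.3, -9.3, -13.5, -22.2),
             "women": (0.0, -3.5, -11.6, -15.0, -18.3)},
    "fish": {"men": (0.0, 5.4, 11.2, 17.2, 21.0),
             "women": (0.0, 10.5, 14.5, 17.3, 16.6)},
    "egg": {"men": (0.0, -0.2, -0.8, -0.3, -0.1),
            "women": (0.0, -0.7, -2.7, -2.9, -0.6)},
    "beans": {"men": (0.0, 2.4, 5.0, 14.8, 15.9),
              "women": (0.0, 2.3, 9.3, 14.0, 13.7)},
    "confectionery": {"men": (0.0, -1.5, -0.5, -2.3, 0.7),
                      "women": (0.0, 1.3, 1.6, 1.7, 1.7)},
    "sugar": {"men": (0.0, 0.5, 0.3, 0.3, 0.5),
              "women": (0.0, 0.7, 1.1, 1.2, 1.6)},
    "fats and oils": {"men": (0.0, -0.4, -1.4, -1.9, -3.5),
                      "women": (0.0, -0.3, -1.1, -2.5, -3.3)},
}

# Published polish period effects anchored to 1989 (g/4,186 kJ/day).
PERIOD_EFFECTS: dict[str, dict[str, tuple[float, ...]]] = {
    "rice": {"men": (0.0, -4.7, 2.1), "women": (0.0, -9.9, -7.2)},
    "wheat": {"men": (0.0, -9.9, 0.6), "women": (0.0, -1.1, 9.5)},
    "potatoes": {"men": (0.0, 12.7, 9.1), "women": (0.0, 8.0, 1.2)},
    "green yellow vegetables": {"men": (0.0, 15.0, 12.4), "women": (0.0, 3.3, 6.4)},
    "other vegetables": {"men": (0.0, 19.7, 13.8), "women": (0.0, -1.3, -8.3)},
    "fruits": {"men": (0.0, 4.7, 0.0), "women": (0.0, -15.5, -20.8)},
    "milk and dairy products": {"men": (0.0, -10.5, -16.2), "women": (0.0, -1.3, -8.3)},
    "meat": {"men": (0.0, 9.4, 17.6), "women": (0.0, 7.4, 14.0)},
    "fish": {"men": (0.0, 8.2, -3.7), "women": (0.0, 5.1, -5.9)},
    "egg": {"men": (0.0, 0.9, -1.7), "women": (0.0, -1.6, -2.9)},
    "beans": {"men": (0.0, 2.5, -6.2), "women": (0.0, 4.3, -2.5)},
    "confectionery": {"men": (0.0, 0.9, 2.2), "women": (0.0, 1.8, 3.2)},
    "sugar": {"men": (0.0, -0.3, -1.8), "women": (0.0, -1.1, -2.5)},
    "fats and oils": {"men": (0.0, -1.2, -3.6), "women": (0.0, -0.7, -3.6)},
}

# Published cohort effects, birth decades 1930-39 ... 1970-79 (g/4,186 kJ/day).
COHORT_EFFECTS: dict[str, dict[str, tuple[float, ...]]] = {
    "rice": {"men": (3.1, -3.6, -3.4, 1.2, 2.2),
             "women": (0.7, 1.6, -1.4, -1.6, -0.2)},
    "wheat": {"men": (0.3, 1.2, -0.2, 0.0, -2.1),
              "women": (-0.6, -1.7, -0.4, 0.1, 2.6)},
    "potatoes": {"men": (1.0, 0.1, -0.1, -0.5, 1.4),
                 "women": (1.5, 0.0, -2.0, -0.7, 0.5)},
    "green yellow vegetables": {"men": (-0.1, 0.8, 0.9, 0.1, -0.7),
                                "women": (-3.4, 1.5, 3.8, 1.3, -2.5)},
    "other vegetables": {"men": (-1.3, -1.9, -0.2, -1.9, 4.2),
                         "women": (-2.7, -0.6, 4.5, 0.8, -5.4)},
    "fruits": {"men": (3.0, 3.2, 1.4, -2.3, -2.7),
               "women": (-5.2, 5.4, 7.6, -4.5, -5.3)},
    "milk and dairy products": {"men": (-4.7, 3.6, -4.1, -7.6, 5.3),
                                "women": (3.4, 3.2, 0.1, -2.8, -0.8)},
    "meat": {"men": (0.3, -1.9, 0.3, 1.2, 0.8),
             "women": (0.5, -2.1, -1.4, -0.1, 1.8)},
    "fish": {"men": (-3.3, 4.2, 0.0, -2.3, 1.3),
             "women": (-1.8, -0.1, 5.7, -0.4, -4.7)},
    "egg": {"men": (-1.0, -1.2, 1.8, -0.5, -0.8),
            "women": (-0.4, -1.0, -0.3, 1.0, 0.1)},
    "beans": {"men": (3.4, -1.3, -1.7, -1.1, 1.2),
              "women": (1.5, 0.3, -0.9, -0.1, -0.1)},
    "confectionery": {"men": (-0.8, 0.2, -0.2, -0.3, -0.5),
                      "women": (1.8, -0.8, -1.2, -0.7, 1.5)},
    "sugar": {"men": (0.2, 0.3, 0.3, -0.1, -0.3),
              "women": (-0.3, 0.2, 0.1, -0.4, 0.0)},
    "fats and oils": {"men": (-0.1, 0.0, 0.5, 0.4, -0.6),
                      "women": (-0.2, 0.2, 0.1, 0.2, -0.2)},
}
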