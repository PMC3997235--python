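import csv

import numpy as np
import pytest

from apcpolish import AGE_GROUPS, PERIODS, APCTable, food_group


def closed_form_decomposition(values: np.ndarray):
    """Independent oracle: the textbook two-way decomposition.

    grand = overall mean, a_i = row mean - grand, t_j = column mean -
    grand, e_ij = value - row mean - column mean + grand.
    """
    grand = values.mean()
    a = values.mean(axis=1) - grand
    t = values.mean(axis=0) - grand
    resid = values - values.mean(axis=1, keepdims=True) \
        - values.mean(axis=0, keepdims=True) + grand
    return grand, a, t, resid


@pytest.fixture
def random_table():
    def make(seed: int, low: float = 0.0, high: float = 200.0) -> APCTable:
        rng = np.random.default_rng(seed)
        values = rng.uniform(low, high, size=(len(AGE_GROUPS), len(PERIODS)))
        return APCTable(values, "men", food_group("meat"))
    return make


@pytest.fixture
def write_long_csv(tmp_path):
    """Write rows of (gender, age, year, food, intake, energy, n) to a CSV."""
    def write(rows, name="table.csv", header=None):
        path = tmp_path / name
        header = header or ["gender", "age_group", "survey_year", "food_group",
                            "mean_intake_g_per_day", "mean_energy", "n_subjects"]
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)
        return path
    return write


@pytest.fixture
def complete_rows():
    """Raw CSV rows covering the full 5 x 3 grid for one gender x food."""
    def make(gender="men", food="meat", intake=100.0, energy=4186.0, n=50):
        return [
            [gender, a.label, p.year, food, intake, energy, n]
            for a in AGE_GROUPS for p in PERIODS
        ]
    return make
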