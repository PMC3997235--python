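"""Long-format survey tables: records, readers/writers, harmonization.

The interchange format is a delimited long table with one row per
(gender, age group, survey year, food group) cell holding the cell's
mean intake, mean energy and subject count — the machine-readable
counterpart of published gender- and age-stratified survey tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .energy import KCAL_TO_KJ_FACTOR, REFERENCE_ENERGY_KJ, energy_adjust
from .grid import (AGE_GROUPS, GENDERS, PERIODS, AgeGroup, FoodGroup, Period,
                   age_group, food_group, period)


class TableError(ValueError):
    """Fatal problem in a long table: parse failure, duplicate or missing cell."""


class HarmonizationError(ValueError):
    """Invalid harmonization rule or attempted re-application."""


@dataclass(frozen=True)
class LongRecord:
    """One survey cell: a gender x age x period x food mean.

    ``mean_intake`` is in g/day until :func:`adjust_records` re-expresses
    it in g per 4,186 kJ/day and sets ``energy_adjusted``.  ``period`` is
    ``None`` only for year-averaged reference records, which are valid
    for marginal summaries but never for the 5 x 3 decomposition.
    ``harmonizations`` records the ids of coding-correction rules already
    applied, so a rule is never applied twice.
    """

    gender: str
    age_group: AgeGroup
    period: Period | None
    food: FoodGroup
    mean_intake: float
    mean_energy_kj: float
    n_subjects: int
    energy_adjusted: bool = False
    harmonizations: tuple[str, ...] = ()
    year_averaged: bool = False

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise TableError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if not np.isfinite(self.mean_intake) or self.mean_intake < 0:
            raise TableError(f"mean intake must be finite and >= 0, got {self.mean_intake!r}")
        if not np.isfinite(self.mean_energy_kj) or self.mean_energy_kj <= 0:
            raise TableError(f"mean energy must be finite and > 0, got {self.mean_energy_kj!r}")
        if self.n_subjects < 1:
            raise TableError(f"n_subjects must be >= 1, got {self.n_subjects!r}")

    @property
    def key(self) -> tuple[str, str, int | None, str]:
        year = self.period.year if self.period is not None else None
        return (self.gender, self.age_group.label, year, self.food.name)


# ---------------------------------------------------------------------------
# Reading and writing

DEFAULT_COLUMNS: Mapping[str, str] = {
    "gender": "gender",
    "age_group": "age_group",
    "survey_year": "survey_year",
    "food_group": "food_group",
    "mean_intake": "mean_intake_g_per_day",
    "mean_energy": "mean_energy",
    "n_subjects": "n_subjects",
}


@dataclass(frozen=True)
class Dialect:
    """How to read one long-table file.

    The energy unit is declared, never auto-detected; kcal values are
    converted to kJ on read with the configured factor (default 4.186).
    """

    delimiter: str = ","
    columns: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    energy_unit: str = "kJ"          # "kJ" or "kcal"
    kcal_factor: float = KCAL_TO_KJ_FACTOR

    def __post_init__(self) -> None:
        if self.energy_unit not in ("kJ", "kcal"):
            raise TableError(f"energy_unit must be 'kJ' or 'kcal', got {self.energy_unit!r}")


def read_long_table(path: str | Path, dialect: Dialect = Dialect()) -> list[LongRecord]:
    """Read a delimited long table into records, validating every row.

    Raises :class:`TableError` with the offending column name, key or
    line number on missing columns, duplicate keys, or unparseable or
    negative values.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str,
                     skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [v for v in dialect.columns.values() if v not in df.columns]
    if missing:
        raise TableError(f"{path}: missing column(s) {missing}")

    records: list[LongRecord] = []
    seen: dict[tuple, int] = {}
    col = dialect.columns
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        row = dict(zip(df.columns, row))
        try:
            intake = float(row[col["mean_intake"]])
            energy = float(row[col["mean_energy"]])
            n = int(float(row[col["n_subjects"]]))
        except (TypeError, ValueError) as exc:
            raise TableError(f"{path}:{line}: non-numeric value ({exc})") from None
        if dialect.energy_unit == "kcal":
            energy *= dialect.kcal_factor
        try:
            rec = LongRecord(
                gender=str(row[col["gender"]]).strip().lower(),
                age_group=age_group(row[col["age_group"]]),
                period=period(row[col["survey_year"]]),
                food=food_group(row[col["food_group"]]),
                mean_intake=intake,
                mean_energy_kj=energy,
                n_subjects=n,
            )
        except (KeyError, TableError) as exc:
            raise TableError(f"{path}:{line}: {exc}") from None
        if rec.key in seen:
            raise TableError(
                f"{path}:{line}: duplicate key {rec.key} "
                f"(first seen at line {seen[rec.key]})"
            )
        seen[rec.key] = line
        records.append(rec)
    return records


def write_long_table(records: Iterable[LongRecord], path: str | Path,
                     dialect: Dialect = Dialect()) -> None:
    """Write records as a delimited long table (full precision, kJ energies)."""
    path = Path(path)
    col = dialect.columns
    header = [col["gender"], col["age_group"], col["survey_year"],
              col["food_group"], col["mean_intake"], col["mean_energy"],
              col["n_subjects"]]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(header)
        for r in sorted(records, key=lambda r: (r.gender, r.food.name,
                                                r.period.index if r.period else 0,
                                                r.age_group.index)):
            writer.writerow([
                r.gender, r.age_group.label,
                r.period.year if r.period is not None else "",
                r.food.name, repr(r.mean_intake), repr(r.mean_energy_kj),
                r.n_subjects,
            ])


# ---------------------------------------------------------------------------
# Harmonization of food-coding changes across survey waves

@dataclass(frozen=True)
class HarmonizationRule:
    """Divide one food's intake in one survey year by a fixed factor.

    The default rule halves rice in 2009: that survey coded rice as
    steamed rather than milled grain, roughly doubling recorded weights,
    so intakes are divided by exactly 2 to restore comparability.
    """

    food: str
    year: int
    divisor: float

    @property
    def rule_id(self) -> str:
        return f"{self.food}/{self.year}/{self.divisor:g}"


DEFAULT_RULES: tuple[HarmonizationRule, ...] = (
    HarmonizationRule("rice", 2009, 2.0),
)


def harmonize_food_coding(
    records: Sequence[LongRecord],
    rules: Sequence[HarmonizationRule] = DEFAULT_RULES,
) -> tuple[list[LongRecord], list[str]]:
    """Apply coding-correction rules, returning new records and an audit log.

    Non-matching records pass through unchanged.  A record already
    tagged with a rule's id is refused — re-applying would compound the
    correction — raising :class:`HarmonizationError`.
    """
    for rule in rules:
        food_group(rule.food)  # raises KeyError on unknown food
        period(rule.year)
        if rule.divisor <= 0:
            raise HarmonizationError(f"divisor must be positive in rule {rule.rule_id}")

    out: list[LongRecord] = []
    audit: list[str] = []
    for rec in records:
        for rule in rules:
            matches = (rec.food.name == food_group(rule.food).name
                       and rec.period is not None
                       and rec.period.year == rule.year)
            if not matches:
                continue
            if rule.rule_id in rec.harmonizations:
                raise HarmonizationError(
                    f"rule {rule.rule_id} already applied to record {rec.key}; "
                    "refusing to re-apply"
                )
            new_intake = rec.mean_intake / rule.divisor
            audit.append(
                f"harmonize {rule.rule_id}: {rec.key} "
                f"intake {rec.mean_intake!r} -> {new_intake!r}"
            )
            rec = replace(rec, mean_intake=new_intake,
                          harmonizations=rec.harmonizations + (rule.rule_id,))
        out.append(rec)
    return out, audit


# ---------------------------------------------------------------------------
# Energy adjustment of cell means

def adjust_records(records: Sequence[LongRecord],
                   reference_energy_kj: float = REFERENCE_ENERGY_KJ) -> list[LongRecord]:
    """Energy-density adjust every record's cell mean (g/day -> g/4,186 kJ/day).

    Records already adjusted pass through unchanged.
    """
    out = []
    for rec in records:
        if rec.energy_adjusted:
            out.append(rec)
            continue
        adj = energy_adjust(rec.mean_intake, rec.mean_energy_kj,
                            reference_energy_kj)
        out.append(replace(rec, mean_intake=adj, energy_adjusted=True))
    return out


# ---------------------------------------------------------------------------
# Contingency-table assembly

def to_apc_table(records: Iterable[LongRecord], gender: str, food: str | FoodGroup):
    """Assemble the complete 5 x 3 age x period table for one gender x food.

    Requires exactly one energy-adjusted record per cell; any missing
    cell is fatal (the decomposition presumes a complete table and the
    package never imputes).  Returns an :class:`~apcpolish.polish.APCTable`.
    """
    from .polish import APCTable  # local import to keep polish free of IO

    food = food_group(food)
    values = np.full((len(AGE_GROUPS), len(PERIODS)), np.nan)
    counts = np.zeros((len(AGE_GROUPS), len(PERIODS)), dtype=int)
    for rec in records:
        if rec.gender != gender or rec.food.name != food.name:
            continue
        if rec.period is None:
            raise TableError(
                f"year-averaged record {rec.key} cannot enter an age-period table"
            )
        if not rec.energy_adjusted:
            raise TableError(f"record {rec.key} is not energy-adjusted")
        i, j = rec.age_group.index - 1, rec.period.index - 1
        if not np.isnan(values[i, j]):
            raise TableError(f"duplicate cell for {rec.key}")
        values[i, j] = rec.mean_intake
        counts[i, j] = rec.n_subjects
    missing = [(AGE_GROUPS[i].label, PERIODS[j].year)
               for i in range(len(AGE_GROUPS)) for j in range(len(PERIODS))
               if np.isnan(values[i, j])]
    if missing:
        raise TableError(
            f"incomplete table for ({gender}, {food.name}): "
            f"missing (age, period) cells {missing}"
        )
    return APCTable(values=values, gender=gender, food=food, n_subjects=counts)


# ---------------------------------------------------------------------------
# Marginal summaries (descriptive, across periods)

def marginal_age_summary(records: Sequence[LongRecord],
                         weights: str = "none") -> pd.DataFrame:
    """Per-age-group means across survey years, unweighted or n-weighted.

    Both weightings are offered because published year-averaged tables
    do not state which they used; neither reproduces the polish age
    effects, which are adjusted for period.
    """
    if weights not in ("none", "n_subjects"):
        raise ValueError("weights must be 'none' or 'n_subjects'")
    rows = []
    for rec in records:
        rows.append({
            "gender": rec.gender, "food": rec.food.name,
            "age_group": rec.age_group.label,
            "value": rec.mean_intake, "n": rec.n_subjects,
        })
    df = pd.DataFrame(rows)

    def agg(g: pd.DataFrame) -> float:
        if weights == "none":
            return float(g["value"].mean())
        return float(np.average(g["value"], weights=g["n"]))

    out = (df.groupby(["gender", "food", "age_group"])
             .apply(agg, include_groups=False)
             .rename("mean_intake").reset_index())
    return out


# ---------------------------------------------------------------------------
# Effect-table output

def write_effect_tables(results: Mapping, out_dir: str | Path,
                        rounding: int = 1) -> dict[str, Path]:
    """Write the three effect tables plus a full-precision sidecar.

    ``results`` maps (gender, food name) to an
    :class:`~apcpolish.pipeline.APCResult`.  Three delimited files mirror
    the conventional presentation — foods as rows, gender x level as
    columns, values rounded to ``rounding`` decimals (default 1) — while
    ``effects_full.csv`` keeps every quantity at full precision, keyed by
    gender, food, effect type and level.  An empty ``results`` produces
    header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genders = sorted({g for g, _ in results}) or list(GENDERS)
    foods = sorted({f for _, f in results})

    def wide(path: Path, levels: list[str], get) -> None:
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["food"] + [f"{g}_{lv}" for g in genders for lv in levels])
            for food in foods:
                row: list[str] = [food]
                for g in genders:
                    res = results.get((g, food))
                    for lv in levels:
                        v = get(res, lv) if res is not None else None
                        row.append("" if v is None else f"{round(v, rounding):.{rounding}f}")
                w.writerow(row)

    age_labels = [a.label for a in AGE_GROUPS]
    period_labels = [str(p.year) for p in PERIODS]

    paths = {
        "age": out_dir / "age_effects.csv",
        "period": out_dir / "period_effects.csv",
        "cohort": out_dir / "cohort_effects.csv",
        "sidecar": out_dir / "effects_full.csv",
    }

    wide(paths["age"], age_labels,
         lambda r, lv: r.anchored.age_effects_vs_ref[age_labels.index(lv)])
    wide(paths["period"], period_labels,
         lambda r, lv: r.anchored.period_effects_vs_ref[period_labels.index(lv)])

    reported = [c.label for c in _reported_cohorts(results)]
    wide(paths["cohort"], reported,
         lambda r, lv: r.cohorts.by_label[lv].c_value if r.cohorts.by_label[lv].reported else None)

    with paths["sidecar"].open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gender", "food", "effect_type", "level", "value",
                    "n_cells", "reported", "converged", "iterations"])
        for (g, food), res in sorted(results.items()):
            d = res.decomposition
            meta = [d.converged, d.iterations]
            w.writerow([g, food, "grand", "", repr(d.grand), "", "", *meta])
            for a, v in zip(AGE_GROUPS, d.age_effects):
                w.writerow([g, food, "age_centered", a.label, repr(float(v)), "", "", *meta])
            for i, a in enumerate(AGE_GROUPS):
                w.writerow([g, food, "age_anchored", a.label,
                            repr(float(res.anchored.age_effects_vs_ref[i])), "", "", *meta])
            for p, v in zip(PERIODS, d.period_effects):
                w.writerow([g, food, "period_centered", p.year, repr(float(v)), "", "", *meta])
            for j, p in enumerate(PERIODS):
                w.writerow([g, food, "period_anchored", p.year,
                            repr(float(res.anchored.period_effects_vs_ref[j])), "", "", *meta])
            for ce in res.cohorts.effects:
                w.writerow([g, food, "cohort", ce.label, repr(ce.c_value),
                            ce.n_cells, ce.reported, *meta])
    return paths


def _reported_cohorts(results: Mapping):
    from .grid import COHORTS
    if not results:
        return [c for c in COHORTS if c.n_cells >= 2]
    first = next(iter(results.values()))
    return [cohortobj for cohortobj, ce in
            ((c, e) for c, e in zip(COHORTS, first.cohorts.effects)) if ce.reported]
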