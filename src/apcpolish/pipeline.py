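"""End-to-end orchestration: harmonize -> adjust -> tabulate -> polish -> report.

:func:`run_apc` is the one call that takes raw long-format records to
per-(gender, food) decompositions, cohort effects and anchored effects,
with every stage error tagged by the gender x food series it hit.
Defaults reproduce the reference analysis choices: mean polish, rice
halved in 2009, anchors at age 20-29 and year 1989, cohort window
1930-1979, unweighted residual averages, one-decimal reporting.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .grid import ANALYZED_FOOD_NAMES, food_group
from .polish import (AnchoredEffects, APCTable, CohortEffects,
                     EffectDecomposition, anchor, cohort_effects,
                     mean_polish, median_polish)
from .tables import (DEFAULT_RULES, Dialect, HarmonizationRule, LongRecord,
                     adjust_records, harmonize_food_coding, to_apc_table,
                     write_effect_tables)

log = logging.getLogger("apcpolish")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage and series context in its message."""


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of a pipeline run, defaulting to the reference choices."""

    polish: str = "mean"                       # "mean" or "median"
    anchor_age: str = "20-29"
    anchor_period: int = 1989
    cohort_window: tuple[int, int] = (1930, 1979)
    weights: str = "none"                      # "none" or "n_subjects"
    rounding: int = 1
    harmonization_rules: tuple[HarmonizationRule, ...] = DEFAULT_RULES
    harmonize: bool = True
    energy_unit: str = "kJ"
    delimiter: str = ","
    reference_energy_kj: float = 4186.0

    def __post_init__(self) -> None:
        if self.polish not in ("mean", "median"):
            raise ValueError("polish must be 'mean' or 'median'")
        if self.weights not in ("none", "n_subjects"):
            raise ValueError("weights must be 'none' or 'n_subjects'")

    def dialect(self) -> Dialect:
        return Dialect(delimiter=self.delimiter, energy_unit=self.energy_unit)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["harmonization_rules"] = [r.rule_id for r in self.harmonization_rules]
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "cohort_window" in data and not isinstance(data["cohort_window"], tuple):
            cw = data["cohort_window"]
            if isinstance(cw, str):
                lo, hi = cw.split(":")
                data["cohort_window"] = (int(lo), int(hi))
            else:
                data["cohort_window"] = tuple(int(v) for v in cw)
        if "harmonization_rules" in data:
            rules = []
            for r in data["harmonization_rules"]:
                if isinstance(r, HarmonizationRule):
                    rules.append(r)
                elif isinstance(r, str):
                    foodname, year, divisor = r.split("/")
                    rules.append(HarmonizationRule(foodname, int(year), float(divisor)))
                else:
                    rules.append(HarmonizationRule(r["food"], int(r["year"]),
                                                   float(r["divisor"])))
            data["harmonization_rules"] = tuple(rules)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class APCResult:
    """All outputs for one gender x food series."""

    table: APCTable
    decomposition: EffectDecomposition
    cohorts: CohortEffects
    anchored: AnchoredEffects


def run_apc(records: Sequence[LongRecord],
            config: RunConfig | None = None,
            genders: Sequence[str] | None = None,
            foods: Sequence[str] | None = None,
            ) -> tuple[dict[tuple[str, str], APCResult], list[str]]:
    """Run the full decomposition for every requested gender x food series.

    Records may be raw (g/day) or already energy-adjusted; harmonization
    is applied once unless disabled.  By default every analyzed food
    present in the records is processed for every gender present.
    Returns the results keyed by (gender, food name) and the
    harmonization audit log.
    """
    cfg = config or RunConfig()

    log.info("stage=harmonize rules=%d enabled=%s",
             len(cfg.harmonization_rules), cfg.harmonize)
    audit: list[str] = []
    if cfg.harmonize:
        records, audit = harmonize_food_coding(records, cfg.harmonization_rules)

    log.info("stage=adjust reference_energy_kj=%s", cfg.reference_energy_kj)
    records = adjust_records(records, cfg.reference_energy_kj)

    present_genders = sorted({r.gender for r in records})
    present_foods = {r.food.name for r in records}
    genders = list(genders) if genders else present_genders
    if foods:
        foods = [food_group(f).name for f in foods]
    else:
        foods = [f for f in ANALYZED_FOOD_NAMES if f in present_foods]

    polish_fn = mean_polish if cfg.polish == "mean" else median_polish
    results: dict[tuple[str, str], APCResult] = {}
    for gender in genders:
        for food in foods:
            ctx = f"({gender}, {food})"
            try:
                table = to_apc_table(records, gender, food)
                decomp = polish_fn(table)
                if not decomp.converged:
                    log.warning("stage=polish series=%s not converged after "
                                "%d iterations", ctx, decomp.iterations)
                cohorts = cohort_effects(decomp, window=cfg.cohort_window,
                                         weights=cfg.weights)
                anchored = anchor(decomp, cfg.anchor_age, cfg.anchor_period)
            except Exception as exc:
                raise PipelineError(f"series {ctx}: {exc}") from exc
            results[(gender, food)] = APCResult(table, decomp, cohorts, anchored)
    log.info("stage=polish series=%d method=%s", len(results), cfg.polish)
    return results, audit


def run_and_write(records: Sequence[LongRecord], out_dir: str | Path,
                  config: RunConfig | None = None,
                  **kwargs) -> dict[tuple[str, str], APCResult]:
    """:func:`run_apc` plus effect tables, sidecar and audit log on disk."""
    cfg = config or RunConfig()
    out_dir = Path(out_dir)
    results, audit = run_apc(records, cfg, **kwargs)
    paths = write_effect_tables(results, out_dir, rounding=cfg.rounding)
    audit_path = out_dir / "harmonization_audit.log"
    audit_path.write_text("".join(line + "\n" for line in audit))
    log.info("stage=write out=%s files=%d", out_dir, len(paths) + 1)
    return results
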