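"""Synthetic survey data with known age, period and cohort structure.

Real microdata behind the published survey tables is not distributable,
so every pipeline stage is exercised against generated inputs whose
truth is known by construction.  Two generators share one latent model

    latent(i, j) = grand + a_i + t_j + c(birth decade of cell i, j)

* :func:`make_cell_table` adds Gaussian cell-level noise to the latent
  values and emits them directly as cell means, with energy pinned to
  the 4,186 kJ reference so the adjustment step is the identity.
* :func:`make_microdata` instead draws per-subject records — gamma
  intakes (non-negative, right-skewed, as dietary intakes are) around
  an energy-proportional mean, normal energies truncated at a positive
  floor — and aggregates them to cell means, so sampling noise scales
  with 1/sqrt(n) as in a real survey.

Both are bit-reproducible given the spec's seed.  Default subject
counts per cell follow the published survey layout, which ranges from
25 to over 1,000 subjects per gender x age x year cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import published
from .energy import REFERENCE_ENERGY_KJ
from .grid import (AGE_GROUPS, ANALYZED_FOOD_NAMES, GENDERS, PERIODS,
                   birth_decade, food_group)
from .tables import LongRecord

_COHORT_STARTS = tuple(range(1920, 1990, 10))


@dataclass(frozen=True)
class MicrodataSpec:
    """Subject-level sampling model for :func:`make_microdata`.

    ``n_per_cell`` is an integer applied to every cell, or the string
    ``"nhns"`` for the published per-cell subject counts.  Subject
    intake is gamma with the given shape (default 4, coefficient of
    variation 0.5); subject energy is normal with a gender x age mean
    from the published tables, a relative spread ``energy_cv`` and a
    hard positive floor.
    """

    n_per_cell: int | str = "nhns"
    intake_gamma_shape: float = 4.0
    energy_cv: float = 0.2
    energy_floor_kj: float = 2000.0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_cell, int) and self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if isinstance(self.n_per_cell, str) and self.n_per_cell != "nhns":
            raise ValueError("n_per_cell must be an int or 'nhns'")
        if self.intake_gamma_shape <= 0:
            raise ValueError("intake_gamma_shape must be > 0")
        if not 0 <= self.energy_cv < 1:
            raise ValueError("energy_cv must be in [0, 1)")
        if self.energy_floor_kj <= 0:
            raise ValueError("energy_floor_kj must be > 0")

    def cell_n(self, gender: str, age_index: int, year: int) -> int:
        if isinstance(self.n_per_cell, int):
            return self.n_per_cell
        return published.N_SUBJECTS[year][gender][age_index - 1]


@dataclass(frozen=True)
class SynthSpec:
    """True effects, noise model and seed for one synthetic data set.

    Effects are in g per 4,186 kJ per day.  ``cohort_effects`` maps
    birth-decade start years (1920 ... 1980) to the interaction added
    along that diagonal; an empty map with ``noise_sd`` 0 gives an
    exactly additive table.  The same truth is used for every requested
    gender x food series; noise draws are independent across series.
    ``noise_sd`` defaults to 1 g/4,186 kJ/day, the order of a survey
    cell mean's standard error at a few hundred subjects.
    """

    grand: float = 100.0
    age_effects: tuple[float, ...] = (0.0,) * 5
    period_effects: tuple[float, ...] = (0.0,) * 3
    cohort_effects: Mapping[int, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0
    genders: tuple[str, ...] = GENDERS
    foods: tuple[str, ...] = ANALYZED_FOOD_NAMES
    microdata: MicrodataSpec | None = None

    def __post_init__(self) -> None:
        if len(self.age_effects) != len(AGE_GROUPS):
            raise ValueError(f"age_effects must have {len(AGE_GROUPS)} entries")
        if len(self.period_effects) != len(PERIODS):
            raise ValueError(f"period_effects must have {len(PERIODS)} entries")
        for start in self.cohort_effects:
            if start not in _COHORT_STARTS:
                raise ValueError(f"unknown birth decade {start}; "
                                 f"expected one of {_COHORT_STARTS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for g in self.genders:
            if g not in GENDERS:
                raise ValueError(f"unknown gender {g!r}")
        for f in self.foods:
            food_group(f)  # raises on unknown names

    def latent(self) -> np.ndarray:
        """The noise-free 5 x 3 latent table (g/4,186 kJ/day)."""
        out = np.empty((len(AGE_GROUPS), len(PERIODS)))
        for a in AGE_GROUPS:
            for p in PERIODS:
                c = self.cohort_effects.get(birth_decade(a, p), 0.0)
                out[a.index - 1, p.index - 1] = (
                    self.grand + self.age_effects[a.index - 1]
                    + self.period_effects[p.index - 1] + c)
        return out


@dataclass(frozen=True)
class SynthOutput:
    """Generated records plus the truth that produced them."""

    records: list[LongRecord]
    truth: SynthSpec
    latent: dict[tuple[str, str], np.ndarray]


def build_additive_table(grand: float, age_effects: Sequence[float],
                         period_effects: Sequence[float]) -> np.ndarray:
    """A zero-residual 5 x 3 table ``grand + age_effects[i] + period_effects[j]``.

    The effect vectors need not be centered — anchored rows work as-is;
    any non-zero means simply shift into the table's grand term.
    """
    a = np.asarray(age_effects, dtype=float)
    t = np.asarray(period_effects, dtype=float)
    if a.shape != (len(AGE_GROUPS),) or t.shape != (len(PERIODS),):
        raise ValueError("effect vectors must match the 5 x 3 grid")
    return grand + a[:, None] + t[None, :]


def _default_n(gender: str, age_index: int, year: int) -> int:
    return published.N_SUBJECTS[year][gender][age_index - 1]


def make_cell_table(spec: SynthSpec) -> SynthOutput:
    """Generate cell-mean records: latent value plus Gaussian cell noise.

    Energy is pinned at the 4,186 kJ reference so energy adjustment is
    the identity and the polished effects can be compared directly with
    the injected truth.  Subject counts follow the published survey
    layout.  Deterministic for a given spec (the seed covers all
    gender x food series).
    """
    rng = np.random.default_rng(spec.seed)
    latent = spec.latent()
    records: list[LongRecord] = []
    latents: dict[tuple[str, str], np.ndarray] = {}
    for gender in spec.genders:
        for food in spec.foods:
            latents[(gender, food)] = latent.copy()
            noise = rng.normal(0.0, spec.noise_sd, size=latent.shape) \
                if spec.noise_sd > 0 else np.zeros_like(latent)
            cells = latent + noise
            if np.any(cells < 0):
                raise ValueError(
                    f"negative generated intake for ({gender}, {food}); "
                    "raise the grand term or lower the noise")
            for a in AGE_GROUPS:
                for p in PERIODS:
                    records.append(LongRecord(
                        gender=gender, age_group=a, period=p,
                        food=food_group(food),
                        mean_intake=float(cells[a.index - 1, p.index - 1]),
                        mean_energy_kj=REFERENCE_ENERGY_KJ,
                        n_subjects=_default_n(gender, a.index, p.year),
                    ))
    return SynthOutput(records=records, truth=spec, latent=latents)


def make_microdata(spec: SynthSpec) -> SynthOutput:
    """Generate subject-level draws and aggregate them to cell means.

    For each cell the latent adjusted intake (plus optional cell noise)
    sets the target: a subject with energy E eats gamma-distributed
    grams with mean ``latent * E / 4186``, so the cell's ratio of mean
    intake to mean energy converges to the latent adjusted value as n
    grows.  Emitted records are unadjusted (g/day with varying energy),
    exercising the adjustment stage.
    """
    if spec.microdata is None:
        raise ValueError("spec.microdata must be set for make_microdata")
    md = spec.microdata
    rng = np.random.default_rng(spec.seed)
    latent = spec.latent()
    records: list[LongRecord] = []
    latents: dict[tuple[str, str], np.ndarray] = {}
    for gender in spec.genders:
        for food in spec.foods:
            latents[(gender, food)] = latent.copy()
            noise = rng.normal(0.0, spec.noise_sd, size=latent.shape) \
                if spec.noise_sd > 0 else np.zeros_like(latent)
            cells = latent + noise
            if np.any(cells < 0):
                raise ValueError(
                    f"negative latent intake for ({gender}, {food})")
            for a in AGE_GROUPS:
                for p in PERIODS:
                    n = md.cell_n(gender, a.index, p.year)
                    e_mean = published.ENERGY_KJ[gender][a.index - 1]
                    energies = rng.normal(e_mean, md.energy_cv * e_mean, size=n)
                    np.clip(energies, md.energy_floor_kj, None, out=energies)
                    target = cells[a.index - 1, p.index - 1]
                    means = target * energies / REFERENCE_ENERGY_KJ
                    if target > 0:
                        intakes = rng.gamma(md.intake_gamma_shape,
                                            means / md.intake_gamma_shape)
                    else:
                        intakes = np.zeros(n)
                    records.append(LongRecord(
                        gender=gender, age_group=a, period=p,
                        food=food_group(food),
                        mean_intake=float(intakes.mean()),
                        mean_energy_kj=float(energies.mean()),
                        n_subjects=n,
                    ))
    return SynthOutput(records=records, truth=spec, latent=latents)


def nhns_year_averaged_fixture() -> list[LongRecord]:
    """The published year-averaged survey marginals as records.

    A verbatim transcription of the gender- and age-stratified National
    Health and Nutrition Survey (Japan) intake table averaged over the
    1989/1999/2009 waves: 14 analyzed foods x 2 genders x 5 age groups,
    already energy-adjusted (g/4,186 kJ/day), with the year-averaged
    energy row and total subject counts.  Periods are collapsed, so the
    records carry ``period=None`` and ``year_averaged=True``: they feed
    marginal summaries but are rejected — by design — as input to the
    5 x 3 decomposition.
    """
    records = []
    for food, by_gender in published.YEAR_AVERAGED_INTAKE.items():
        for gender, values in by_gender.items():
            for a in AGE_GROUPS:
                i = a.index - 1
                n_total = sum(published.N_SUBJECTS[y][gender][i]
                              for y in published.PERIOD_YEARS)
                records.append(LongRecord(
                    gender=gender, age_group=a, period=None,
                    food=food_group(food),
                    mean_intake=values[i],
                    mean_energy_kj=published.ENERGY_KJ[gender][i],
                    n_subjects=n_total,
                    energy_adjusted=True,
                    year_averaged=True,
                ))
    return records


def nhns_subject_counts() -> dict[int, dict[str, tuple[int, ...]]]:
    """Published subjects per survey wave, keyed year -> gender -> 5 ages."""
    return {y: dict(g) for y, g in published.N_SUBJECTS.items()}
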