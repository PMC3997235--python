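"""The age x period grid and its birth-cohort diagonals.

The analysis grid is fixed by the published survey layout: five 10-year
age bands (20-29 ... 60-69) crossed with three survey years spaced 10
years apart (1989, 1999, 2009).  Because the age-band width equals the
survey spacing, people born in the same decade occupy a diagonal of the
grid; the 5 x 3 grid decomposes into 7 birth-decade cohorts (1920-29
through 1980-89) that partition its 15 cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class AgeGroup:
    """One 10-year age band, ordinal ``index`` 1..5."""

    index: int
    label: str = field(compare=False)
    lower_bound: int = field(compare=False)
    upper_bound: int = field(compare=False)

    def __post_init__(self) -> None:
        if self.lower_bound != 20 + 10 * (self.index - 1):
            raise ValueError(
                f"age group index {self.index} inconsistent with lower bound "
                f"{self.lower_bound}"
            )
        if self.upper_bound != self.lower_bound + 9:
            raise ValueError("age bands are 10 years wide")


@dataclass(frozen=True, order=True)
class Period:
    """One survey wave, ordinal ``index`` 1..3."""

    index: int
    year: int = field(compare=False)


AGE_GROUPS: tuple[AgeGroup, ...] = tuple(
    AgeGroup(i, f"{20 + 10 * (i - 1)}-{29 + 10 * (i - 1)}",
             20 + 10 * (i - 1), 29 + 10 * (i - 1))
    for i in range(1, 6)
)

PERIODS: tuple[Period, ...] = tuple(
    Period(j, 1989 + 10 * (j - 1)) for j in range(1, 4)
)

GENDERS: tuple[str, str] = ("men", "women")

N_AGE = len(AGE_GROUPS)
N_PERIOD = len(PERIODS)

_AGE_BY_LABEL = {a.label: a for a in AGE_GROUPS}
_PERIOD_BY_YEAR = {p.year: p for p in PERIODS}


def age_group(label: str | AgeGroup) -> AgeGroup:
    """Resolve an age-band label like ``"20-29"`` (en dashes accepted)."""
    if isinstance(label, AgeGroup):
        return label
    key = str(label).strip().replace("–", "-").replace("—", "-")
    try:
        return _AGE_BY_LABEL[key]
    except KeyError:
        raise KeyError(
            f"unknown age group {label!r}; expected one of "
            f"{sorted(_AGE_BY_LABEL)}"
        ) from None


def period(year: int | str | Period) -> Period:
    """Resolve a survey year (1989, 1999 or 2009)."""
    if isinstance(year, Period):
        return year
    try:
        return _PERIOD_BY_YEAR[int(year)]
    except (KeyError, ValueError):
        raise KeyError(
            f"unknown survey year {year!r}; expected one of "
            f"{sorted(_PERIOD_BY_YEAR)}"
        ) from None


@dataclass(frozen=True)
class Cohort:
    """A birth-decade cohort: the diagonal of (age, period) cells it occupies.

    ``birth_decade_start`` satisfies the closed form
    ``1960 - 10*(i - 1) + 10*(j - 1)`` for every member cell ``(i, j)``:
    someone aged 20-29 at the 1989 survey was born in 1960-1969, each
    step up in age shifts the decade back, each later survey shifts it
    forward.
    """

    birth_decade_start: int
    label: str
    cells: frozenset[tuple[AgeGroup, Period]]

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def birth_decade(age: AgeGroup | str, per: Period | int) -> int:
    """Birth-decade start year for one (age group, survey year) cell."""
    a, p = age_group(age), period(per)
    return 1960 - 10 * (a.index - 1) + 10 * (p.index - 1)


def all_cohorts() -> tuple[Cohort, ...]:
    """The 7 birth-decade cohorts partitioning the 5 x 3 grid, ascending."""
    by_start: dict[int, set[tuple[AgeGroup, Period]]] = {}
    for a in AGE_GROUPS:
        for p in PERIODS:
            by_start.setdefault(birth_decade(a, p), set()).add((a, p))
    return tuple(
        Cohort(start, f"{start}-{start + 9}", frozenset(cells))
        for start, cells in sorted(by_start.items())
    )


COHORTS: tuple[Cohort, ...] = all_cohorts()
_COHORT_BY_START = {c.birth_decade_start: c for c in COHORTS}


def cohort(start: int) -> Cohort:
    """Resolve a cohort by its birth-decade start year (1920 ... 1980)."""
    try:
        return _COHORT_BY_START[int(start)]
    except (KeyError, ValueError):
        raise KeyError(
            f"unknown birth decade {start!r}; expected one of "
            f"{sorted(_COHORT_BY_START)}"
        ) from None


# ---------------------------------------------------------------------------
# Food-group vocabulary.
#
# Fourteen groups carry the analysis: eleven staples with mean intake above
# 30 g/day plus three (confectionery, sugar, fats and oils) kept for their
# interpretive value.  Five low-intake groups and beverages are representable
# so input files mentioning them parse, but they are flagged non-analyzed and
# the pipeline skips them.

@dataclass(frozen=True)
class FoodGroup:
    name: str
    analyzed: bool


ANALYZED_FOOD_NAMES: tuple[str, ...] = (
    "rice",
    "wheat",
    "potatoes",
    "green yellow vegetables",
    "other vegetables",
    "fruits",
    "milk and dairy products",
    "meat",
    "fish",
    "egg",
    "beans",
    "confectionery",
    "sugar",
    "fats and oils",
)

EXCLUDED_FOOD_NAMES: tuple[str, ...] = (
    "nuts and seeds",
    "mushrooms",
    "algae",
    "seasonings and spices",
    "prepared foods",
    "beverages",
)

FOOD_GROUPS: tuple[FoodGroup, ...] = tuple(
    [FoodGroup(n, True) for n in ANALYZED_FOOD_NAMES]
    + [FoodGroup(n, False) for n in EXCLUDED_FOOD_NAMES]
)

# Aliases cover the comma style of the published tables and en dashes.
_FOOD_ALIASES = {
    "milk, dairy products": "milk and dairy products",
    "milk,dairy products": "milk and dairy products",
    "green-yellow vegetables": "green yellow vegetables",
}
_FOOD_BY_NAME = {f.name: f for f in FOOD_GROUPS}


def food_group(name: str | FoodGroup) -> FoodGroup:
    """Resolve a food-group name, tolerant of case and punctuation variants."""
    if isinstance(name, FoodGroup):
        return name
    key = " ".join(str(name).strip().lower().split())
    key = _FOOD_ALIASES.get(key, key)
    try:
        return _FOOD_BY_NAME[key]
    except KeyError:
        raise KeyError(f"unknown food group {name!r}") from None
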