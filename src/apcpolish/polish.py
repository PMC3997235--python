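"""Two-way polish of age x period tables and cohort-diagonal residual averages.

The model is additive: an energy-adjusted intake R_ij for age group i at
survey j is decomposed as

    R_ij = m + a_i + t_j + e_ij

with centered age effects a_i, centered period effects t_j and residuals
e_ij whose row and column means vanish.  A birth-cohort effect c(k) is
the average of the residuals over cohort k's diagonal cells: nonzero
residual structure along a diagonal is exactly an age x period
interaction attributable to that birth decade.  Because c(k) is a
residual it has no reference level — zero means no interaction.

On a complete table the mean polish fixed point coincides with the
closed-form two-way decomposition (row means, column means, grand mean),
so the iteration converges in at most two sweeps; the iterative form is
kept so the robust median variant shares the same engine.  The polish
is purely descriptive: no standard errors or significance tests are
attached to the effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import (AGE_GROUPS, COHORTS, PERIODS, AgeGroup, Cohort, FoodGroup,
                   Period, age_group, period)

#: Absolute convergence tolerance for the polish sweep adjustments.
DEFAULT_TOL = 1e-10
#: Mean polish converges in <= 2 sweeps; more iterations signal a bug.
DEFAULT_MAX_ITER_MEAN = 20
#: Median polish may need many sweeps on noisy tables.
DEFAULT_MAX_ITER_MEDIAN = 100


@dataclass(frozen=True)
class APCTable:
    """A complete 5 x 3 matrix of energy-adjusted intakes for one gender x food."""

    values: np.ndarray
    gender: str
    food: FoodGroup
    n_subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(AGE_GROUPS), len(PERIODS)):
            raise ValueError(f"table must be {len(AGE_GROUPS)} x {len(PERIODS)}, "
                             f"got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("table has non-finite cells")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class EffectDecomposition:
    """Grand term, centered effects and residuals of one polished table.

    ``grand + age_effects[i] + period_effects[j] + residuals[i, j]``
    reconstructs the input exactly; for the mean variant the effect
    vectors are centered and every residual row/column mean is zero.
    """

    grand: float
    age_effects: np.ndarray      # length 5, centered
    period_effects: np.ndarray   # length 3, centered
    residuals: np.ndarray        # 5 x 3
    iterations: int
    converged: bool
    method: str
    gender: str | None = None
    food: FoodGroup | None = None
    n_subjects: np.ndarray | None = None

    def fitted(self) -> np.ndarray:
        return (self.grand + self.age_effects[:, None]
                + self.period_effects[None, :])

    def reconstruction(self) -> np.ndarray:
        return self.fitted() + self.residuals


@dataclass(frozen=True)
class CohortEffect:
    """One birth decade's residual average."""

    birth_decade_start: int
    label: str
    c_value: float
    n_cells: int
    reported: bool


@dataclass(frozen=True)
class CohortEffects:
    """All 7 cohort residual averages, ascending by birth decade."""

    effects: tuple[CohortEffect, ...]
    window: tuple[int, int]
    weights: str

    @property
    def by_label(self) -> dict[str, CohortEffect]:
        return {e.label: e for e in self.effects}

    @property
    def by_start(self) -> dict[int, CohortEffect]:
        return {e.birth_decade_start: e for e in self.effects}

    def reported_values(self) -> dict[str, float]:
        return {e.label: e.c_value for e in self.effects if e.reported}


@dataclass(frozen=True)
class AnchoredEffects:
    """Effects re-expressed against a reference age group and period.

    The reference entries are exactly zero and pairwise differences are
    those of the centered effects.  Cohort effects are never anchored:
    as residual averages they have no reference level.
    """

    age_effects_vs_ref: np.ndarray
    period_effects_vs_ref: np.ndarray
    ref_age: AgeGroup
    ref_period: Period


def _polish(values: np.ndarray, center, max_iter: int, tol: float):
    """Shared polish engine; ``center`` is np.mean or np.median over an axis."""
    r = values.astype(float).copy()
    grand = float(center(r, axis=None))
    r -= grand
    a = np.zeros(r.shape[0])
    t = np.zeros(r.shape[1])
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        delta = 0.0

        row = center(r, axis=1)
        a += row
        r -= row[:, None]
        delta = max(delta, float(np.max(np.abs(row))))
        shift = float(center(a, axis=None))
        grand += shift
        a -= shift

        col = center(r, axis=0)
        t += col
        r -= col[None, :]
        delta = max(delta, float(np.max(np.abs(col))))
        shift = float(center(t, axis=None))
        grand += shift
        t -= shift

        if delta <= tol:
            converged = True
            break
    return grand, a, t, r, iterations, converged


def mean_polish(table: APCTable, max_iter: int = DEFAULT_MAX_ITER_MEAN,
                tol: float = DEFAULT_TOL) -> EffectDecomposition:
    """Decompose a complete table into grand + age + period effects + residuals.

    Sweeps row (age) means then column (period) means out of the table,
    folding the mean of each effect vector back into the grand term,
    until the largest adjustment in a full sweep falls below ``tol``.
    The fixed point equals the closed-form two-way decomposition
    (a_i = row mean - grand, t_j = column mean - grand), so two sweeps
    suffice; non-convergence is flagged, not fatal.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    grand, a, t, r, iterations, converged = _polish(
        table.values, np.mean, max_iter, tol)
    return EffectDecomposition(grand, a, t, r, iterations, converged,
                               method="mean", gender=table.gender,
                               food=table.food, n_subjects=table.n_subjects)


def median_polish(table: APCTable, max_iter: int = DEFAULT_MAX_ITER_MEDIAN,
                  tol: float = DEFAULT_TOL) -> EffectDecomposition:
    """Robust variant of :func:`mean_polish` sweeping medians.

    Resistant to single aberrant cells, which stay concentrated in their
    own residual instead of leaking into row and column effects.  Unlike
    the mean variant there is no two-sweep guarantee, and residual row
    and column medians (not means) tend to zero.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    grand, a, t, r, iterations, converged = _polish(
        table.values, np.median, max_iter, tol)
    return EffectDecomposition(grand, a, t, r, iterations, converged,
                               method="median", gender=table.gender,
                               food=table.food, n_subjects=table.n_subjects)


DEFAULT_COHORT_WINDOW: tuple[int, int] = (1930, 1979)


def cohort_effects(decomp: EffectDecomposition,
                   window: tuple[int, int] = DEFAULT_COHORT_WINDOW,
                   weights: str = "none") -> CohortEffects:
    """Average the residuals along each of the 7 birth-decade diagonals.

    Every cell participates regardless of the reporting window; the
    ``reported`` flag marks cohorts whose birth decade starts inside
    ``window`` (default 1930-1979, the five cohorts observed in at
    least two cells).  The corner cohorts (1920-29, 1980-89) rest on a
    single cell each, so their "average" is one residual — computed,
    flagged unreported by default.

    ``weights='n_subjects'`` averages residuals weighted by cell subject
    counts instead of the default unweighted mean.
    """
    if weights not in ("none", "n_subjects"):
        raise ValueError("weights must be 'none' or 'n_subjects'")
    if weights == "n_subjects" and decomp.n_subjects is None:
        raise ValueError("weights='n_subjects' requires subject counts on the table")
    lo, hi = window
    effects = []
    for c in COHORTS:
        idx = [(a.index - 1, p.index - 1) for a, p in c.cells]
        vals = np.array([decomp.residuals[i, j] for i, j in idx])
        if weights == "none":
            value = float(vals.mean())
        else:
            w = np.array([decomp.n_subjects[i, j] for i, j in idx], dtype=float)
            value = float(np.average(vals, weights=w))
        effects.append(CohortEffect(
            birth_decade_start=c.birth_decade_start, label=c.label,
            c_value=value, n_cells=c.n_cells,
            reported=lo <= c.birth_decade_start <= hi,
        ))
    return CohortEffects(tuple(effects), window=(lo, hi), weights=weights)


def anchor(decomp: EffectDecomposition,
           ref_age: str | AgeGroup = "20-29",
           ref_period: int | Period = 1989) -> AnchoredEffects:
    """Re-express effects as differences from a reference level.

    The reference age group and period get exactly 0; every other entry
    is its centered effect minus the reference's.  Anchoring is a pure
    re-parameterization: fitted cell values are unchanged once the
    reference effects are folded into the offset.
    """
    ra = age_group(ref_age)
    rp = period(ref_period)
    a = decomp.age_effects - decomp.age_effects[ra.index - 1]
    t = decomp.period_effects - decomp.period_effects[rp.index - 1]
    a[ra.index - 1] = 0.0  # exact zero, not -0.0 epsilon
    t[rp.index - 1] = 0.0
    return AnchoredEffects(a, t, ref_age=ra, ref_period=rp)
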