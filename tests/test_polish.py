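"""Polish engine: oracle equivalence, invariants, cohorts, anchoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from apcpolish import (AGE_GROUPS, COHORTS, PERIODS, APCTable, anchor,
                       build_additive_table, cohort_effects, food_group,
                       mean_polish, median_polish)
from apcpolish.polish import EffectDecomposition
from apcpolish.published import AGE_EFFECTS, PERIOD_EFFECTS

from conftest import closed_form_decomposition


def table_of(values, gender="men", food="meat", n=None):
    return APCTable(np.asarray(values, dtype=float), gender,
                    food_group(food), n_subjects=n)


table_values = arrays(np.float64, (5, 3),
                      elements=st.floats(0, 500, allow_nan=False,
                                         allow_infinity=False))


class TestMeanPolish:
    def test_constant_table_gives_pure_grand(self):
        d = mean_polish(table_of(np.full((5, 3), 7.0)))
        assert d.grand == pytest.approx(7.0)
        np.testing.assert_allclose(d.age_effects, 0, atol=1e-12)
        np.testing.assert_allclose(d.period_effects, 0, atol=1e-12)
        np.testing.assert_allclose(d.residuals, 0, atol=1e-12)
        assert d.converged

    @pytest.mark.parametrize("gender", ["men", "women"])
    def test_additive_table_recovers_published_meat_profile(self, gender):
        # A zero-residual table built from the published anchored meat
        # rows must polish back to exactly those effects after anchoring.
        age_row = AGE_EFFECTS["meat"][gender]
        period_row = PERIOD_EFFECTS["meat"][gender]
        d = mean_polish(table_of(build_additive_table(100.0, age_row, period_row),
                                 gender=gender))
        anc = anchor(d)
        np.testing.assert_allclose(anc.age_effects_vs_ref, age_row, atol=1e-9)
        np.testing.assert_allclose(anc.period_effects_vs_ref, period_row, atol=1e-9)
        np.testing.assert_allclose(d.residuals, 0, atol=1e-9)

    @settings(deadline=None, max_examples=200)
    @given(table_values)
    def test_matches_closed_form_oracle(self, values):
        d = mean_polish(table_of(values))
        grand, a, t, resid = closed_form_decomposition(values)
        assert d.grand == pytest.approx(grand, abs=1e-10)
        np.testing.assert_allclose(d.age_effects, a, atol=1e-10)
        np.testing.assert_allclose(d.period_effects, t, atol=1e-10)
        np.testing.assert_allclose(d.residuals, resid, atol=1e-10)

    @settings(deadline=None, max_examples=100)
    @given(table_values)
    def test_zero_sum_and_reconstruction(self, values):
        d = mean_polish(table_of(values))
        assert abs(d.age_effects.sum()) < 1e-9
        assert abs(d.period_effects.sum()) < 1e-9
        np.testing.assert_allclose(d.residuals.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(d.residuals.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(d.reconstruction(), values, atol=1e-9)

    def test_converges_within_two_sweeps(self, random_table):
        for seed in range(10):
            d = mean_polish(random_table(seed))
            assert d.converged and d.iterations <= 3

    def test_sweep_order_does_not_change_the_fixed_point(self, random_table):
        # Sweeping columns first is sweeping rows first on the transpose;
        # the fixed point must be identical either way.
        from apcpolish.polish import _polish
        t = random_table(3)
        d_rows = mean_polish(t)
        grand_c, t_eff, a_eff, resid_c, _, _ = _polish(t.values.T, np.mean, 20, 1e-10)
        assert d_rows.grand == pytest.approx(grand_c, abs=1e-10)
        np.testing.assert_allclose(d_rows.age_effects, a_eff, atol=1e-10)
        np.testing.assert_allclose(d_rows.period_effects, t_eff, atol=1e-10)
        np.testing.assert_allclose(d_rows.residuals, resid_c.T, atol=1e-10)

    def test_constant_shift_moves_only_the_grand_term(self, random_table):
        t = random_table(5)
        d0 = mean_polish(t)
        d1 = mean_polish(table_of(t.values + 42.0))
        assert d1.grand == pytest.approx(d0.grand + 42.0, abs=1e-9)
        np.testing.assert_allclose(d1.age_effects, d0.age_effects, atol=1e-9)
        np.testing.assert_allclose(d1.period_effects, d0.period_effects, atol=1e-9)
        np.testing.assert_allclose(d1.residuals, d0.residuals, atol=1e-9)

    def test_non_finite_table_fatal(self):
        values = np.full((5, 3), 1.0)
        values[0, 0] = np.nan
        with pytest.raises(ValueError):
            table_of(values)


class TestMedianPolish:
    def test_constant_table_all_zero_effects(self):
        d = median_polish(table_of(np.full((5, 3), 7.0)))
        assert d.grand == pytest.approx(7.0)
        np.testing.assert_allclose(d.residuals, 0, atol=1e-12)

    def test_exact_on_additive_tables(self):
        values = build_additive_table(50.0, (0, -3.3, -9.3, -13.5, -22.2),
                                      (0, 9.4, 17.6))
        d = median_polish(table_of(values))
        anc = anchor(d)
        np.testing.assert_allclose(anc.age_effects_vs_ref,
                                   (0, -3.3, -9.3, -13.5, -22.2), atol=1e-9)

    def test_outlier_stays_concentrated_in_its_own_residual(self):
        values = build_additive_table(100.0, (0, 2, 4, 6, 8), (0, 5, 10))
        values[2, 1] += 100.0
        dm = mean_polish(table_of(values))
        dd = median_polish(table_of(values))
        def concentration(d):
            r = np.abs(d.residuals)
            return r[2, 1] / r.sum()
        assert concentration(dd) > concentration(dm)
        assert np.abs(dd.residuals[2, 1]) > np.abs(dm.residuals[2, 1])
        np.testing.assert_allclose(dd.reconstruction(), values, atol=1e-8)


def decomp_with_residuals(residuals, n=None):
    residuals = np.asarray(residuals, dtype=float)
    return EffectDecomposition(
        grand=0.0, age_effects=np.zeros(5), period_effects=np.zeros(3),
        residuals=residuals, iterations=2, converged=True, method="mean",
        gender="men", food=food_group("meat"),
        n_subjects=None if n is None else np.asarray(n))


class TestCohortEffects:
    def test_zero_residuals_give_zero_cohorts(self):
        ce = cohort_effects(decomp_with_residuals(np.zeros((5, 3))))
        assert all(e.c_value == 0 for e in ce.effects)

    def test_direct_averaging_over_a_single_diagonal(self):
        # +3 on the two cells of the 1930s diagonal: age 50-59 in 1989
        # and age 60-69 in 1999.
        r = np.zeros((5, 3))
        r[3, 0] = 3.0
        r[4, 1] = 3.0
        ce = cohort_effects(decomp_with_residuals(r))
        assert ce.by_start[1930].c_value == pytest.approx(3.0)
        for start, e in ce.by_start.items():
            if start != 1930:
                assert e.c_value == 0.0

    def test_hand_enumerated_diagonal_means(self):
        r = np.arange(15, dtype=float).reshape(5, 3)
        ce = cohort_effects(decomp_with_residuals(r))
        # Hand enumeration: cell (i, j) (0-based) has residual 3i + j and
        # lies on diagonal 1960 - 10i + 10j.
        expected = {
            1920: [12], 1930: [9, 13], 1940: [6, 10, 14],
            1950: [3, 7, 11], 1960: [0, 4, 8], 1970: [1, 5], 1980: [2],
        }
        for start, cells in expected.items():
            assert ce.by_start[start].c_value == pytest.approx(np.mean(cells))
            assert ce.by_start[start].n_cells == len(cells)

    def test_reported_window_is_the_five_multi_cell_cohorts(self):
        ce = cohort_effects(decomp_with_residuals(np.zeros((5, 3))))
        reported = [e.birth_decade_start for e in ce.effects if e.reported]
        assert reported == [1930, 1940, 1950, 1960, 1970]
        assert all(e.n_cells >= 2 for e in ce.effects if e.reported)
        assert all(e.n_cells == 1 for e in ce.effects if not e.reported)

    @pytest.mark.parametrize("seed", range(5))
    def test_cell_weighted_mean_of_all_cohorts_closes_to_zero(self, random_table, seed):
        d = mean_polish(random_table(seed))
        ce = cohort_effects(d)
        total = sum(e.n_cells * e.c_value for e in ce.effects)
        assert abs(total) < 1e-9

    def test_subject_weighted_averaging_mode(self):
        r = np.zeros((5, 3))
        r[3, 0] = 1.0
        r[4, 1] = 3.0
        n = np.ones((5, 3), dtype=int)
        n[3, 0] = 30
        n[4, 1] = 10
        ce = cohort_effects(decomp_with_residuals(r, n=n), weights="n_subjects")
        assert ce.by_start[1930].c_value == pytest.approx((30 * 1 + 10 * 3) / 40)


class TestAnchor:
    def test_reference_levels_exactly_zero(self, random_table):
        anc = anchor(mean_polish(random_table(1)))
        assert anc.age_effects_vs_ref[0] == 0.0
        assert anc.period_effects_vs_ref[0] == 0.0

    def test_pairwise_differences_preserved(self, random_table):
        d = mean_polish(random_table(2))
        anc = anchor(d, ref_age="40-49", ref_period=1999)
        for vec_anc, vec_cent in [(anc.age_effects_vs_ref, d.age_effects),
                                  (anc.period_effects_vs_ref, d.period_effects)]:
            diffs_anc = np.subtract.outer(vec_anc, vec_anc)
            diffs_cent = np.subtract.outer(vec_cent, vec_cent)
            np.testing.assert_allclose(diffs_anc, diffs_cent, atol=1e-12)

    def test_anchoring_preserves_fitted_values(self, random_table):
        d = mean_polish(random_table(4))
        anc = anchor(d)
        offset = d.grand + d.age_effects[0] + d.period_effects[0]
        refit = (offset + anc.age_effects_vs_ref[:, None]
                 + anc.period_effects_vs_ref[None, :])
        np.testing.assert_allclose(refit, d.fitted(), atol=1e-9)

    def test_idempotent_at_the_same_reference(self, random_table):
        d = mean_polish(random_table(6))
        once = anchor(d)
        # re-anchoring the anchored vectors subtracts an exact zero
        again_age = once.age_effects_vs_ref - once.age_effects_vs_ref[0]
        np.testing.assert_array_equal(again_age, once.age_effects_vs_ref)

    def test_published_centered_meat_value_anchors_to_printed_row(self):
        # The centered men's meat age effect at 20-29 is +9.66 (the mean
        # of the anchored row is -9.66); anchoring restores the row.
        age_row = np.array(AGE_EFFECTS["meat"]["men"])
        d = mean_polish(table_of(build_additive_table(
            100.0, age_row, PERIOD_EFFECTS["meat"]["men"])))
        assert d.age_effects[0] == pytest.approx(-age_row.mean(), abs=1e-9)
        anc = anchor(d)
        np.testing.assert_allclose(anc.age_effects_vs_ref, age_row, atol=1e-9)

    def test_unknown_reference_fatal(self, random_table):
        d = mean_polish(random_table(8))
        with pytest.raises(KeyError):
            anchor(d, ref_age="70-79")

    def test_cohort_values_are_never_anchored(self, random_table):
        # Cohort effects are residual averages without a reference level:
        # anchoring the decomposition must leave them untouched.
        d = mean_polish(random_table(9))
        before = [e.c_value for e in cohort_effects(d).effects]
        anchor(d)
        after = [e.c_value for e in cohort_effects(d).effects]
        assert before == after
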