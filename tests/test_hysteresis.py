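"""Hysteresis decomposition, Spearman, Fitness Index and quintile selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oleohyst import (
    default_cultivars,
    fit_and_integrate,
    fitness_index,
    generate_season,
    hyst_index,
    rotate_arm,
    select_predictors,
    spearman,
    turning_point,
)
from oleohyst.errors import ParameterError, SelectionError


def brute_force_hyst(ci, oil):
    """Independent reference: explicit rotation + trapezoid on raw points."""
    ci = np.asarray(ci, float)
    oil = np.asarray(oil, float)
    turn = max(range(len(ci)), key=lambda i: (ci[i], -i))  # first argmax
    ci_max = ci[turn]
    x = ci.copy()
    x[turn + 1 :] = ci_max + (ci_max - ci[turn + 1 :])
    order = np.argsort(x)
    xs, ys = x[order], np.clip(oil[order], 0, None)
    tot = np.trapezoid(ys, xs)
    hi = xs[-1]
    if hi <= ci_max:
        hyst_area = 0.0
    else:
        grid = np.linspace(ci_max, hi, 2048)
        hyst_area = np.trapezoid(np.interp(grid, xs, ys), grid)
    return (hyst_area - (tot - hyst_area)) / tot


class TestTurningPoint:
    @pytest.mark.parametrize(
        "ci,expected",
        [([1, 2, 3, 4], 3), ([1, 4, 3, 2], 1), ([1, 4, 4, 2], 1)],
    )
    def test_first_occurrence_of_maximum(self, ci, expected):
        assert turning_point(ci) == expected
        # brute-force argmax-first oracle
        assert turning_point(ci) == min(i for i, v in enumerate(ci) if v == max(ci))


class TestRotateArm:
    def test_fixed_point(self):
        assert rotate_arm([200.0], 200.0)[0] == 200.0

    def test_substitution(self):
        assert rotate_arm([150.0], 200.0)[0] == 250.0

    def test_involution(self, rng):
        vals = rng.uniform(0, 100, 20)
        twice = 2 * 100.0 - rotate_arm(vals, 100.0)
        assert twice == pytest.approx(vals)

    def test_values_above_max_rejected(self):
        with pytest.raises(ParameterError):
            rotate_arm([201.0], 200.0)


class TestFitAndIntegrate:
    def test_constant_rectangle(self):
        x = np.linspace(0, 1, 12)
        assert fit_and_integrate(x, np.full(12, 10.0), 0, 1) == pytest.approx(10, abs=1e-6)

    def test_linear_triangle(self):
        x = np.linspace(0, 2, 12)
        assert fit_and_integrate(x, x, 0, 2) == pytest.approx(2, abs=1e-3)

    def test_spline_close_to_raw_trapezoid_oracle(self, rng):
        x = np.sort(rng.uniform(0, 10, 40))
        y = 5 + 0.8 * x + rng.normal(0, 0.05, 40)
        spline_area = fit_and_integrate(x, y, x[0], x[-1])
        raw = np.trapezoid(y, x)
        assert spline_area == pytest.approx(raw, rel=0.05)

    def test_degenerate_span_is_zero(self):
        x = np.linspace(0, 1, 10)
        assert fit_and_integrate(x, x, 0.5, 0.5) == 0.0


class TestHystIndex:
    def test_monotone_increasing_ci_gives_exactly_minus_one(self):
        oil = np.linspace(5, 15, 12)
        ci = np.linspace(100, 180, 12)
        dec = hyst_index(ci, oil)
        assert dec.hyst == -1.0
        assert dec.hyst_area == 0.0

    def test_mirror_arms_give_zero(self):
        # downward arm mirrors the upward arm over constant oil: the
        # reflected half carries exactly half of the total area
        ci = [0, 1, 2, 1, 0]
        oil = [3, 3, 3, 3, 3]
        assert hyst_index(ci, oil, spline=False).hyst == pytest.approx(0.0, abs=1e-12)

    def test_piecewise_linear_toy_pinned_against_brute_force(self):
        ci = [0, 1, 2, 1, 0]
        oil = [1, 2, 3, 4, 5]
        dec = hyst_index(ci, oil, spline=False)
        assert dec.hyst == pytest.approx(brute_force_hyst(ci, oil), abs=1e-9)
        assert dec.hyst == pytest.approx(1 / 3, abs=1e-9)  # regression value
        assert dec.tot_area == pytest.approx(12.0, abs=1e-6)
        assert dec.hyst_area == pytest.approx(8.0, abs=1e-6)

    def test_spline_agrees_with_brute_force_on_smooth_data(self):
        p = default_cultivars()[0].with_(noise_oil=0.05, noise_band=(0.2, 0.2, 0.2))
        t = generate_season(p, seed=11)
        dec_spline = hyst_index(t.green, t.oil, spline=True)
        dec_brute = brute_force_hyst(t.green.to_numpy(), t.oil.to_numpy())
        assert dec_spline.hyst == pytest.approx(dec_brute, abs=0.05)

    def test_too_short_trajectory_raises(self):
        with pytest.raises(ParameterError):
            hyst_index([1, 2, 3], [1, 2, 3])

    def test_bounded_on_random_trajectories(self, rng):
        for _ in range(200):
            n = rng.integers(5, 40)
            ci = rng.uniform(0, 255, n)
            oil = np.sort(rng.uniform(1, 25, n))
            dec = hyst_index(ci, oil)
            assert 0 <= dec.hyst_area <= dec.tot_area + 1e-9
            assert -1 <= dec.hyst <= 1

    def test_invariance_to_affine_ci_and_oil_scaling(self):
        p = default_cultivars()[2]
        t = generate_season(p, seed=5)
        base = hyst_index(t.green, t.oil).hyst
        scaled_ci = hyst_index(3.7 * t.green + 12.0, t.oil).hyst
        scaled_oil = hyst_index(t.green, 2.5 * t.oil).hyst
        assert scaled_ci == pytest.approx(base, abs=1e-9)
        assert scaled_oil == pytest.approx(base, abs=1e-6)

    def test_earlier_fall_onset_never_decreases_hyst(self):
        p = default_cultivars()[0].with_(noise_oil=0.0, noise_band=(0.0, 0.0, 0.0))
        hysts = []
        for onset in [30.0, 12.0, 9.0, 6.0, 3.0]:
            t = generate_season(p.with_(band_fall_onset=onset), seed=0)
            hysts.append(hyst_index(t.green, t.oil).hyst)
        assert hysts[0] == -1.0  # onset beyond season: no loop at all
        for earlier, later in zip(hysts[1:], hysts[:-1]):
            assert earlier >= later - 0.02


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10, dtype=float)
        assert spearman(x, 2 * x + 1) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_ties_match_hand_expanded_ranks(self):
        # ranks of x=[1,2,2,3] -> [1, 2.5, 2.5, 4]; y=[1,3,2,4] -> [1,3,2,4]
        expected = np.corrcoef([1, 2.5, 2.5, 4], [1, 3, 2, 4])[0, 1]
        assert spearman([1, 2, 2, 3], [1, 3, 2, 4]) == pytest.approx(expected)
        assert expected == pytest.approx(3 / np.sqrt(10))

    def test_constant_vector_undefined(self):
        assert np.isnan(spearman([1, 1, 1, 1], [1, 2, 3, 4]))


class TestFitnessIndex:
    def test_substitution(self):
        assert fitness_index(-1.0, -0.94) == pytest.approx(1.94)
        assert fitness_index(0.0, 0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            fitness_index(1.5, 0.0)

    def test_bounded_on_suite(self, suite_result):
        fi = suite_result.selection.fi.dropna()
        assert ((fi >= 0) & (fi <= 2)).all()


class TestSelectPredictors:
    def test_35_distinct_fis_select_7(self, rng):
        records = pd.DataFrame({"ci_name": [f"c{i}" for i in range(35)],
                                "fi": rng.permutation(np.linspace(0.1, 1.9, 35))})
        out = select_predictors(records)
        assert out.selected.sum() == 7
        # sort-and-slice oracle: the selected are exactly the top 7 by FI
        top = set(records.nlargest(7, "fi").ci_name)
        assert set(out.query("selected").ci_name) == top

    def test_38_distinct_fis_select_8(self, rng):
        records = pd.DataFrame({"ci_name": [f"c{i}" for i in range(38)],
                                "fi": rng.permutation(np.linspace(0.1, 1.9, 38))})
        assert select_predictors(records).selected.sum() == 8

    def test_all_equal_all_selected(self):
        records = pd.DataFrame({"ci_name": list("abcde"), "fi": [1.0] * 5})
        assert select_predictors(records).selected.all()

    def test_undefined_fi_excluded(self):
        records = pd.DataFrame({"ci_name": list("abcdef"),
                                "fi": [np.nan, 0.5, 1.0, 1.5, 1.8, 1.9]})
        out = select_predictors(records)
        assert not out.selected.iloc[0]
        assert out.selected.sum() >= 1

    def test_all_undefined_raises(self):
        records = pd.DataFrame({"ci_name": list("abcde"), "fi": [np.nan] * 5})
        with pytest.raises(SelectionError):
            select_predictors(records)


class TestSuiteConcordance:
    def test_high_rho_cooccurs_with_extreme_hyst(self, suite_result):
        """Strong rank correlation goes with Hyst near +/-1 across the suite."""
        sel = suite_result.selection.dropna(subset=["hyst", "rho"])
        r = spearman(sel.rho.abs().to_numpy(), sel.hyst.abs().to_numpy())
        assert r > 0
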