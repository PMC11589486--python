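"""Benchmark splits, OLS fits, VIF reduction and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from oleohyst import (
    evaluate,
    fit_linear,
    make_splits,
    reduce_by_vif,
    run_model_suite,
    vif,
)
from oleohyst.errors import ParameterError, RankDeficiencyError

# three-band coefficients used as generator truth (intercept, R, G, B)
TRUTH = (2.71, 0.28, -0.25, 0.15)


def make_design(n, rng):
    return pd.DataFrame({
        "red": rng.uniform(60, 180, n),
        "green": rng.uniform(60, 180, n),
        "blue": rng.uniform(40, 120, n),
    })


def linear_oil(design, noise=0.0, rng=None):
    a, br, bg, bb = TRUTH
    y = a + br * design.red + bg * design.green + bb * design.blue
    if noise and rng is not None:
        y = y + rng.normal(0, noise, len(design))
    return y


class TestMakeSplits:
    def test_70_30_sizes(self):
        plan = make_splits(40, seed=0)
        assert plan.assignments.shape == (5, 40)
        assert (plan.assignments.sum(axis=1) == 28).all()

    def test_round_half_even_at_45(self):
        # 0.7 * 45 = 31.5 -> round-half-even gives 32 despite float error
        plan = make_splits(45, seed=0)
        assert plan.n_train == 32
        assert (~plan.assignments[0]).sum() == 13

    def test_deterministic_given_seed(self):
        a = make_splits(45, seed=7)
        b = make_splits(45, seed=7)
        assert (a.assignments == b.assignments).all()
        assert not (a.assignments == make_splits(45, seed=8).assignments).all()

    def test_too_small_n_rejected(self):
        with pytest.raises(ParameterError):
            make_splits(9, seed=0)


class TestFitLinear:
    def test_noiseless_three_band_recovery(self, rng):
        design = make_design(45, rng)
        fit = fit_linear(linear_oil(design), design)
        assert fit.coefficients["Intercept"] == pytest.approx(TRUTH[0], abs=1e-8)
        assert fit.coefficients["red"] == pytest.approx(TRUTH[1], abs=1e-8)
        assert fit.coefficients["green"] == pytest.approx(TRUTH[2], abs=1e-8)
        assert fit.coefficients["blue"] == pytest.approx(TRUTH[3], abs=1e-8)
        assert set(fit.vif) == {"red", "green", "blue"}

    def test_constant_response_gives_zero_slopes(self, rng):
        design = make_design(30, rng)
        fit = fit_linear(np.full(30, 8.0), design)
        for name in ("red", "green", "blue"):
            assert fit.coefficients[name] == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_predictor_raises_rank_error(self, rng):
        design = make_design(30, rng)
        design["red2"] = design["red"]
        with pytest.raises(RankDeficiencyError, match="red2"):
            fit_linear(linear_oil(design[["red", "green", "blue"]]), design)

    def test_single_predictor_has_no_vif(self, rng):
        design = make_design(30, rng)[["red"]]
        fit = fit_linear(design.red * 0.1 + 3, design)
        assert fit.vif == {}


class TestVif:
    def test_orthogonal_predictors_unity(self):
        n = 400
        x = np.tile([1.0, -1.0], n // 2)
        z = np.repeat([1.0, -1.0], n // 2)
        vals = vif(pd.DataFrame({"x": x, "z": z}))
        assert vals["x"] == pytest.approx(1.0, abs=1e-9)
        assert vals["z"] == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_two_predictors(self, rng):
        # VIF = 1 / (1 - r^2) for a two-column design
        x = rng.normal(size=600)
        z = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=600)
        design = pd.DataFrame({"x": x, "z": z})
        r = np.corrcoef(x, z)[0, 1]
        expected = 1.0 / (1.0 - r**2)
        vals = vif(design)
        assert vals["x"] == pytest.approx(expected, abs=1e-9)
        assert vals["z"] == pytest.approx(expected, abs=1e-9)
        # r = 0.9 exactly would give ~5.263
        assert 1.0 / (1.0 - 0.9**2) == pytest.approx(5.263, abs=1e-3)

    def test_perfect_collinearity_reports_infinity(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        design = pd.DataFrame({"x": x, "z": z, "s": x + z})
        assert np.isinf(vif(design)["s"])

    def test_constant_column_undefined(self, rng):
        design = pd.DataFrame({"x": rng.normal(size=30), "c": np.ones(30)})
        assert np.isnan(vif(design)["c"])


class TestReduceByVif:
    def test_low_vif_set_retained(self, rng):
        design = make_design(200, rng)
        retained, removed = reduce_by_vif(design)
        assert retained == ["red", "green", "blue"]
        assert removed == []

    def test_red_green_collinear_drops_red(self, rng):
        # red nearly duplicates green (the collinear-band pattern): red has
        # the highest VIF and is dropped first, leaving green + blue
        green = rng.uniform(60, 180, 300)
        red = green * 1.1 + rng.normal(0, 1.0, 300)
        blue = rng.uniform(40, 120, 300)
        design = pd.DataFrame({"red": red, "green": green, "blue": blue})
        retained, removed = reduce_by_vif(design)
        assert [n for n, _ in removed][0] in {"red", "green"}
        assert retained[-1] == "blue" or "blue" in retained
        assert len(retained) == 2

    def test_two_perfectly_collinear_keep_exactly_one(self, rng):
        x = rng.normal(size=50)
        design = pd.DataFrame({"a": x, "b": 2 * x})
        retained, removed = reduce_by_vif(design)
        assert len(retained) == 1
        assert len(removed) == 1


class TestEvaluate:
    def _fit(self, rng, noise=0.0):
        design = make_design(45, rng)
        y = linear_oil(design, noise=noise, rng=rng)
        table = design.assign(oil=y)
        return fit_linear(y, design), table

    def test_perfect_predictions(self, rng):
        fit, table = self._fit(rng)
        m = evaluate(fit, table)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0, abs=1e-9)
        assert m.mae == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_keeps_r2(self, rng):
        fit, table = self._fit(rng)
        shifted = table.assign(oil=table.oil + 2.5)
        m = evaluate(fit, shifted)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(2.5, abs=1e-9)
        assert m.mae == pytest.approx(2.5, abs=1e-9)

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            fit, table = self._fit(rng, noise=1.0)
            m = evaluate(fit, table)
            assert m.rmse >= m.mae - 1e-12


class TestRunModelSuite:
    @pytest.fixture()
    def table_and_plan(self, rng):
        design = make_design(45, rng)
        y = linear_oil(design, noise=0.5, rng=rng)
        table = design.assign(oil=y)
        # seven single-predictor candidates: noisy transforms of the bands
        for i in range(7):
            table[f"ci{i}"] = table.red * (1 + 0.1 * i) + rng.normal(0, 2, 45)
        return table, make_splits(45, seed=3)

    def test_metric_row_count(self, table_and_plan):
        table, plan = table_and_plan
        metrics, residuals = run_model_suite(table, [f"ci{i}" for i in range(7)], plan)
        n_models = metrics.model_id.nunique()
        assert len(metrics) == 5 * n_models
        assert metrics.query("model_id == 'RGB'").shape[0] == 5

    def test_rgb_model_accurate_on_linear_generator(self, table_and_plan):
        table, plan = table_and_plan
        metrics, _ = run_model_suite(table, [], plan)
        rgb = metrics.query("model_id == 'RGB'")
        assert rgb.r2.median() >= 0.9

    def test_pooled_residuals_centered(self, table_and_plan):
        table, plan = table_and_plan
        _, residuals = run_model_suite(table, [], plan)
        res = residuals["RGB"]
        assert abs(res.mean()) < 2 * res.std() / np.sqrt(len(res))

    def test_noiseless_generator_perfect_metrics(self, rng):
        design = make_design(45, rng)
        table = design.assign(oil=linear_oil(design))
        metrics, _ = run_model_suite(table, [], make_splits(45, seed=1))
        rgb = metrics.query("model_id == 'RGB'")
        assert (rgb.r2 > 1 - 1e-9).all()
        assert (rgb.rmse < 1e-8).all()

    def test_benchmark_partitions_shared_across_models(self, table_and_plan):
        table, plan = table_and_plan
        metrics, _ = run_model_suite(table, ["ci0", "ci1"], plan)
        sizes = metrics.groupby("iteration")[["n_train", "n_test"]].nunique()
        assert (sizes == 1).all().all()  # every model saw identical partitions
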