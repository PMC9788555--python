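import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from nichecast.geo_io import EnvStack, GridGeometry
from nichecast.maxent_core import (
    FeatureSpec,
    FitSettings,
    beta_class,
    fit_maxent,
    jackknife,
    kkt_violation,
    predict,
    predict_values,
    response_curve,
    sample_background,
    variable_contributions,
)


def _spec_with_knots(classes, scaling, hinge=None, thresh=None):
    spec = FeatureSpec(classes)
    spec.scaling = scaling
    spec.hinge_knots = hinge
    spec.threshold_knots = thresh
    return spec


def _nll(lam, F_pres, F_bg, beta):
    s = F_bg @ lam
    smax = s.max()
    return (
        -float(F_pres.mean(axis=0) @ lam)
        + smax
        + np.log(np.exp(s - smax).sum())
        + float(beta @ np.abs(lam))
    )


class TestBuildFeatures:
    def test_linear_and_quadratic_scaling(self):
        spec = _spec_with_knots("LQ", {"v": (10.0, 30.0)})
        F, names, _ = spec.transform(pd.DataFrame({"v": [20.0]}))
        out = dict(zip(names, F[0]))
        assert out["L(v)"] == pytest.approx(0.5)
        assert out["Q(v)"] == pytest.approx(0.25)

    def test_forward_hinge_formula(self):
        spec = _spec_with_knots(
            "H", {"v": (0.0, 1.0)}, hinge={"v": np.array([0.5])}
        )
        F, names, _ = spec.transform(pd.DataFrame({"v": [0.75]}))
        out = dict(zip(names, F[0]))
        assert out["HF(v@0.5)"] == pytest.approx(0.5)  # (0.75-0.5)/(1-0.5)
        assert out["HR(v@0.5)"] == pytest.approx(0.0)

    def test_product_feature_and_parents(self):
        spec = _spec_with_knots("P", {"a": (0.0, 1.0), "b": (0.0, 1.0)})
        F, names, parents = spec.transform(pd.DataFrame({"a": [0.5], "b": [0.4]}))
        assert names == ["P(a*b)"]
        assert parents == [("a", "b")]
        assert F[0, 0] == pytest.approx(0.2)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown feature class"):
            FeatureSpec("LX")


class TestFitMaxent:
    def test_full_shrinkage_gives_uniform_raw(self):
        rng = np.random.default_rng(0)
        bg = pd.DataFrame({"v": rng.standard_normal(200)})
        pres = bg.iloc[:20]
        model = fit_maxent(
            pres, bg, FitSettings(rm=1e6), FeatureSpec("LQ"), include_presences=False
        )
        assert np.all(model.lambdas == 0.0)
        raw = predict_values(model, bg, output="raw")
        np.testing.assert_allclose(raw, 1.0 / len(bg), rtol=1e-12)

    def test_two_cell_closed_form_lambda(self):
        # background {x=0, x=1}, presences all at x=1, beta=0.1:
        # KKT forces E_raw[x] = 0.9, hence lambda = ln 9
        bg = pd.DataFrame({"x": [0.0, 1.0]})
        pres = pd.DataFrame({"x": [1.0] * 5})
        model = fit_maxent(
            pres,
            bg,
            FitSettings(),
            FeatureSpec("L"),
            include_presences=False,
            betas=np.array([0.1]),
        )
        assert model.lambdas[0] == pytest.approx(np.log(9.0), abs=1e-4)

    def test_linear_toy_matches_independent_solver(self):
        # 5-cell problem, L features, vanishing penalty: compare with a
        # general-purpose convex optimizer on the same objective
        bg = pd.DataFrame({"x": [0.0, 0.25, 0.5, 0.75, 1.0]})
        pres = pd.DataFrame({"x": [0.75, 1.0, 1.0]})
        beta = np.array([1e-9])
        model = fit_maxent(
            pres, bg, FitSettings(kkt_tol=1e-9, convergence_tol=1e-15),
            FeatureSpec("L"), include_presences=False, betas=beta,
        )
        spec = model.feature_spec
        F_pres, _, _ = spec.transform(pres)
        F_bg, _, _ = spec.transform(bg)
        ref = minimize(
            _nll, x0=np.zeros(1), args=(F_pres, F_bg, np.zeros(1)),
            method="BFGS", options={"gtol": 1e-10},
        )
        assert abs(model.lambdas[0] - ref.x[0]) < 1e-3

    def test_lq_fit_matches_independent_solver(self):
        # synthetic quadratic niche, penalty off: the coordinate solver and
        # a general-purpose optimizer must find the same coefficients
        rng = np.random.default_rng(1)
        bg = pd.DataFrame({"x": rng.uniform(-2, 2, 600)})
        eta = 1.5 * bg["x"] - 1.2 * bg["x"] ** 2
        w = np.exp(eta - eta.max())
        idx = rng.choice(len(bg), size=300, p=w / w.sum())
        pres = bg.iloc[idx].reset_index(drop=True)
        model = fit_maxent(
            pres, bg, FitSettings(kkt_tol=1e-9, convergence_tol=1e-15),
            FeatureSpec("LQ"), include_presences=False, betas=np.zeros(2),
        )
        spec = model.feature_spec
        F_pres, _, _ = spec.transform(pres)
        F_bg, _, _ = spec.transform(bg)
        ref = minimize(
            _nll, x0=np.zeros(2), args=(F_pres, F_bg, np.zeros(2)),
            method="BFGS", options={"gtol": 1e-10},
        )
        np.testing.assert_allclose(model.lambdas, ref.x, atol=1e-3)

    def test_kkt_certificate_on_randomized_fits(self):
        rng = np.random.default_rng(7)
        for classes in ("L", "LQ", "LQH"):
            n_bg, n_pres = 500, 60
            bg = pd.DataFrame(
                {f"v{i}": rng.standard_normal(n_bg) for i in range(3)}
            )
            w = np.exp(bg["v0"] - 0.5 * bg["v1"] ** 2)
            pres = bg.iloc[
                rng.choice(n_bg, size=n_pres, p=(w / w.sum()).to_numpy())
            ].reset_index(drop=True)
            model = fit_maxent(pres, bg, FitSettings(), FeatureSpec(classes))
            assert model.converged
            assert kkt_violation(model, pres, bg) <= 1e-4

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(3)
        bg = pd.DataFrame({"v": rng.standard_normal(300)})
        pres = bg.iloc[:30]
        a = fit_maxent(pres, bg, FitSettings(), FeatureSpec("LQ"))
        b = fit_maxent(pres, bg, FitSettings(), FeatureSpec("LQ"))
        np.testing.assert_array_equal(a.lambdas, b.lambdas)

    def test_too_few_presences(self):
        bg = pd.DataFrame({"v": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 2"):
            fit_maxent(bg.iloc[:1], bg, FitSettings(), FeatureSpec("L"))


class TestBetaSchedule:
    def test_interpolation_clamps_at_table_ends(self):
        assert beta_class(5, "L") == 1.0
        assert beta_class(1000, "L") == 0.05
        assert beta_class(65, "L") == pytest.approx((0.2 + 0.05) / 2)
        assert beta_class(50, "H") == 0.5


class TestPredict:
    def _null_model_and_stack(self):
        geom = GridGeometry(5, 5, 0.5, 100.0, 40.0)
        rng = np.random.default_rng(4)
        stack = EnvStack(geom, {"v": rng.standard_normal(geom.shape)})
        bg = stack.table()
        model = fit_maxent(
            bg.iloc[:5], bg, FitSettings(rm=1e6), FeatureSpec("L"),
            include_presences=False,
        )
        return model, stack

    def test_null_model_closed_form(self):
        model, stack = self._null_model_and_stack()
        n = stack.geometry.n_valid
        assert model.entropy == pytest.approx(np.log(n))
        raw = predict(model, stack, output="raw")
        np.testing.assert_allclose(raw.valid_values(), 1.0 / n, rtol=1e-12)
        logistic = predict(model, stack, output="logistic")
        np.testing.assert_allclose(logistic.valid_values(), 1.0 / 3.0, rtol=1e-12)

    def test_raw_sums_to_one_over_training_background(self):
        rng = np.random.default_rng(5)
        bg = pd.DataFrame({"v": rng.standard_normal(400)})
        pres = bg.iloc[:40]
        model = fit_maxent(pres, bg, FitSettings(), FeatureSpec("LQ"))
        F_fit = pd.concat([bg, pres], ignore_index=True)
        raw = predict_values(model, F_fit, output="raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_logistic_preserves_raw_ranking(self):
        rng = np.random.default_rng(6)
        bg = pd.DataFrame({"v": rng.standard_normal(300)})
        pres = bg.iloc[np.argsort(bg["v"].to_numpy())[-40:]]
        model = fit_maxent(pres, bg, FitSettings(), FeatureSpec("LQ"))
        raw = predict_values(model, bg, output="raw")
        logi = predict_values(model, bg, output="logistic")
        np.testing.assert_array_equal(np.argsort(raw), np.argsort(logi))

    def test_clamped_projection_equals_boundary_prediction(self):
        rng = np.random.default_rng(7)
        bg = pd.DataFrame({"v": rng.uniform(0.0, 1.0, 300)})
        pres = bg.iloc[:30]
        model = fit_maxent(pres, bg, FitSettings(), FeatureSpec("LQ"))
        hi = bg["v"].max()
        outside = pd.DataFrame({"v": [hi + 5.0]})
        boundary = pd.DataFrame({"v": [hi]})
        assert predict_values(model, outside, clamp=True)[0] == pytest.approx(
            predict_values(model, boundary, clamp=True)[0]
        )


class TestSampleBackground:
    def test_small_landscape_returns_all_cells(self, stack3):
        rows, cols = sample_background(stack3, 20000, seed=0)
        assert len(rows) == stack3.geometry.n_valid == 100

    def test_large_landscape_caps_at_max_distinct(self):
        geom = GridGeometry(250, 250, 0.05, 100.0, 40.0)
        stack = EnvStack(geom, {"v": np.zeros(geom.shape)})
        rows, cols = sample_background(stack, 20000, seed=1)
        assert len(rows) == 20000
        assert len(set(zip(rows.tolist(), cols.tolist()))) == 20000

    def test_seeded_reproducibility(self):
        geom = GridGeometry(60, 60, 0.05, 100.0, 40.0)
        stack = EnvStack(geom, {"v": np.zeros(geom.shape)})
        a = sample_background(stack, 1000, seed=9)
        b = sample_background(stack, 1000, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


def _two_var_fit(informative_strength=3.0, seed=0, classes="LQ"):
    rng = np.random.default_rng(seed)
    bg = pd.DataFrame(
        {"good": rng.standard_normal(800), "noise": rng.standard_normal(800)}
    )
    eta = informative_strength * bg["good"] - bg["good"] ** 2
    w = np.exp(eta - eta.max())
    pres = bg.iloc[
        rng.choice(len(bg), size=150, p=(w / w.sum()).to_numpy())
    ].reset_index(drop=True)
    return pres, bg, fit_maxent(pres, bg, FitSettings(), FeatureSpec(classes))


class TestContributions:
    def test_single_variable_model_gets_everything(self):
        rng = np.random.default_rng(1)
        bg = pd.DataFrame({"v": rng.standard_normal(300)})
        pres = bg.iloc[np.argsort(bg["v"].to_numpy())[-50:]]
        model = fit_maxent(pres, bg, FitSettings(), FeatureSpec("LQ"))
        contrib = variable_contributions(model)
        assert contrib["v"] == pytest.approx(100.0)

    def test_contributions_sum_to_100(self):
        _, _, model = _two_var_fit()
        assert variable_contributions(model).sum() == pytest.approx(100.0, abs=0.01)

    def test_driving_variable_dominates(self):
        _, _, model = _two_var_fit()
        contrib = variable_contributions(model)
        assert contrib["good"] > contrib["noise"]


class TestJackknife:
    def test_gain_structure(self):
        pres, bg, _ = _two_var_fit(seed=2)
        table = jackknife(pres, bg)
        full = table.attrs["full_gain"]
        assert table.loc["noise", "gain_alone"] == pytest.approx(0.0, abs=0.05)
        assert table.loc["good", "gain_alone"] > 0.2
        # removing either variable cannot raise the gain
        assert np.all(table["gain_without"] <= full + 1e-6)
        # dropping the informative variable hurts more
        assert table.loc["good", "gain_without"] < table.loc["noise", "gain_without"]


class TestResponseCurve:
    def test_irrelevant_variable_is_flat(self):
        # pin the noise variable's features to zero with a huge penalty:
        # its response curve must then be exactly flat
        rng = np.random.default_rng(3)
        bg = pd.DataFrame(
            {"good": rng.standard_normal(400), "noise": rng.standard_normal(400)}
        )
        w = np.exp(2.0 * bg["good"])
        pres = bg.iloc[
            rng.choice(len(bg), size=80, p=(w / w.sum()).to_numpy())
        ].reset_index(drop=True)
        betas = np.array([1e-4, 1e6, 1e-4, 1e6])  # L(good), L(noise), Q(good), Q(noise)
        model = fit_maxent(
            pres, bg, FitSettings(), FeatureSpec("LQ"), betas=betas
        )
        assert all(
            model.lambdas[j] == 0.0
            for j, name in enumerate(model.feature_names)
            if "noise" in name
        )
        curve = response_curve(model, "noise")
        assert curve["logistic"].std() == pytest.approx(0.0, abs=1e-12)

    def test_positive_linear_model_is_monotone(self):
        rng = np.random.default_rng(4)
        bg = pd.DataFrame({"v": rng.uniform(0, 1, 500)})
        w = np.exp(3.0 * bg["v"])
        pres = bg.iloc[
            rng.choice(len(bg), size=100, p=(w / w.sum()).to_numpy())
        ].reset_index(drop=True)
        model = fit_maxent(pres, bg, FitSettings(), FeatureSpec("L"))
        curve = response_curve(model, "v")
        assert np.all(np.diff(curve["logistic"]) >= 0)

    def test_quadratic_model_peaks_at_analytic_vertex(self):
        _, _, model = _two_var_fit(seed=5)
        lam = dict(zip(model.feature_names, model.lambdas))
        lam_l, lam_q = lam["L(good)"], lam["Q(good)"]
        assert lam_q < 0
        mn, mx = model.clamp_ranges["good"]
        vertex_raw = mn + (mx - mn) * (-lam_l / (2.0 * lam_q))
        curve = response_curve(model, "good", n_points=400)
        peak = curve["value"][curve["logistic"].idxmax()]
        assert abs(peak - vertex_raw) < (mx - mn) / 100
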