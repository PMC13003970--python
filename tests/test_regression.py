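import numpy as np
import pandas as pd
import pytest

from paddytiller.regression import (
    ALGORITHMS,
    PsoConfig,
    evaluate_regression,
    fit_ml,
    fit_pso_ml,
    load_linear_models,
    predict_linear,
    pso_optimize,
    split_train_test,
)


def reference_pso(objective, bounds, swarm, iters, w, c1, c2, seed):
    """Independent straightforward PSO sharing the engine's draw order."""
    bounds = np.asarray(bounds, float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = len(bounds)
    rng = np.random.default_rng(seed)
    x = np.stack([lo + rng.random(d) * (hi - lo) for _ in range(swarm)])
    v = np.zeros_like(x)
    pbest = x.copy()
    pval = np.array([objective(xi) for xi in x])
    g = int(np.argmin(pval))
    gbest, gval = pbest[g].copy(), pval[g]
    trace = []
    for _ in range(iters):
        for i in range(swarm):
            r1, r2 = rng.random(d), rng.random(d)
            v[i] = w * v[i] + c1 * r1 * (pbest[i] - x[i]) + c2 * r2 * (gbest - x[i])
            x[i] = np.clip(x[i] + v[i], lo, hi)
            val = objective(x[i])
            if val < pval[i]:
                pval[i], pbest[i] = val, x[i].copy()
                if val < gval:
                    gval, gbest = val, x[i].copy()
        trace.append(gval)
    return gbest, gval, trace


class TestLinearModels:
    def test_all_eleven_models_load(self):
        models = load_linear_models()
        assert sorted(models) == [
            "F1", "F2", "F3", "F4", "F5", "F6", "MF1", "MF2", "MF3", "MF4", "MF5",
        ]

    def test_intercepts_returned_at_zero_inputs(self):
        for model in load_linear_models().values():
            zeros = {n: 0.0 for n in model.feature_names}
            assert predict_linear(model, zeros) == pytest.approx(model.intercept)

    def test_plant_area_model_by_hand(self):
        f1 = load_linear_models()["F1"]
        assert predict_linear(f1, {"total_area": 0.0}) == 3.5401
        assert predict_linear(f1, {"total_area": 1000.0}) == pytest.approx(8.0401)

    def test_four_feature_model_intercept(self):
        mf3 = load_linear_models()["MF3"]
        assert predict_linear(mf3, {n: 0.0 for n in mf3.feature_names}) == 2.0999

    def test_missing_feature_named_in_error(self):
        f1 = load_linear_models()["F1"]
        with pytest.raises(KeyError, match="total_area"):
            predict_linear(f1, {"perimeter": 5.0})

    def test_dataframe_prediction_vectorized(self):
        f1 = load_linear_models()["F1"]
        table = pd.DataFrame({"total_area": [0.0, 1000.0]})
        assert predict_linear(f1, table) == pytest.approx([3.5401, 8.0401])


class TestMetrics:
    def test_perfect_predictions(self):
        r = evaluate_regression([1, 2, 3], [1, 2, 3])
        assert r.rmse == 0 and r.mae == 0 and r.r2 == 1.0

    def test_constant_prediction_hand_arithmetic(self):
        r = evaluate_regression([1, 2, 3], [2, 2, 2])
        assert r.rmse == pytest.approx(np.sqrt(2 / 3))
        assert r.mae == pytest.approx(2 / 3)
        assert r.r2 == 0.0 and r.r2_printed == 0.0

    def test_nrmse_with_explicit_normalizer(self):
        r = evaluate_regression([1, 2, 3], [2, 2, 2], nf=2.0)
        assert r.nrmse == pytest.approx(np.sqrt(2 / 3) / 2 * 100)

    def test_rmse_dominates_mae(self, rng):
        y = rng.normal(size=50)
        p = y + rng.normal(size=50)
        r = evaluate_regression(y, p)
        assert r.rmse >= r.mae >= 0

    def test_zero_variance_truth_flags_degenerate(self):
        r = evaluate_regression([2, 2, 2], [1, 2, 3])
        assert r.degenerate and np.isnan(r.r2)


class TestSplit:
    def test_ten_rows_split_eight_two(self):
        t = pd.DataFrame({"x": range(10)})
        tr, te = split_train_test(t, seed=0)
        assert len(tr) == 8 and len(te) == 2

    def test_disjoint_and_exhaustive(self):
        t = pd.DataFrame({"x": range(23)})
        tr, te = split_train_test(t, seed=1)
        assert set(tr["x"]) | set(te["x"]) == set(range(23))
        assert not set(tr["x"]) & set(te["x"])

    def test_seed_reproducibility(self):
        t = pd.DataFrame({"x": range(12)})
        a = split_train_test(t, seed=5)[0]["x"].tolist()
        b = split_train_test(t, seed=5)[0]["x"].tolist()
        assert a == b


class TestPso:
    def test_sphere_convergence(self):
        cfg = PsoConfig(bounds=[(-5, 5), (-5, 5)], seed=0)
        _, val, _ = pso_optimize(lambda x: float((x**2).sum()), cfg)
        assert val < 1e-3

    def test_matches_reference_implementation_step_for_step(self):
        def rosenbrock(x):
            return float((1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2)

        cfg = PsoConfig(swarm_size=10, iterations=20, bounds=[(-2, 2), (-2, 2)], seed=3)
        pos, val, trace = pso_optimize(rosenbrock, cfg)
        rpos, rval, rtrace = reference_pso(
            rosenbrock, cfg.bounds, 10, 20, cfg.inertia, cfg.cognitive, cfg.social, 3
        )
        assert np.allclose(pos, rpos)
        assert val == pytest.approx(rval)
        assert np.allclose(trace, rtrace)

    def test_gbest_trace_monotone_and_bounded(self, rng):
        cfg = PsoConfig(swarm_size=8, iterations=15, bounds=[(0, 1), (-1, 1)], seed=2)
        seen = []

        def obj(x):
            seen.append(x.copy())
            return float(np.abs(x).sum())

        _, _, trace = pso_optimize(obj, cfg)
        assert all(a >= b for a, b in zip(trace, trace[1:]))
        pts = np.array(seen)
        assert (pts[:, 0] >= 0).all() and (pts[:, 0] <= 1).all()
        assert (np.abs(pts[:, 1]) <= 1).all()

    def test_nan_objective_penalized(self):
        cfg = PsoConfig(swarm_size=4, iterations=3, bounds=[(-1, 1)], seed=0)
        _, val, _ = pso_optimize(
            lambda x: float("nan") if x[0] > 0 else float(x[0] ** 2), cfg
        )
        assert np.isfinite(val)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PsoConfig(bounds=[(1, 1)])
        with pytest.raises(ValueError):
            PsoConfig(swarm_size=1)


def _linear_table(n=160, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(1, 2, (n, 12))
    y = 4 + 10 * X[:, 0] + 3 * X[:, 1] + rng.normal(0, noise, n)
    t = pd.DataFrame(X, columns=[f"f{i}" for i in range(12)])
    t["tiller_count"] = y
    return t


class TestFitMl:
    def test_noiseless_linear_data_r2(self):
        t = _linear_table()
        tr, te = split_train_test(t, seed=0)
        model = fit_ml(tr, "gradient-boosted-trees", seed=0)
        pred = model.predict(te[model.feature_cols_].to_numpy(float))
        assert evaluate_regression(te["tiller_count"].to_numpy(), pred).r2 >= 0.95

    @pytest.mark.parametrize("algorithm", list(ALGORITHMS))
    def test_seed_reproducibility(self, algorithm):
        t = _linear_table(noise=0.3)
        m1 = fit_ml(t, algorithm, seed=4)
        m2 = fit_ml(t, algorithm, seed=4)
        x = t[m1.feature_cols_].to_numpy(float)
        assert np.allclose(m1.predict(x), m2.predict(x))

    def test_single_row_yields_constant_predictor(self):
        t = _linear_table(n=1)
        model = fit_ml(t, "random-forest", seed=0)
        x = np.vstack([t[model.feature_cols_].to_numpy(float)] * 3) * [1, 2, 3][0]
        assert len(np.unique(model.predict(x))) == 1

    def test_non_numeric_target_rejected(self):
        t = _linear_table(n=10)
        t["tiller_count"] = "many"
        with pytest.raises(Exception):
            fit_ml(t, "random-forest", seed=0)


class TestFitPsoMl:
    def test_tuned_never_worse_than_default_on_shared_folds(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(1, 2, (90, 12))
        y = 8 * X[:, 0] * X[:, 1] + rng.normal(0, 0.3, 90)
        t = pd.DataFrame(X, columns=[f"f{i}" for i in range(12)])
        t["tiller_count"] = y
        _, hp, report = fit_pso_ml(
            t,
            "gradient-boosted-trees",
            PsoConfig(swarm_size=5, iterations=4, seed=0),
            cv_folds=3,
            seed=0,
        )
        assert report["tuned_cv_rmse"] <= report["default_cv_rmse"]
        for (name, lo, hi, logscale, _integer) in ALGORITHMS["gradient-boosted-trees"]:
            assert lo * (1 - 1e-9) <= hp[name] <= hi * (1 + 1e-9)

    def test_hyperparameter_choice_reproducible(self):
        t = _linear_table(n=40, noise=0.5, seed=2)
        kwargs = dict(
            pso_config=PsoConfig(swarm_size=4, iterations=3, seed=1), cv_folds=3, seed=1
        )
        _, hp1, _ = fit_pso_ml(t, "support-vector", **kwargs)
        _, hp2, _ = fit_pso_ml(t, "support-vector", **kwargs)
        assert hp1 == hp2

    def test_too_many_folds_rejected(self):
        t = _linear_table(n=4)
        with pytest.raises(ValueError):
            fit_pso_ml(t, "random-forest", cv_folds=10)
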