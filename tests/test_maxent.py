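import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from sdmax.grid_io import EnvStack
from sdmax.maxent import (
    ReplicateConfig,
    build_features,
    fit_maxent,
    predict_logistic,
    predict_raw,
    run_replicates,
)
from sdmax.occurrences import PresenceTable
from tests.conftest import make_grid


def table_from(df: pd.DataFrame) -> PresenceTable:
    data = df.copy()
    data.insert(0, "lat", 0.0)
    data.insert(0, "lon", 0.0)
    return PresenceTable(data=data, variables=list(df.columns), n_effective=len(df))


def objective(lam, F_p, F_b, betas):
    """Independent evaluation of the penalized maxent objective."""
    lam = np.atleast_1d(lam)
    return float(-(F_p @ lam).mean() + logsumexp(F_b @ lam) + betas @ np.abs(lam))


def refine_grid_minimize(f, dim, lo=-10.0, hi=10.0, points=13, rounds=14):
    """Dense-grid brute force with iterative refinement (convex objective)."""
    center = np.zeros(dim)
    half = (hi - lo) / 2
    for _ in range(rounds):
        axes = [np.linspace(c - half, c + half, points) for c in center]
        best, best_val = None, np.inf
        for combo in itertools.product(*axes):
            v = f(np.array(combo))
            if v < best_val:
                best, best_val = np.array(combo), v
        center = best
        half *= 2.0 / (points - 1)  # keep neighbors of the grid argmin
    return center


class TestBuildFeatures:
    def test_linear_only_below_quadratic_threshold(self):
        rng = np.random.default_rng(0)
        bg = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        table = table_from(bg.iloc[:5])
        fs = build_features(table, bg)
        assert [f.kind for f in fs.features] == ["linear"] * 3

    def test_full_feature_count_at_100_presences(self):
        rng = np.random.default_rng(1)
        bg = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        table = table_from(pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc")))
        fs = build_features(table, bg, ReplicateConfig(hinge_knots=20))
        kinds = pd.Series([f.kind for f in fs.features]).value_counts()
        assert kinds["linear"] == 3 and kinds["quadratic"] == 3 and kinds["product"] == 3
        assert kinds["hinge_fwd"] + kinds["hinge_rev"] == 3 * 2 * 20

    def test_scaled_features_in_unit_interval_on_background(self):
        rng = np.random.default_rng(2)
        bg = pd.DataFrame(rng.normal(size=(100, 2)), columns=list("ab"))
        table = table_from(pd.DataFrame(rng.normal(size=(20, 2)), columns=list("ab")))
        fs = build_features(table, bg)
        F = fs.evaluate(bg)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_constant_variable_features_dropped(self):
        bg = pd.DataFrame({"a": np.arange(30.0), "c": np.full(30, 7.0)})
        table = table_from(bg.iloc[:5])
        with pytest.warns(UserWarning, match="constant"):
            fs = build_features(table, bg)
        assert all("c" not in f.variables for f in fs.features)


class TestFitMaxent:
    def test_uninformative_features_give_null_model(self):
        rng = np.random.default_rng(3)
        bg = pd.DataFrame({"a": rng.normal(size=100)})
        table = table_from(bg)  # presences identical to background
        fs = build_features(table, bg, ReplicateConfig())
        model = fit_maxent(bg, bg, fs)
        assert np.allclose(model.lambdas, 0.0)
        assert model.gain == pytest.approx(0.0, abs=1e-9)
        # raw distribution uniform over background
        np.testing.assert_allclose(model.raw(bg), 1.0 / len(bg))

    def test_single_binary_feature_matches_1d_oracle(self):
        # presence mean 0.9, background mean 0.1, no penalty:
        # closed form lambda = log(9 * 0.9 / 0.1) = log 81
        pres = pd.DataFrame({"a": np.r_[np.ones(90), np.zeros(10)]})
        bg = pd.DataFrame({"a": np.r_[np.ones(10), np.zeros(90)]})
        fs = build_features(table_from(pres), bg, ReplicateConfig())
        fs.features = [f for f in fs.features if f.kind == "linear"]
        fs.scaling = np.array([[0.0, 1.0]])
        cfg = ReplicateConfig(beta_multiplier=0.0, max_iterations=2000, tolerance=1e-14)
        model = fit_maxent(pres, bg, fs, cfg)
        F_p, F_b = fs.evaluate(pres), fs.evaluate(bg)
        oracle = refine_grid_minimize(lambda l: objective(l, F_p, F_b, np.zeros(1)), dim=1)
        assert model.lambdas[0] == pytest.approx(oracle[0], abs=1e-6)
        assert model.lambdas[0] == pytest.approx(np.log(81), abs=1e-6)

    def test_small_instance_matches_dense_grid_oracle(self):
        # <= 3 features, <= 50 background cells, beta = 0
        rng = np.random.default_rng(7)
        bg = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        pres = pd.DataFrame(rng.normal(loc=0.6, size=(30, 3)), columns=list("abc"))
        fs = build_features(table_from(pres), bg, ReplicateConfig())
        fs.features = [f for f in fs.features if f.kind == "linear"]
        fs.scaling = fs.scaling[:3]
        cfg = ReplicateConfig(beta_multiplier=0.0, max_iterations=5000, tolerance=1e-15)
        model = fit_maxent(pres, bg, fs, cfg)
        F_p, F_b = fs.evaluate(pres), fs.evaluate(bg)
        oracle = refine_grid_minimize(lambda l: objective(l, F_p, F_b, np.zeros(3)), dim=3,
                                      points=9, rounds=20)
        np.testing.assert_allclose(model.lambdas, oracle, atol=1e-4)

    def test_raw_probabilities_sum_to_one(self, presence_table, env_stack):
        cfg = ReplicateConfig(background_size=1000, seed=5)
        from sdmax.maxent import sample_background
        bg = sample_background(env_stack, 1000, np.random.default_rng(5))
        fs = build_features(presence_table, bg, cfg)
        model = fit_maxent(presence_table.env, bg, fs, cfg)
        assert model.raw(bg).sum() == pytest.approx(1.0, abs=1e-9)

    def test_objective_nonincreasing(self, presence_table, env_stack):
        from sdmax.maxent import sample_background
        bg = sample_background(env_stack, 1000, np.random.default_rng(6))
        cfg = ReplicateConfig(background_size=1000)
        fs = build_features(presence_table, bg, cfg)
        model = fit_maxent(presence_table.env, bg, fs, cfg)
        diffs = np.diff(model.objective_trace)
        assert np.all(diffs <= 1e-10)

    def test_kkt_box_condition(self):
        rng = np.random.default_rng(8)
        bg = pd.DataFrame(rng.normal(size=(300, 2)), columns=list("ab"))
        pres = pd.DataFrame(rng.normal(loc=0.8, size=(60, 2)), columns=list("ab"))
        cfg = ReplicateConfig(max_iterations=3000, tolerance=1e-12)
        fs = build_features(table_from(pres), bg, cfg)
        model = fit_maxent(pres, bg, fs, cfg)
        F_p, F_b = fs.evaluate(pres), fs.evaluate(bg)
        w = np.exp(F_b @ model.lambdas - logsumexp(F_b @ model.lambdas))
        gap = np.abs(w @ F_b - F_p.mean(axis=0))
        assert np.all(gap <= model.betas + 1e-3)


class TestPrediction:
    def null_model(self):
        bg = pd.DataFrame({"a": np.linspace(0, 1, 50)})
        fs = build_features(table_from(bg.iloc[:5]), bg, ReplicateConfig())
        return fit_maxent(bg, bg, fs), bg

    def test_null_model_constant_raw_and_logistic_half(self):
        model, bg = self.null_model()
        grid = make_grid(np.linspace(0, 1, 16).reshape(4, 4), name="a")
        stack = EnvStack(layers=[grid])
        raw = predict_raw(model, stack)
        assert np.allclose(raw.values, raw.values[0, 0])
        smap = predict_logistic(model, stack)
        np.testing.assert_allclose(smap.grid.values, 0.5, rtol=0, atol=1e-12)

    def test_logistic_monotone_in_raw_score(self):
        rng = np.random.default_rng(9)
        bg = pd.DataFrame({"a": rng.uniform(size=200)})
        pres = pd.DataFrame({"a": rng.uniform(size=50) ** 0.3})
        cfg = ReplicateConfig()
        fs = build_features(table_from(pres), bg, cfg)
        model = fit_maxent(pres, bg, fs, cfg)
        sweep = pd.DataFrame({"a": np.linspace(0, 1, 101)})
        raw = model.raw(sweep)
        logistic = model.logistic(sweep)
        order = np.argsort(raw)
        assert np.all(np.diff(logistic[order]) >= -1e-12)

    def test_logistic_matches_direct_formula(self):
        rng = np.random.default_rng(10)
        bg = pd.DataFrame({"a": rng.normal(size=150)})
        pres = pd.DataFrame({"a": rng.normal(loc=1.0, size=40)})
        cfg = ReplicateConfig()
        fs = build_features(table_from(pres), bg, cfg)
        model = fit_maxent(pres, bg, fs, cfg)
        q = np.exp(fs.evaluate(bg) @ model.lambdas - model.log_partition)
        expected = np.exp(model.entropy) * q / (1 + np.exp(model.entropy) * q)
        np.testing.assert_allclose(model.logistic(bg), expected, rtol=1e-12)

    def test_missing_variable_is_projection_error(self):
        model, _ = self.null_model()
        stack = EnvStack(layers=[make_grid(np.zeros((2, 2)), name="other")])
        with pytest.raises(ValueError, match="missing"):
            predict_raw(model, stack)


class TestRunReplicates:
    def test_split_sizes(self, thinned, env_stack):
        cfg = ReplicateConfig(n_replicates=1, seed=1, background_size=500)
        reps, _ = run_replicates(thinned, env_stack, cfg)
        n = len(reps[0].train_index) + len(reps[0].test_index)
        assert len(reps[0].train_index) == round(0.75 * n)

    def test_deterministic_under_master_seed(self, thinned, env_stack):
        cfg = ReplicateConfig(n_replicates=2, seed=42, background_size=500)
        r1, m1 = run_replicates(thinned, env_stack, cfg)
        r2, m2 = run_replicates(thinned, env_stack, cfg)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.train_index, b.train_index)
            np.testing.assert_array_equal(a.model.lambdas, b.model.lambdas)
        np.testing.assert_array_equal(m1.grid.values, m2.grid.values)

    def test_mean_map_of_single_replicate_is_that_map(self, thinned, env_stack):
        cfg = ReplicateConfig(n_replicates=1, seed=3, background_size=500)
        reps, mean_map = run_replicates(thinned, env_stack, cfg)
        np.testing.assert_allclose(mean_map.grid.values, reps[0].suitability.grid.values)
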