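import numpy as np
import pandas as pd
import pytest

from sdmax.evaluate import (
    auc_presence_background,
    evaluate_replicates,
    jackknife_gains,
    kappa_tss,
    max_tss_threshold,
    percent_contribution,
    permutation_importance,
    response_curve,
)
from sdmax.maxent import ReplicateConfig, build_features, fit_maxent, run_replicates
from tests.conftest import make_grid
from tests.test_maxent import table_from


def auc_pairwise_oracle(p, b):
    p, b = np.asarray(p, float), np.asarray(b, float)
    wins = sum((pi > bi) + 0.5 * (pi == bi) for pi in p for bi in b)
    return wins / (p.size * b.size)


class TestAuc:
    def test_perfect_separation(self):
        assert auc_presence_background([1, 1, 1], [0, 0]) == 1.0

    def test_all_ties(self):
        assert auc_presence_background([0.3] * 5, [0.3] * 7) == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(size=50), 2)  # rounding forces ties
        b = np.round(rng.uniform(size=50), 2)
        assert auc_presence_background(p, b) == pytest.approx(auc_pairwise_oracle(p, b), abs=1e-12)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            auc_presence_background([], [1.0])


class TestKappaTss:
    def test_perfect_classifier(self):
        kappa, tss = kappa_tss((50, 0, 0, 50))
        assert kappa == 1.0 and tss == 1.0

    def test_printed_example(self):
        kappa, tss = kappa_tss((40, 10, 5, 45))
        assert kappa == pytest.approx(0.70)
        assert tss == pytest.approx(0.70)

    def test_all_predicted_positive_balanced(self):
        _, tss = kappa_tss((50, 0, 50, 0))
        assert tss == pytest.approx(0.0)

    def test_degenerate_margins_give_nan_kappa(self):
        kappa, _ = kappa_tss((10, 0, 0, 0))
        assert np.isnan(kappa)

    def test_random_tables_match_hand_formula(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            tp, fn, fp, tn = rng.integers(0, 100, size=4)
            if tp + fn == 0 or fp + tn == 0:
                continue
            n = tp + fn + fp + tn
            po = (tp + tn) / n
            pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
            kappa, tss = kappa_tss((tp, fn, fp, tn))
            if pe < 1:
                assert kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
            assert tss == pytest.approx(tp / (tp + fn) + tn / (tn + fp) - 1, abs=1e-12)


class TestEvaluateReplicates:
    @pytest.fixture(scope="class")
    def replicates(self, thinned, env_stack):
        cfg = ReplicateConfig(n_replicates=3, seed=21, background_size=1000)
        reps, _ = run_replicates(thinned, env_stack, cfg)
        return reps

    def test_single_replicate_sd_zero(self, replicates):
        summary, _ = evaluate_replicates(replicates[:1])
        assert (summary["SD"] == 0).all()

    def test_identical_replicates_sd_zero(self, replicates):
        summary, _ = evaluate_replicates([replicates[0]] * 3)
        assert np.allclose(summary["SD"], 0.0)

    def test_summary_matches_per_replicate_values(self, replicates):
        summary, per = evaluate_replicates(replicates)
        assert summary.loc["AUC", "Average"] == pytest.approx(np.mean([m.auc for m in per]))
        assert summary.loc["TSS", "SD"] == pytest.approx(np.std([m.tss for m in per], ddof=1))

    def test_metrics_within_ranges(self, replicates):
        _, per = evaluate_replicates(replicates)
        for m in per:
            assert 0 <= m.auc <= 1 and -1 <= m.kappa <= 1 and -1 <= m.tss <= 1
            assert sum(m.confusion) > 0

    def test_max_tss_threshold_is_optimal(self):
        rng = np.random.default_rng(5)
        p, b = rng.uniform(0.3, 1, 50), rng.uniform(0, 0.7, 200)
        thr = max_tss_threshold(p, b)
        best = max(np.mean(p >= t) + np.mean(b < t) - 1
                   for t in np.unique(np.r_[p, b]))
        got = np.mean(p >= thr) + np.mean(b < thr) - 1
        assert got == pytest.approx(best, abs=1e-12)


class TestImportance:
    @pytest.fixture(scope="class")
    def model(self, presence_table, env_stack):
        from sdmax.maxent import sample_background
        cfg = ReplicateConfig(seed=31)
        bg = sample_background(env_stack, 2000, np.random.default_rng(31))
        fs = build_features(presence_table, bg, cfg)
        return fit_maxent(presence_table.env, bg, fs, cfg, variables=presence_table.variables)

    def test_percent_contribution_sums_to_100(self, model):
        pc = percent_contribution(model)
        assert pc.sum() == pytest.approx(100.0, abs=1e-6)
        assert (pc >= 0).all()

    def test_permutation_importance_sums_to_100(self, model):
        pi = permutation_importance(model, seed=1)
        assert pi.sum() == pytest.approx(100.0, abs=1e-6)
        assert (pi >= 0).all()

    def test_single_variable_model_gets_all_contribution(self, presence_table, env_stack):
        from sdmax.maxent import sample_background
        cfg = ReplicateConfig(seed=32)
        bg = sample_background(env_stack, 1000, np.random.default_rng(32))
        fs = build_features(presence_table, bg[["bio1"]], cfg, variables=["bio1"])
        model = fit_maxent(presence_table.env[["bio1"]], bg[["bio1"]], fs, cfg, variables=["bio1"])
        assert percent_contribution(model)["bio1"] == pytest.approx(100.0)

    def test_driver_dominates_both_rankings(self, model):
        assert percent_contribution(model).idxmax() == "bio1"
        assert permutation_importance(model, seed=2).idxmax() == "bio1"


class TestJackknife:
    def test_driver_has_largest_isolated_gain(self, presence_table, env_stack):
        cfg = ReplicateConfig(seed=41, background_size=1000)
        jk, gain_all = jackknife_gains(presence_table, env_stack,
                                       ["bio1", "bio2", "bio17"], cfg)
        assert jk["gain_with_only"].idxmax() == "bio1"
        assert np.isfinite(gain_all) and gain_all > 0

    def test_uninformative_variable(self, presence_table, env_stack):
        # bio17 is unrelated to the truth: alone it gains ~nothing, and
        # leaving it out keeps nearly the full gain
        cfg = ReplicateConfig(seed=42, background_size=1000)
        jk, gain_all = jackknife_gains(presence_table, env_stack,
                                       ["bio1", "bio2", "bio17"], cfg)
        assert jk.loc["bio17", "gain_with_only"] < 0.25 * gain_all
        assert jk.loc["bio17", "gain_without"] > 0.75 * gain_all


class TestResponseCurve:
    def test_flat_near_half_on_constant_truth(self):
        from sdmax.grid_io import EnvStack
        from sdmax.occurrences import extract_presence_values
        from sdmax.synthetic import TruthConfig, sample_occurrences
        rng = np.random.default_rng(3)
        grid = make_grid(rng.uniform(0, 10, (20, 20)), cellsize=0.5, name="bio1")
        stack = EnvStack(layers=[grid])
        suit = make_grid(np.full((20, 20), 0.6), cellsize=0.5)
        occ = sample_occurrences(suit, TruthConfig(seed=3, n_presence=400))
        table = extract_presence_values(occ, stack)
        curve = response_curve(table, stack, "bio1", config=ReplicateConfig(seed=3))
        assert np.all(np.abs(curve.probability - 0.5) < 0.15)

    def test_peak_recovered_near_thermal_optimum(self, presence_table, env_stack, truth_config):
        curve = response_curve(presence_table, env_stack, "bio1",
                               config=ReplicateConfig(seed=4))
        step = curve.grid[1] - curve.grid[0]  # sweep discretization
        assert abs(curve.argmax - truth_config.optimum) <= truth_config.breadth + step

    def test_monotone_secondary_response(self):
        # truth monotone in bio2 alone (flat thermal response): the fitted
        # single-variable curve must trend upward over the data range
        from sdmax.occurrences import extract_presence_values
        from sdmax.synthetic import (
            TruthConfig,
            generate_env_stack,
            sample_occurrences,
            true_suitability,
        )
        header = {"nrows": 40, "ncols": 40, "xllcorner": 0.0, "yllcorner": 0.0,
                  "cellsize": 0.1, "nodata_value": -9999.0}
        cfg = TruthConfig(seed=6, n_presence=500, breadth=1e6,  # driver effectively flat
                          secondary_slope=0.4, intercept=-3.0)
        stack = generate_env_stack(header, cfg)
        suit = true_suitability(stack, cfg)
        occ = sample_occurrences(suit, cfg)
        table = extract_presence_values(occ, stack)
        curve = response_curve(table, stack, "bio2", config=ReplicateConfig(seed=6))
        third = len(curve.probability) // 3
        assert curve.probability[-third:].mean() > curve.probability[:third].mean()
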