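import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stoolmark import (
    ErfConfig,
    SimSpec,
    best_shadow,
    erf_rank,
    make_shadow,
    relevance_likelihoods,
    run_stability,
    simulate_cohort,
    to_relative_abundance,
    tune_mtry,
)
from stoolmark.erf_select import SHADOW_SUFFIX, VimRuns

TINY = ErfConfig(n_trees=100, mtry=30, n_stability_runs=5, seed=0)


def _vimruns(values: dict[str, list[float]], shadows: dict[str, list[float]]) -> VimRuns:
    cols = {**values, **{k + SHADOW_SUFFIX: v for k, v in shadows.items()}}
    return VimRuns(
        vims=pd.DataFrame(cols),
        feature_ids=tuple(values),
        shadow_ids=tuple(k + SHADOW_SUFFIX for k in shadows),
        run_seeds=tuple(range(len(next(iter(values.values()))))),
    )


class TestMakeShadow:
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_shadow_preserves_marginal_multiset(self, column, run_seed):
        X = np.array(column)[:, None]
        ext = make_shadow(X, run_seed)
        assert ext.shape == (len(column), 2)
        assert sorted(ext[:, 1]) == sorted(column)
        assert (ext[:, 0] == X[:, 0]).all()

    def test_constant_column_shadow_identical(self):
        X = np.full((4, 1), 4.0)
        ext = make_shadow(X, 7)
        assert (ext[:, 1] == 4.0).all()

    def test_same_seed_same_extension(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        assert (make_shadow(X, 123) == make_shadow(X, 123)).all()

    def test_shadows_differ_across_seeds(self):
        X = np.arange(20, dtype=float).reshape(10, 2)
        assert not (make_shadow(X, 1) == make_shadow(X, 2)).all()


class TestRunStability:
    def test_deterministic_given_config(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        a = run_stability(X, y, TINY)
        b = run_stability(X, y, TINY)
        assert (a.vims.to_numpy() == b.vims.to_numpy()).all()
        assert a.run_seeds == b.run_seeds

    def test_refuses_too_few_samples(self):
        with pytest.raises(ValueError, match="too few samples"):
            run_stability(np.ones((4, 3)), np.arange(4.0), TINY)

    def test_refuses_non_finite_response(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        y = np.array([1.0, np.nan, 2, 3, 4, 5, 6, 7])
        with pytest.raises(ValueError, match="non-finite"):
            run_stability(X, y, TINY)

    def test_signal_feature_beats_best_shadow(self):
        """A strongly predictive column's mean VIM exceeds the noise ceiling."""
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 20))
            y = 3 * X[:, 0] + rng.normal(scale=0.3, size=30)
            cfg = ErfConfig(n_trees=150, mtry=15, n_stability_runs=6, seed=seed)
            v = run_stability(X, y, cfg)
            bs = best_shadow(v)
            assert v.vims["f0"].mean() > v.vims[bs].mean()

    def test_null_vims_match_shadow_distribution(self):
        """With y independent of X, original and shadow mean VIMs are drawn
        from the same distribution (two-sample KS on pooled values)."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 60))
        y = rng.normal(size=30)
        cfg = ErfConfig(n_trees=200, mtry=40, n_stability_runs=10, seed=3)
        v = run_stability(X, y, cfg)
        orig = v.vims[list(v.feature_ids)].mean(axis=0)
        shad = v.vims[list(v.shadow_ids)].mean(axis=0)
        assert stats.ks_2samp(orig, shad).pvalue > 0.01

    def test_classification_mode_runs(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 10))
        y = np.r_[["control"] * 10, ["case"] * 10]
        X[:10, 0] += 3.0
        cfg = ErfConfig(n_trees=100, mtry=8, n_stability_runs=4,
                        response_mode="group_classification", seed=1)
        v = run_stability(X, y, cfg)
        assert v.vims.shape == (4, 20)
        assert v.vims["f0"].mean() > 0


class TestBestShadow:
    def test_highest_mean_wins(self):
        v = _vimruns({"a": [0, 0]}, {"s1": [0.1, 0.1], "s2": [0.3, 0.3]})
        assert best_shadow(v) == "s2" + SHADOW_SUFFIX

    def test_tie_breaks_lexicographic(self):
        v = _vimruns({"a": [0, 0]}, {"z": [0.2, 0.2], "b": [0.2, 0.2]})
        assert best_shadow(v) == "b" + SHADOW_SUFFIX


class TestRelevanceLikelihoods:
    def test_feature_equal_to_shadow_is_half(self):
        v = _vimruns({"a": [1.0, 2.0, 3.0]}, {"s": [1.0, 2.0, 3.0]})
        res = relevance_likelihoods(v)
        assert res.table.loc["a", "likelihood"] == pytest.approx(0.5)
        assert res.best_shadow_likelihood == pytest.approx(0.5)

    def test_welch_one_sided_matches_textbook_computation(self):
        # feature VIMs [10,11,12,10,11] vs best shadow [1,1,2,1,1]:
        # Welch t = 22.627417 on df = 6.1132, one-sided p = 1.98804e-07
        v = _vimruns({"a": [10, 11, 12, 10, 11]}, {"s": [1, 1, 2, 1, 1]})
        res = relevance_likelihoods(v)
        assert res.table.loc["a", "likelihood"] == pytest.approx(
            1 - 1.9880367028063412e-07, abs=1e-12
        )

    def test_relevance_flag_is_strict_threshold(self):
        rng = np.random.default_rng(0)
        shadow = list(rng.normal(0, 1, size=8))
        v = _vimruns(
            {
                "strong": list(rng.normal(6, 1, size=8)),
                "weak": list(rng.normal(0.5, 1, size=8)),
                "null": shadow,
            },
            {"s": shadow},
        )
        res = relevance_likelihoods(v, ErfConfig(n_trees=1, mtry=1, n_stability_runs=8))
        tab = res.table
        assert (tab["relevant"] == (tab["likelihood"] > 0.70)).all()
        assert bool(tab.loc["strong", "relevant"])
        assert not bool(tab.loc["null", "relevant"])

    def test_ranks_are_permutation_and_likelihood_monotone(self):
        rng = np.random.default_rng(4)
        feats = {f"f{i}": list(rng.normal(i * 0.5, 1, size=6)) for i in range(5)}
        v = _vimruns(feats, {"s": list(rng.normal(0, 1, size=6))})
        res = relevance_likelihoods(v)
        assert sorted(res.table["rank"]) == [1, 2, 3, 4, 5]
        ordered = res.table.sort_values("rank")["likelihood"].to_numpy()
        assert (np.diff(ordered) <= 1e-12).all()


class TestPlantedRecoverySmall:
    def test_planted_taxa_rank_high(self):
        otu, meta, truth = simulate_cohort(SimSpec(seed=9))
        rel = to_relative_abundance(otu)
        cfg = ErfConfig(n_trees=200, mtry=200, n_stability_runs=6, seed=9)
        res = erf_rank(rel.data, meta.symptom_score, cfg)
        top = set(res.top(26))
        assert len(set(truth.planted_feature_ids) & top) >= 4


class TestTuneMtry:
    def test_single_candidate(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        assert tune_mtry(X, y, [1], ErfConfig(n_trees=50, mtry=1, n_stability_runs=2)) == 1

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        cfg = ErfConfig(n_trees=80, mtry=2, n_stability_runs=2, seed=5)
        assert tune_mtry(X, y, [1, 3, 10], cfg) == tune_mtry(X, y, [1, 3, 10], cfg)

    def test_chosen_mtry_has_no_worse_oob_error(self):
        """Strong single-feature signal: re-evaluating both grid ends directly
        confirms the winner's OOB error is <= the loser's."""
        from sklearn.ensemble import RandomForestRegressor

        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 12))
        y = 4 * X[:, 0] + rng.normal(scale=0.3, size=40)
        cfg = ErfConfig(n_trees=150, mtry=2, n_stability_runs=2, seed=2)
        grid = [1, 12]
        chosen = tune_mtry(X, y, grid, cfg)
        errs = {}
        for m in grid:
            rf = RandomForestRegressor(
                n_estimators=150, max_features=m, min_samples_leaf=5,
                oob_score=True, random_state=cfg.seed, n_jobs=1,
            ).fit(X, y)
            errs[m] = np.mean((rf.oob_prediction_ - y) ** 2)
        other = grid[1] if chosen == grid[0] else grid[0]
        assert errs[chosen] <= errs[other]


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_trees": 0},
            {"n_stability_runs": 1},
            {"relevance_threshold": 1.5},
            {"response_mode": "anova"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ErfConfig(**kwargs)

    def test_scaled_profile_only_changes_trees(self):
        cfg = ErfConfig(seed=4)
        scaled = cfg.scaled()
        assert scaled.n_trees == 500
        assert (scaled.mtry, scaled.n_stability_runs, scaled.seed) == (200, 20, 4)
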