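import numpy as np
import pandas as pd
import pytest

from dupdyn.retention import (
    filter_groups,
    fit_retention_model,
    leave_one_out_robustness,
    prefilter_features,
    retention_odds,
)
from dupdyn.simulate import (
    empirical_retention_odds,
    simulate_group_feature_table,
)

from test_acceptance import exact_conditional_ci_oracle


class TestOdds:
    def test_balanced_table_has_unit_odds(self):
        assert retention_odds(50, 50, 500, 500).odds == pytest.approx(1.0)

    def test_point_estimate_formula(self):
        # (30/10) / (400/600) = 3 / (2/3) = 4.5
        assert retention_odds(30, 10, 400, 600).odds == pytest.approx(4.5)

    def test_ci_brackets_the_estimate(self):
        r = retention_odds(30, 10, 400, 600)
        assert r.ci_low < r.odds < r.ci_high

    def test_zero_denominator_gives_infinite_odds_with_warning(self):
        with pytest.warns(UserWarning, match="infinite"):
            r = retention_odds(30, 0, 400, 600)
        assert np.isinf(r.odds)
        assert np.isinf(r.ci_high)

    def test_group_and_complement_odds_are_reciprocal(self):
        r = retention_odds(30, 10, 400, 600)
        rc = retention_odds(400, 600, 30, 10)
        assert r.odds * rc.odds == pytest.approx(1.0)

    def test_ci_matches_independent_inversion(self, rng):
        for _ in range(5):
            a, b, c, d = rng.integers(5, 80, 4)
            r = retention_odds(a, b, c, d)
            lo, hi = exact_conditional_ci_oracle(a, b, c, d)
            assert r.ci_low == pytest.approx(lo, abs=1e-6, rel=1e-6)
            assert r.ci_high == pytest.approx(hi, abs=1e-6, rel=1e-6)


class TestGroupFilter:
    def test_size_and_pair_thresholds(self):
        groups = pd.DataFrame({
            "gene_count": [99, 100, 2000, 2001, 1500],
            "pair_count": [50, 20, 20, 50, 19],
        }, index=["too_small", "lo_edge", "hi_edge", "too_big", "few_pairs"])
        kept = filter_groups(groups)
        assert sorted(kept.index) == ["hi_edge", "lo_edge"]


class TestPrefilter:
    def test_identical_features_keep_one(self, rng):
        f = pd.Series(rng.normal(size=20))
        features = pd.DataFrame({"f1": f, "f2": f})
        odds = pd.Series(rng.normal(size=20))
        assert len(prefilter_features(features, odds)) == 1

    def test_independent_features_all_survive(self, rng):
        features = pd.DataFrame(rng.normal(size=(20, 5)),
                                columns=[f"f{i}" for i in range(5)])
        odds = pd.Series(rng.normal(size=20))
        corr = features.corr().abs().to_numpy()
        assert (corr[~np.eye(5, dtype=bool)] <= 0.7).all()
        assert len(prefilter_features(features, odds)) == 5

    def test_mostly_missing_feature_removed(self, rng):
        f = pd.Series(rng.normal(size=25))
        sparse = f.copy()
        sparse.iloc[:22] = np.nan  # 88% missing
        features = pd.DataFrame({"good": f, "sparse": sparse})
        odds = pd.Series(rng.normal(size=25))
        with pytest.warns(UserWarning, match="missing"):
            kept = prefilter_features(features, odds)
        assert kept == ["good"]

    def test_constant_feature_removed_with_warning(self, rng):
        features = pd.DataFrame({"flat": np.ones(20),
                                 "ok": rng.normal(size=20)})
        odds = pd.Series(rng.normal(size=20))
        with pytest.warns(UserWarning, match="constant"):
            kept = prefilter_features(features, odds)
        assert kept == ["ok"]

    def test_blacklisted_feature_excluded(self, rng):
        features = pd.DataFrame(rng.normal(size=(20, 3)),
                                columns=["f1", "ds_derived", "f3"])
        odds = pd.Series(rng.normal(size=20))
        kept = prefilter_features(features, odds,
                                  blacklist={"ds_derived"})
        assert kept == ["f1", "f3"]

    def test_conflict_keeps_stronger_marginal_correlate(self, rng):
        base = rng.normal(size=30)
        odds = pd.Series(base + rng.normal(0, 0.1, 30))
        features = pd.DataFrame({
            "strong": base + rng.normal(0, 0.05, 30),
            "weak": base + rng.normal(0, 0.4, 30),
        })
        if features.corr().abs().iloc[0, 1] > 0.7:
            assert prefilter_features(features, odds) == ["strong"]


class TestModelFit:
    def test_perfect_predictor_gives_r2_one(self, rng):
        odds = pd.Series(rng.uniform(1, 3, 15))
        features = pd.DataFrame({
            "exact": odds.to_numpy(),
            "noise": rng.normal(size=15),
        })
        model = fit_retention_model(features, odds)
        assert model.features == ["exact"]
        assert model.r_squared == pytest.approx(1.0)

    def test_constant_odds_selects_nothing(self, rng):
        odds = pd.Series(np.full(15, 2.0))
        features = pd.DataFrame(rng.normal(size=(15, 3)),
                                columns=list("abc"))
        model = fit_retention_model(features, odds)
        assert model.features == []
        assert model.coefficients["const"] == pytest.approx(2.0)

    def test_noise_free_coefficients_match_truth(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, size=(20, 4)),
                         columns=["f1", "f2", "f3", "f4"])
        odds = pd.Series(2.0 + 1.5 * X["f1"] - 0.8 * X["f2"])
        model = fit_retention_model(X, odds)
        assert sorted(model.features) == ["f1", "f2"]
        assert model.coefficients["f1"] == pytest.approx(1.5, abs=1e-6)
        assert model.coefficients["f2"] == pytest.approx(-0.8, abs=1e-6)
        assert model.coefficients["const"] == pytest.approx(2.0, abs=1e-6)

    def test_final_f_at_least_full_model_f(self, rng):
        sim = simulate_group_feature_table(20, 8, {"f1": 1.2}, rng=rng)
        odds = empirical_retention_odds(sim["counts"])
        model = fit_retention_model(sim["features"], odds)
        full_f = model.history[0]["f_statistic"]
        assert model.f_statistic >= full_f

    def test_generative_recovery(self):
        """Backward elimination finds exactly the informative features on
        most seeds of the generative benchmark."""
        hits = 0
        for seed in range(10):
            gen = np.random.default_rng(seed)
            sim = simulate_group_feature_table(
                20, 11, {"f1": 1.5, "f2": -0.8}, noise_sd=0.05,
                count_scale=2000, rng=gen)
            odds = empirical_retention_odds(sim["counts"])
            model = fit_retention_model(sim["features"], odds)
            if sorted(model.features) == ["f1", "f2"] \
                    and model.r_squared > 0.9:
                hits += 1
        assert hits >= 9

    def test_importance_is_delta_r2(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, size=(20, 2)),
                         columns=["f1", "f2"])
        odds = pd.Series(1.0 + 2.0 * X["f1"] + 0.3 * X["f2"]
                         + rng.normal(0, 0.02, 20))
        model = fit_retention_model(X, odds)
        if set(model.features) == {"f1", "f2"}:
            assert model.importance["f1"] > model.importance["f2"]


class TestLeaveOneOut:
    def test_duplicated_groups_have_zero_dispersion(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, size=(8, 2)),
                         columns=["f1", "f2"],
                         index=pd.Index([f"g{i}" for i in range(8)]))
        odds = pd.Series(1.0 + 1.2 * X["f1"], index=X.index)
        X2 = pd.concat([X, X.set_index(X.index + "_dup")])
        odds2 = pd.concat([odds, odds.set_axis(X.index + "_dup")])
        rob = leave_one_out_robustness(X2, odds2)
        assert (rob["sd"] < 1e-8).all()

    def test_dispersion_equals_brute_force_refits(self, rng):
        sim = simulate_group_feature_table(12, 4, {"f1": 1.0},
                                           noise_sd=0.1, rng=rng)
        odds = empirical_retention_odds(sim["counts"])
        X = sim["features"]
        rob = leave_one_out_robustness(X, odds)
        # independent recomputation, one refit per omission
        est = {}
        for g in X.index:
            keep = X.index != g
            m = fit_retention_model(X[keep], odds[keep])
            for k, v in m.coefficients.items():
                est.setdefault(k, []).append(v)
        for k, vals in est.items():
            vals = np.array(vals)
            assert rob.loc[k, "mean"] == pytest.approx(vals.mean())
            expect_sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
            assert rob.loc[k, "sd"] == pytest.approx(expect_sd)

    def test_high_leverage_group_causes_largest_shift(self, rng):
        X = pd.DataFrame({"f1": np.r_[rng.uniform(0, 1, 11), 4.0]},
                         index=[f"g{i}" for i in range(12)])
        odds = pd.Series(1.0 + X["f1"] + rng.normal(0, 0.05, 12),
                         index=X.index)
        odds.iloc[-1] += 3.0  # outlier response at the leverage point
        shifts = {}
        base = fit_retention_model(X, odds).coefficients.get("f1", 0.0)
        for g in X.index:
            m = fit_retention_model(X[X.index != g], odds[odds.index != g])
            shifts[g] = abs(m.coefficients.get("f1", 0.0) - base)
        assert max(shifts, key=shifts.get) == "g11"
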