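import itertools

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import chi2

from dupdyn.dynamics import (
    LrtResult,
    OdeSystem,
    fit_ode,
    fit_single_copy_model,
    generator,
    likelihood_ratio_test,
    ode_solution,
    rate_groups,
    stationary_distribution,
)
from dupdyn.simulate import simulate_pair_fates


class TestSolution:
    def test_identity_at_time_zero(self):
        s = OdeSystem("pair", 0.7, 0.2, 0.1, 0.05, p0=[0.5, 0.3, 0.2])
        np.testing.assert_allclose(ode_solution(s, 0.0), [0.5, 0.3, 0.2])

    def test_frozen_system_is_constant(self):
        s = OdeSystem("single", 0, 0, 0, 0, p0=[0.2, 0.5, 0.3])
        for t in (0.1, 1.0, 10.0):
            np.testing.assert_allclose(ode_solution(s, t), [0.2, 0.5, 0.3],
                                       atol=1e-12)

    def test_pure_first_loss_closed_form(self):
        # x alone: O(t) = exp(-x t), mass flows into I
        s = OdeSystem("pair", 1.0, 0.0, 0.0, 0.0)
        np.testing.assert_allclose(
            ode_solution(s, np.log(2)), [0.5, 0.5, 0.0], atol=1e-12)
        ts = np.linspace(0, 4, 9)
        np.testing.assert_allclose(
            ode_solution(s, ts)[:, 0], np.exp(-ts), atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ode_solution(OdeSystem("pair", 1, 0, 0, 0), -0.5)

    @pytest.mark.parametrize("kind", ["pair", "single"])
    def test_generator_conserves_mass(self, kind, rng):
        for _ in range(20):
            A = generator(kind, *rng.uniform(0, 3, 4))
            np.testing.assert_allclose(A.sum(axis=0), 0.0, atol=1e-12)

    @pytest.mark.parametrize("kind", ["pair", "single"])
    def test_analytic_matches_numeric_integration(self, kind, rng):
        ts = np.linspace(0.0, 5.0, 26)
        for _ in range(30):
            s = OdeSystem(kind, *rng.uniform(0, 2.5, 4))
            num = solve_ivp(lambda t, p: s.A @ p, (0, 5), s.p0, t_eval=ts,
                            rtol=1e-10, atol=1e-12)
            ana = ode_solution(s, ts)
            assert np.max(np.abs(ana - num.y.T)) < 1e-7
            np.testing.assert_allclose(ana.sum(axis=1), 1.0, atol=1e-10)
            assert ana.min() >= 0 and ana.max() <= 1

    def test_repeated_eigenvalue_case(self):
        # x = y = w = z makes the spectrum degenerate-ish; solution must
        # still match numeric integration
        s = OdeSystem("pair", 0.5, 0.5, 0.5, 0.5)
        ts = np.linspace(0, 5, 11)
        num = solve_ivp(lambda t, p: s.A @ p, (0, 5), s.p0, t_eval=ts,
                        rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(ode_solution(s, ts) - num.y.T)) < 1e-7

    def test_long_run_reaches_stationary_distribution(self, rng):
        for _ in range(5):
            s = OdeSystem("pair", *rng.uniform(0.3, 2.0, 4))
            pi = stationary_distribution(s)
            np.testing.assert_allclose(ode_solution(s, 200.0), pi, atol=1e-8)


class TestFit:
    def test_grid_search_never_beats_optimizer(self):
        """Coarse grid over the rate space attains a likelihood no better
        than the multi-start optimum (independent search oracle)."""
        grid = np.array([0.02, 0.1, 0.3, 0.8, 2.0])
        for seed in range(4):
            gen = np.random.default_rng(300 + seed)
            truth = gen.uniform(0.05, 1.0, 4)
            df = simulate_pair_fates(
                200, tuple(truth), ds_sampler=lambda r, n: r.uniform(
                    0.3, 3, n), rng=gen)
            fit = fit_ode(df[["true_class", "ds"]], "four", n_starts=6,
                          rng=gen)
            from dupdyn.dynamics import _class_indices, _log_likelihood
            cls = _class_indices(df["true_class"], ("O", "I", "II"))
            ts = df["ds"].to_numpy()
            best_grid = max(
                _log_likelihood("pair", np.array(r), fit.p0, cls, ts)
                for r in itertools.product(grid, repeat=4))
            assert fit.log_likelihood >= best_grid - 1e-6

    def test_all_O_data_pushes_loss_rate_to_boundary(self, rng):
        obs = [("O", 0.01)] * 50
        fit = fit_ode(obs, "one", n_starts=4, rng=rng)
        assert fit.rates["x"] < 0.5
        assert fit.boundary

    def test_recovers_pair_rates(self):
        """Four-parameter fit recovers the dominant loss rates from data
        simulated at known rates (single replicate; the full replication
        experiment lives in the acceptance suite)."""
        gen = np.random.default_rng(42)
        truth = (0.9, 0.05, 0.12, 0.02)
        df = simulate_pair_fates(
            5000, truth, ds_sampler=lambda r, n: r.uniform(0.5, 3, n),
            rng=gen)
        fit = fit_ode(df[["true_class", "ds"]], "four", n_starts=8, rng=gen)
        assert fit.rates["x"] == pytest.approx(truth[0], rel=0.2)
        assert fit.rates["w"] == pytest.approx(truth[2], rel=0.2)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            fit_ode([("O", 1.0)] * 5, "one", rng=rng)

    def test_nonpositive_ds_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            fit_ode([("O", 0.0)] * 12, "one", rng=rng)

    def test_impossible_classes_under_frozen_rates(self):
        # with all rates zero and init (1,0,0) only O has positive
        # probability; a "+" observation has log-likelihood -inf
        from dupdyn.dynamics import _log_likelihood

        ll = _log_likelihood("single", np.zeros(4), np.array([1.0, 0, 0]),
                             np.array([1]), np.array([1.0]))
        assert ll < -600  # log of the clipped zero probability


class TestVariants:
    def test_named_variants_partition_rates(self):
        assert rate_groups("pair", "one") == (("x", "y", "w", "z"),)
        assert rate_groups("pair", "two") == (("x", "y"), ("w", "z"))
        assert rate_groups("single", "two") == (("x", "w"), ("y", "z"))
        with pytest.raises(ValueError):
            rate_groups("pair", (("x", "y"), ("w",)))  # z unassigned

    def test_one_parameter_fit_ties_all_rates(self, rng):
        df = simulate_pair_fates(300, (0.5, 0.5, 0.5, 0.5), rng=rng)
        fit = fit_ode(df[["true_class", "ds"]], "one", n_starts=4, rng=rng)
        vals = set(round(v, 12) for v in fit.rates.values())
        assert len(vals) == 1


class TestLrt:
    def test_identical_likelihoods_give_p_one(self):
        f0 = _mkfit("one", 1, -100.0)
        f1 = _mkfit("four", 4, -100.0)
        res = likelihood_ratio_test(f0, f1)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_statistic_and_chi_square_tail(self):
        f0 = _mkfit("one", 1, -102.9)
        f1 = _mkfit("two", 2, -100.0)
        res = likelihood_ratio_test(f0, f1)
        assert res.statistic == pytest.approx(5.8)
        assert res.df == 1
        assert res.p_value == pytest.approx(chi2.sf(5.8, 1))
        assert res.p_value == pytest.approx(0.016, abs=1e-3)

    def test_non_nested_pair_rejected(self):
        f0 = _mkfit("two", 2, -100.0)  # {x,y},{w,z}
        f1 = _mkfit(( ("x", "w"), ("y",), ("z",)), 3, -99.0)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(f0, f1)

    def test_reversed_nesting_rejected(self):
        f0 = _mkfit("four", 4, -99.0)
        f1 = _mkfit("one", 1, -100.0)
        with pytest.raises(ValueError):
            likelihood_ratio_test(f0, f1)


class TestSingleCopy:
    def test_symmetric_data_gives_balanced_up_down_rates(self):
        gen = np.random.default_rng(11)
        df = _simulate_single(5000, (0.35, 0.35, 0.35, 0.35), gen)
        fit = fit_single_copy_model(df, "two", n_starts=6, rng=gen)
        ratio = fit.rates["y"] / fit.rates["x"]
        assert 0.8 <= ratio <= 1.25

    def test_recovers_three_fold_downward_bias(self):
        hits = 0
        for seed in range(5):
            gen = np.random.default_rng(500 + seed)
            df = _simulate_single(5000, (0.2, 0.6, 0.2, 0.6), gen)
            fit = fit_single_copy_model(df, "two", n_starts=6, rng=gen)
            ratio = fit.rates["y"] / fit.rates["x"]
            if 2.0 <= ratio <= 4.5:
                hits += 1
        assert hits >= 4


def _simulate_single(n, rates, gen):
    """Observations from the single-copy kinetics at uniform d_s."""
    ts = gen.uniform(0.5, 3.0, n)
    s = OdeSystem("single", *rates)
    probs = ode_solution(s, ts)
    u = gen.random(n)
    idx = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    states = np.array(["O", "+", "-"])[idx]
    return list(zip(states, ts))


def _mkfit(variant, n_free, ll):
    from dupdyn.dynamics import OdeFit

    return OdeFit(kind="pair", variant=variant,
                  rates={"x": 0.1, "y": 0.1, "w": 0.1, "z": 0.1},
                  log_likelihood=ll, n_free=n_free,
                  p0=np.array([1.0, 0, 0]), n_obs=100, boundary=False)
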