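"""Global Gaussian fitting, model selection and uncertainty bands."""

import numpy as np
import pytest

import deerfit as df
from deerfit.globalfit import bootstrap_band


def make_trace(components, depth=0.3, kappa=0.2, noise=0.0, seed=0, label=None,
               n_points=300, t_max=3.0):
    grid = df.DistanceGrid()
    P = df.DistanceDistribution.from_components(components, grid)
    t = np.linspace(0.0, t_max, n_points)
    meta = {"pair": "pair-A"}
    if label:
        meta["label"] = label
    tr = df.compose_signal(P, df.BackgroundModel(kappa, 3.0), df.ModulationDepth(depth), t, meta=meta)
    return df.add_noise(tr, noise, seed) if noise else tr


class TestFitSingle:
    def test_noiseless_recovery(self):
        tr = make_trace([df.GaussianComponent(3.5, 0.25, 1.0)], depth=0.3, kappa=0.2)
        res = df.fit_single(tr, 1)
        assert res.centers[0] == pytest.approx(3.5, abs=1e-3)
        assert res.widths[0] == pytest.approx(0.25, abs=1e-3)
        assert res.depths[0] == pytest.approx(0.3, abs=1e-3)
        assert res.kappas[0] == pytest.approx(0.2, abs=1e-3)

    def test_noisy_median_center_error(self):
        errs = []
        for seed in range(15):
            tr = make_trace(
                [df.GaussianComponent(3.5, 0.25, 1.0)], noise=0.005, seed=seed
            )
            res = df.fit_single(tr, 1)
            errs.append(abs(res.centers[0] - 3.5))
        assert np.median(errs) <= 0.02

    def test_variable_background_dimension_recovery(self):
        # steeper-than-3D decay (d = 2.4, nanodisc clustering regime)
        grid = df.DistanceGrid()
        P = df.DistanceDistribution.from_components(
            [df.GaussianComponent(3.5, 0.25, 1.0)], grid
        )
        t = np.linspace(0.0, 3.0, 300)
        tr = df.compose_signal(
            P, df.BackgroundModel(0.3, 2.4), df.ModulationDepth(0.3), t,
            meta={"pair": "pair-A"},
        )
        fitter = df.GlobalGaussianFitter(
            n_components=1, vary_background_dim=True, n_restarts=4
        )
        fitter.fit([tr])
        assert fitter.centers_[0] == pytest.approx(3.5, abs=5e-3)
        assert fitter.dims_[0] == pytest.approx(2.4, abs=0.1)

    def test_pure_background_flags_low_modulation(self):
        t = np.linspace(0.0, 3.0, 300)
        V = np.exp(-0.3 * t)
        tr = df.DipolarTrace(t, V, {"pair": "pair-A"})
        with pytest.warns(RuntimeWarning, match="modulation depth"):
            res = df.fit_single(tr, 1)
        assert res.warnings
        # residuals at the noise floor (delta pinned at its lower bound)
        assert res.rss[0] <= 1e-3


class TestFitGlobal:
    def test_two_condition_population_recovery(self):
        comps = lambda a: [  # noqa: E731
            df.GaussianComponent(3.0, 0.3, a),
            df.GaussianComponent(4.5, 0.3, 1 - a),
        ]
        traces = [
            make_trace(comps(0.8), depth=0.35, noise=0.0035, seed=1, label="c1"),
            make_trace(comps(0.3), depth=0.35, noise=0.0035, seed=2, label="c2"),
        ]
        res = df.fit_global(df.ConditionSet(traces), 2)
        assert np.allclose(res.populations[0], [0.8, 0.2], atol=0.05)
        assert np.allclose(res.populations[1], [0.3, 0.7], atol=0.05)

    def test_single_condition_reduces_to_fit_single(self):
        tr = make_trace([df.GaussianComponent(3.5, 0.25, 1.0)])
        res_g = df.fit_global(df.ConditionSet([tr]), 1)
        res_s = df.fit_single(tr, 1)
        assert res_g.objective == pytest.approx(res_s.objective, abs=1e-9)

    def test_condition_permutation_invariance(self):
        comps = lambda a: [  # noqa: E731
            df.GaussianComponent(3.0, 0.3, a),
            df.GaussianComponent(4.5, 0.3, 1 - a),
        ]
        t1 = make_trace(comps(0.8), noise=0.004, seed=3, label="c1")
        t2 = make_trace(comps(0.3), noise=0.004, seed=4, label="c2")
        res_a = df.fit_global(df.ConditionSet([t1, t2]), 2)
        res_b = df.fit_global(df.ConditionSet([t2, t1]), 2)
        assert np.allclose(res_a.centers, res_b.centers, atol=1e-6)
        assert np.allclose(
            res_a.populations[0], res_b.populations[1], atol=1e-6
        )

    def test_duplicated_traces_identical_populations(self):
        comps = [
            df.GaussianComponent(3.0, 0.3, 0.6),
            df.GaussianComponent(4.5, 0.3, 0.4),
        ]
        tr = make_trace(comps, noise=0.004, seed=5)
        t1 = df.DipolarTrace(tr.t.copy(), tr.V.copy(), {"label": "c1"})
        t2 = df.DipolarTrace(tr.t.copy(), tr.V.copy(), {"label": "c2"})
        res = df.fit_global(df.ConditionSet([t1, t2]), 2)
        assert np.allclose(res.populations[0], res.populations[1], atol=1e-6)

    def test_mixed_pair_labels_rejected(self):
        t1 = make_trace([df.GaussianComponent(3.0, 0.3, 1.0)])
        t2 = make_trace([df.GaussianComponent(3.0, 0.3, 1.0)])
        t2.meta["pair"] = "pair-B"
        with pytest.raises(ValueError, match="same spin pair"):
            df.ConditionSet([t1, t2])


class TestChooseModel:
    def test_kmax_one_returns_k1(self):
        tr = make_trace([df.GaussianComponent(3.5, 0.3, 1.0)], noise=0.005, seed=0)
        res = df.choose_model(df.ConditionSet([tr]), K_max=1)
        assert res.n_components == 1

    def test_unimodal_selects_k1(self):
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            tr = make_trace(
                [df.GaussianComponent(3.5, 0.3, 1.0)], depth=0.35, noise=0.007,
                seed=seed,
            )
            res = df.choose_model(df.ConditionSet([tr]), K_max=2)
            hits += res.n_components == 1
        assert hits >= n_runs - 1

    def test_objective_nonincreasing_in_k(self):
        comps = [
            df.GaussianComponent(3.0, 0.3, 0.5),
            df.GaussianComponent(4.5, 0.3, 0.5),
        ]
        tr = make_trace(comps, noise=0.005, seed=11)
        res = df.choose_model(df.ConditionSet([tr]), K_max=3)
        objs = [res.objectives[K] for K in sorted(res.objectives)]
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))


class TestUncertainty:
    def test_noiseless_band_vanishes(self):
        tr = make_trace([df.GaussianComponent(3.5, 0.25, 1.0)])
        res = df.fit_single(tr, 1)
        lo, hi = res.confidence_band()
        assert np.max(hi - lo) / 2 <= 1e-4

    def test_band_brackets_best_fit(self):
        tr = make_trace([df.GaussianComponent(3.5, 0.25, 1.0)], noise=0.01, seed=2)
        res = df.fit_single(tr, 1)
        lo, hi = res.confidence_band()
        P = res.distribution().density
        assert np.all(lo <= P + 1e-12) and np.all(hi >= P - 1e-12)
        assert np.all(lo >= 0)

    def test_delta_vs_bootstrap_halfwidths(self):
        tr = make_trace([df.GaussianComponent(3.5, 0.25, 1.0)], noise=0.01, seed=42)
        res = df.fit_single(tr, 1)
        lo_d, hi_d = res.confidence_band()
        lo_b, hi_b = bootstrap_band(res, n_boot=200, seed=1)
        hw_d, hw_b = (hi_d - lo_d) / 2, (hi_b - lo_b) / 2
        m = hw_b > 1e-7
        ratio = np.median(hw_d[m] / hw_b[m])
        assert 0.5 <= ratio <= 2.0

    def test_state_population_sum_and_selector(self):
        comps = [
            df.GaussianComponent(3.0, 0.3, 0.6),
            df.GaussianComponent(4.5, 0.3, 0.4),
        ]
        tr = make_trace(comps, noise=0.0035, seed=6)
        res = df.fit_single(tr, 2)
        a0, e0 = res.state_population(0)
        a1, e1 = res.state_population(1)
        assert a0 + a1 == pytest.approx(1.0, abs=1e-6)
        assert abs(a0 - 0.6) <= 0.05
        aw, _ = res.state_population((2.9, 3.1))
        assert aw == pytest.approx(a0)
        with pytest.raises(ValueError, match="matches 0"):
            res.state_population((6.0, 7.0))
        with pytest.raises(ValueError, match="matches 2"):
            res.state_population((1.5, 8.0))
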