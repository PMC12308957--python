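"""Penalized likelihood, trust region, smoothing selection, and pair fits."""

import numpy as np
import pytest

from dynacor.design import build_design, link_invert
from dynacor.distributions import zi_copula_loglik
from dynacor.estimation import (CopulaEtaObjective, FitConfig, FitState,
                                StackedDesign, _initial_delta, fit_pair,
                                fit_zero_inflation, grad_hessian,
                                penalized_loglik, predict_curves,
                                select_lambda, trust_region_step)
from dynacor.simulate import sample_zi_gamma_copula, scenario_I, scenario_II
from dynacor.types import COPULA_PARAMS, ParamFormula, SmoothTermSpec


def small_problem(n=60, basis_dim=5, seed=9):
    sim = scenario_II(n=max(n, 100), seed=seed)
    y1, y2, z = sim.y1[:n], sim.y2[:n], sim.z[:n]
    forms = [ParamFormula(p, include_group_intercept=False,
                          smooth_terms=(SmoothTermSpec(basis_dim=basis_dim),)
                          if p == "rho" else ())
             for p in COPULA_PARAMS]
    design = build_design(forms, z)
    return y1, y2, z, design


class TestPenalizedLoglik:
    def test_zero_lambda_equals_total_loglik(self):
        y1, y2, z, design = small_problem()
        st = StackedDesign(design, COPULA_PARAMS)
        delta = _initial_delta(st, y1, y2)
        lp = penalized_loglik(delta, [1e-300], design, (y1, y2))
        etas = st.etas(delta)
        raw = zi_copula_loglik(y1, y2, np.exp(etas[:, 0]), np.exp(etas[:, 1]),
                               np.exp(etas[:, 2]), np.exp(etas[:, 3]),
                               np.tanh(etas[:, 4])).sum()
        assert lp == pytest.approx(raw, rel=1e-12)

    def test_intercept_only_matches_hand_loop(self):
        """delta = 0 means every cell shares link_invert(0) parameters."""
        from dynacor.distributions import cell_loglik
        from dynacor.types import CellParams, GammaParam

        y1, y2, z, _ = small_problem()
        forms = [ParamFormula(p, include_group_intercept=False)
                 for p in COPULA_PARAMS]
        design = build_design(forms, z)
        delta = np.zeros(5)
        lp = penalized_loglik(delta, [], design, (y1, y2))
        shared = CellParams(GammaParam(1.0, 1.0), GammaParam(1.0, 1.0),
                            0.0, 0.5, 0.5)
        hand = sum(cell_loglik((a, b), shared) for a, b in zip(y1, y2))
        assert lp == pytest.approx(hand, rel=1e-10)

    def test_penalty_definition(self):
        y1, y2, z, design = small_problem()
        st = StackedDesign(design, COPULA_PARAMS)
        rng = np.random.default_rng(0)
        delta = _initial_delta(st, y1, y2) + 0.01 * rng.standard_normal(st.p)
        from dynacor.design import assemble_penalty
        S = assemble_penalty(design, [3.0], COPULA_PARAMS)
        lp_pen = penalized_loglik(delta, [3.0], design, (y1, y2))
        lp_unpen = penalized_loglik(delta, [1e-300], design, (y1, y2))
        assert lp_pen + 0.5 * delta @ S @ delta == pytest.approx(lp_unpen, rel=1e-9)


class TestGradHessian:
    def test_matches_finite_differences(self):
        y1, y2, z, design = small_problem()
        st = StackedDesign(design, COPULA_PARAMS)
        rng = np.random.default_rng(0)
        delta = _initial_delta(st, y1, y2) + 0.05 * rng.standard_normal(st.p)
        lam = np.array([2.0])
        data = (y1, y2)
        g, H = grad_hessian(delta, lam, design, data)
        assert np.allclose(H, H.T)
        h = 1e-5
        for i in range(st.p):
            dp, dm = delta.copy(), delta.copy()
            dp[i] += h
            dm[i] -= h
            fd = (penalized_loglik(dp, lam, design, data)
                  - penalized_loglik(dm, lam, design, data)) / (2 * h)
            assert abs(g[i] - fd) < 1e-4
        h = 5e-4
        for i in range(0, st.p, 3):
            for j in range(i, st.p, 3):
                d = delta.copy()

                def f(di, dj, d=d, i=i, j=j):
                    dd = d.copy()
                    dd[i] += di
                    dd[j] += dj
                    return penalized_loglik(dd, lam, design, data)

                if i == j:
                    fd = (f(h, 0) + f(-h, 0) - 2 * f(0, 0)) / h**2
                else:
                    fd = (f(h, h) + f(-h, -h) - f(h, -h) - f(-h, h)) / (4 * h**2)
                assert abs(H[i, j] - fd) < 1e-3

    def test_penalty_gradient_is_exact(self):
        y1, y2, z, design = small_problem()
        st = StackedDesign(design, COPULA_PARAMS)
        delta = _initial_delta(st, y1, y2)
        from dynacor.design import assemble_penalty
        S = assemble_penalty(design, [5.0], COPULA_PARAMS)
        g_pen, _ = grad_hessian(delta, [5.0], design, (y1, y2))
        g_unpen, _ = grad_hessian(delta, [1e-300], design, (y1, y2))
        assert np.allclose(g_pen - g_unpen, -S @ delta, atol=1e-9)

    def test_gradient_small_at_optimum(self):
        y1, y2, z, design = small_problem(n=100)
        cfg = FitConfig(lambda_fixed=1.0, min_cells=20)
        fit = fit_pair(y1, y2, z, formulas={
            p: ParamFormula(p, include_group_intercept=False,
                            smooth_terms=(SmoothTermSpec(basis_dim=5),)
                            if p == "rho" else ())
            for p in list(COPULA_PARAMS) + ["p1", "p2"]}, config=cfg)
        assert np.max(np.abs(fit.copula_fit.gradient)) < 1e-4


class TestTrustRegion:
    def _quadratic(self, dim=4, seed=5):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((dim, dim))
        B = A @ A.T + dim * np.eye(dim)
        b = rng.standard_normal(dim)
        opt = np.linalg.solve(B, b)

        def lp(x):
            return float(b @ x - 0.5 * x @ B @ x)

        return B, b, opt, lp

    def test_exact_quadratic_reaches_optimum(self):
        B, b, opt, lp = self._quadratic()
        state = FitState(delta=np.zeros(4), lambdas=np.array([]),
                         penalized_loglik=lp(np.zeros(4)), trust_radius=1.0)
        for _ in range(3):
            g = b - B @ state.delta
            trust_region_step(state, lp, g, -B)
            if np.allclose(state.delta, opt, atol=1e-10):
                break
        assert np.allclose(state.delta, opt, atol=1e-8)

    def test_bad_model_shrinks_radius(self):
        # a "Hessian" pointing the wrong way forces rejections
        def lp(x):
            return float(-np.sum(x**2))

        state = FitState(delta=np.zeros(2), lambdas=np.array([]),
                         penalized_loglik=0.0, trust_radius=1.0)
        g = np.array([100.0, 0.0])      # wildly wrong gradient
        H = -np.eye(2)
        trust_region_step(state, lp, g, H)
        assert state.trust_radius < 1.0
        assert state.penalized_loglik <= 0.0 + 1e-12

    def test_accepted_steps_never_decrease_objective(self):
        y1, y2, z, design = small_problem(n=120)
        from dynacor.estimation import _fit_penalized

        obj = CopulaEtaObjective(y1, y2)
        st = StackedDesign(design, COPULA_PARAMS)
        fit = _fit_penalized(obj, design, COPULA_PARAMS,
                             FitConfig(lambda_fixed=1.0), _initial_delta(st, y1, y2),
                             None)
        assert np.isfinite(fit.penalized_loglik)


class TestSelectLambda:
    def _zi_fit_edf(self, curve_fun, n=1500, seed=3):
        rng = np.random.default_rng(seed)
        z = rng.uniform(0, 27, n)
        p = 1 / (1 + np.exp(-curve_fun(z)))
        d = (rng.uniform(size=n) < p).astype(float)
        f = ParamFormula("p1", include_group_intercept=False,
                         smooth_terms=(SmoothTermSpec(basis_dim=10),))
        fit = fit_zero_inflation(d, f, z)
        return fit

    def test_straight_line_data_gets_small_edf(self):
        fit = self._zi_fit_edf(lambda z: 0.05 * z - 0.6)
        assert fit.edf("p1") <= 2.5

    def test_high_curvature_data_gets_large_edf(self):
        fit = self._zi_fit_edf(lambda z: 2.0 * np.sin(z / 2.5))
        assert fit.edf("p1") > 4.0

    def test_fixed_lambda_override(self):
        y1, y2, z, design = small_problem(n=150)
        forms = {p: ParamFormula(p, include_group_intercept=False,
                                 smooth_terms=(SmoothTermSpec(basis_dim=5),)
                                 if p == "rho" else ())
                 for p in list(COPULA_PARAMS) + ["p1", "p2"]}
        fit = fit_pair(y1, y2, z, formulas=forms,
                       config=FitConfig(lambda_fixed=7.5, min_cells=20))
        assert np.allclose(fit.copula_fit.lambdas, 7.5)

    def test_select_lambda_deterministic(self):
        y1, y2, z, design = small_problem(n=150)
        st = StackedDesign(design, COPULA_PARAMS)
        state = FitState(delta=_initial_delta(st, y1, y2),
                         lambdas=np.array([1.0]))
        lam1 = select_lambda(state, design, (y1, y2))
        lam2 = select_lambda(state, design, (y1, y2))
        assert np.array_equal(lam1, lam2)


class TestZeroInflationFit:
    def test_intercept_only_recovers_proportion(self):
        rng = np.random.default_rng(4)
        z = rng.uniform(0, 27, 800)
        d = (rng.uniform(size=800) < 0.37).astype(float)
        f = ParamFormula("p1", include_group_intercept=False)
        fit = fit_zero_inflation(d, f, z)
        phat = link_invert(fit.delta[0], "logit")
        assert phat == pytest.approx(d.mean(), abs=1e-6)

    def test_scenario_I_zero_rate_flat(self):
        sim = scenario_I(n=4000, seed=8)
        f = ParamFormula("p1", include_group_intercept=False,
                         smooth_terms=(SmoothTermSpec(basis_dim=8),))
        fit = fit_zero_inflation((sim.y1 == 0).astype(float), f, sim.z)
        grid = np.linspace(1, 26, 20)
        eta, _ = fit.predict_eta("p1", grid)
        p = link_invert(eta, "logit")
        assert np.all(np.abs(p - 0.45) < 0.06)

    def test_sigmoid_curve_recovery(self):
        rng = np.random.default_rng(11)
        z = rng.uniform(0, 27, 2000)
        truth = 1 / (1 + np.exp(-(-0.05 * z + 0.3)))
        d = (rng.uniform(size=2000) < truth).astype(float)
        f = ParamFormula("p1", include_group_intercept=False,
                         smooth_terms=(SmoothTermSpec(basis_dim=10),))
        fit = fit_zero_inflation(d, f, z)
        grid = np.linspace(1, 26, 30)
        eta, se = fit.predict_eta("p1", grid)
        p = link_invert(eta, "logit")
        ptrue = 1 / (1 + np.exp(-(-0.05 * grid + 0.3)))
        # fitted curve within a generous pointwise band of the truth
        assert np.max(np.abs(p - ptrue)) < 0.08

    def test_degenerate_gene_warns(self):
        z = np.random.default_rng(0).uniform(0, 27, 200)
        f = ParamFormula("p1", include_group_intercept=False)
        with pytest.warns(RuntimeWarning):
            fit_zero_inflation(np.zeros(200), f, z)


class TestFitPair:
    def test_min_cells_enforced(self):
        z = np.linspace(0, 27, 100)
        with pytest.raises(ValueError):
            fit_pair(np.zeros(100), np.zeros(100), z)

    def test_constant_generator_gives_flat_curves(self):
        n = 1200
        truth = {k: np.full(n, v) for k, v in
                 [("mu1", 2.0), ("sigma1", 0.3), ("mu2", 1.5), ("sigma2", 0.4),
                  ("rho", 0.4), ("p1", 0.3), ("p2", 0.3)]}
        y1, y2 = sample_zi_gamma_copula(truth, seed=0)
        z = np.random.default_rng(100).uniform(0, 27, n)
        fit = fit_pair(y1, y2, z)
        # edf includes the unpenalized intercept and linear trend (2 total);
        # full smoothing leaves essentially nothing beyond them
        for p in ("mu1", "mu2", "rho"):
            assert fit.edf(p) <= 2.5, p
        curves = predict_curves(fit, np.linspace(2, 25, 15))
        # the unpenalized linear component keeps sampling noise, largest at
        # the interval ends, so the band is wider than 1/sqrt(n)
        for p, v, tol in [("mu1", 2.0, 0.15), ("rho", 0.4, 0.2),
                          ("p1", 0.3, 0.1)]:
            vals = curves[p]["value"]
            assert np.max(np.abs(vals - v)) < tol, p

    def test_decoupling_from_zero_pattern(self):
        """Moving both-zero cells in pseudotime changes the zero-inflation
        fits but leaves the copula-side coefficients untouched."""
        sim = scenario_II(n=600, seed=13)
        both_zero = (sim.y1 == 0) & (sim.y2 == 0)
        assert both_zero.sum() > 20
        z2 = sim.z.copy()
        z2[both_zero] = np.random.default_rng(99).uniform(0, 27,
                                                          both_zero.sum())
        cfg = FitConfig(lambda_fixed=2.0)
        f1 = fit_pair(sim.y1, sim.y2, sim.z, config=cfg)
        f2 = fit_pair(sim.y1, sim.y2, z2, config=cfg)
        # knot sets differ slightly, so compare fitted curves: the copula
        # side is unchanged (up to basis truncation) while the
        # zero-inflation curves respond to the relocated zeros
        grid = np.linspace(2, 25, 20)
        c1 = predict_curves(f1, grid)
        c2 = predict_curves(f2, grid)
        for p in ("mu1", "mu2", "sigma1", "sigma2", "rho"):
            assert np.allclose(c1[p]["value"], c2[p]["value"], atol=0.01), p
        assert np.max(np.abs(c1["p1"]["value"] - c2["p1"]["value"])) > 0.02


class TestPredictCurves:
    def test_flat_for_intercept_model(self):
        y1, y2, z, _ = small_problem(n=200)
        forms = {p: ParamFormula(p, include_group_intercept=False)
                 for p in list(COPULA_PARAMS) + ["p1", "p2"]}
        fit = fit_pair(y1, y2, z, formulas=forms, config=FitConfig(min_cells=20))
        curves = predict_curves(fit, np.linspace(1, 20, 7))
        mu1 = curves["mu1"]["value"]
        assert np.allclose(mu1, link_invert(fit.copula_fit.coef("mu1")[0], "log"))

    def test_rho_interval_respects_domain(self, scen2_fit):
        c = predict_curves(scen2_fit, np.linspace(1, 26, 40))
        assert np.all(np.abs(c["rho"]["lower"]) < 1.0)
        assert np.all(np.abs(c["rho"]["upper"]) < 1.0)
        assert np.all(c["rho"]["lower"] <= c["rho"]["upper"])

    def test_interval_width_shrinks_with_n(self):
        widths = []
        for n in (500, 2000):
            sim = scenario_II(n=n, seed=21)
            fit = fit_pair(sim.y1, sim.y2, sim.z,
                           config=FitConfig(lambda_fixed=10.0))
            c = predict_curves(fit, np.linspace(5, 22, 10))
            widths.append(np.mean(c["rho"]["upper"] - c["rho"]["lower"]))
        assert widths[1] < widths[0]

    def test_extrapolation_warns(self, scen2_fit):
        with pytest.warns(RuntimeWarning):
            predict_curves(scen2_fit, np.array([40.0]), parameters=["mu1"])

    def test_absent_group_errors(self, scen2_fit):
        with pytest.raises(ValueError):
            predict_curves(scen2_fit, np.array([5.0]), group=2,
                           parameters=["mu1"])
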