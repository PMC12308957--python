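"""Penalized likelihood estimation by a trust-region Newton algorithm.

The copula-side coefficient vector ``delta`` (stacked coefficients for
``mu1, sigma1, mu2, sigma2, rho``) maximizes the penalized log-likelihood

    l_p(delta) = sum_i l_i - 0.5 * delta' S delta,

where ``S`` is the block-diagonal smoothing penalty.  The outer loop
alternates (a) one accepted trust-region Newton step in ``delta`` at fixed
smoothing parameters with (b) an update of the smoothing parameters that
minimizes a prediction-error (UBRE-type) criterion of the working linear
model implied by the current gradient and Hessian.  Zero-inflation curves
are fitted separately as penalized logistic additive models on the zero
indicators, using the same design / penalty / optimizer machinery.

Per-cell derivatives of the log-likelihood with respect to the five additive
predictors are obtained by high-accuracy central differencing of the exactly
vectorized likelihood in predictor space and chained through the (linear)
designs; the logistic model uses its closed-form derivatives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import spearmanr

from .design import (DesignSet, assemble_penalty, build_design, link_invert,
                     penalized_blocks, total_cols)
from .distributions import zi_copula_loglik
from .types import COPULA_PARAMS, ParamFormula

logger = logging.getLogger(__name__)

_FD_H = 1e-4          # predictor-space differencing step
_EIG_FLOOR = 1e-7     # eigenvalue floor making (negative) Hessians usable


@dataclass
class FitConfig:
    """Tuning knobs of the penalized fit.

    ``lambda_fixed`` bypasses smoothing-parameter selection entirely (a
    scalar is broadcast across blocks).  ``smoothness_inflation`` multiplies
    the effective-degrees-of-freedom term of the selection criterion;
    values above 1 buy smoother fits.  The default 1.4 is the customary
    inflation factor that protects prediction-error criteria against
    occasional severe undersmoothing.
    """

    basis_dim: int = 10
    lambda_init: float = 1.0
    lambda_fixed: float | np.ndarray | None = None
    max_outer_iter: int = 200
    tol_loglik: float = 1e-7
    tol_grad: float = 1e-5
    min_cells: int = 50
    smoothness_inflation: float = 1.4
    seed: int = 0
    max_knots: int = 2000
    lambda_min: float = 1e-6
    lambda_max: float = 1e10
    shared_sigma_smooth: bool = False
    rho_test: str = "wald"
    trust_radius_init: float = 1.0


# ---------------------------------------------------------------------------
# per-cell objectives in predictor (eta) space


class CopulaEtaObjective:
    """Copula-side log-likelihood as a function of the five predictors."""

    n_eta = 5

    def __init__(self, y1, y2):
        self.y1 = np.asarray(y1, dtype=float)
        self.y2 = np.asarray(y2, dtype=float)

    def value(self, etas):
        """Per-cell log-likelihood at an (n, 5) predictor matrix."""
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return zi_copula_loglik(
                self.y1, self.y2,
                np.exp(etas[:, 0]), np.exp(etas[:, 1]),
                np.exp(etas[:, 2]), np.exp(etas[:, 3]),
                np.tanh(etas[:, 4]))

    def derivs(self, etas):
        """First and second per-cell derivatives w.r.t. the predictors.

        Central finite differences of the vectorized likelihood; the design
        chain rule applied afterwards is exact.
        """
        n, m = etas.shape[0], self.n_eta
        h = _FD_H
        f0 = self.value(etas)
        fp = np.empty((m, n))
        fm = np.empty((m, n))
        for i in range(m):
            e = etas.copy(); e[:, i] += h
            fp[i] = self.value(e)
            e = etas.copy(); e[:, i] -= h
            fm[i] = self.value(e)
        d1 = ((fp - fm) / (2.0 * h)).T
        d2 = np.empty((n, m, m))
        for i in range(m):
            d2[:, i, i] = (fp[i] + fm[i] - 2.0 * f0) / h**2
        for i in range(m):
            for j in range(i + 1, m):
                e = etas.copy(); e[:, i] += h; e[:, j] += h
                fpp = self.value(e)
                e = etas.copy(); e[:, i] -= h; e[:, j] -= h
                fmm = self.value(e)
                e = etas.copy(); e[:, i] += h; e[:, j] -= h
                fpm = self.value(e)
                e = etas.copy(); e[:, i] -= h; e[:, j] += h
                fmp = self.value(e)
                d2[:, i, j] = d2[:, j, i] = (fpp + fmm - fpm - fmp) / (4.0 * h**2)
        return d1, d2


class BernoulliEtaObjective:
    """Bernoulli log-likelihood of the zero indicator on the logit scale."""

    n_eta = 1

    def __init__(self, zero_indicator):
        self.d = np.asarray(zero_indicator, dtype=float)

    def value(self, etas):
        e = etas[:, 0]
        # log p = -log(1+exp(-e)); log(1-p) = -log(1+exp(e))
        return -(self.d * np.logaddexp(0.0, -e)
                 + (1.0 - self.d) * np.logaddexp(0.0, e))

    def derivs(self, etas):
        e = etas[:, 0]
        p = 1.0 / (1.0 + np.exp(-e))
        d1 = (self.d - p)[:, None]
        d2 = (-(p * (1.0 - p)))[:, None, None]
        return d1, d2


# ---------------------------------------------------------------------------
# stacked design and derivatives in coefficient space


class StackedDesign:
    """Per-parameter model matrices stacked into one coefficient vector."""

    def __init__(self, design: DesignSet, order):
        self.design = design
        self.order = list(order)
        self.Xs = [design[p].X for p in self.order]
        sizes = [X.shape[1] for X in self.Xs]
        ends = np.cumsum(sizes)
        self.slices = [slice(e - s, e) for s, e in zip(sizes, ends)]
        self.p = int(ends[-1])
        self.n = self.Xs[0].shape[0]

    def etas(self, delta):
        out = np.empty((self.n, len(self.Xs)))
        for m, (X, sl) in enumerate(zip(self.Xs, self.slices)):
            out[:, m] = X @ delta[sl]
        return out

    def chain(self, d1, d2):
        """Gradient and Hessian in coefficient space from eta-derivatives."""
        g = np.empty(self.p)
        H = np.empty((self.p, self.p))
        for m, (X, sl) in enumerate(zip(self.Xs, self.slices)):
            g[sl] = X.T @ d1[:, m]
            for m2, (X2, sl2) in enumerate(zip(self.Xs, self.slices)):
                if m2 < m:
                    continue
                blk = X.T @ (d2[:, m, m2][:, None] * X2)
                H[sl, sl2] = blk
                if m2 != m:
                    H[sl2, sl] = blk.T
        return g, H


def _floor_pd(A, floor=_EIG_FLOOR):
    """Symmetric eigendecomposition with eigenvalues floored to ``floor``."""
    vals, Q = np.linalg.eigh((A + A.T) / 2.0)
    vals = np.maximum(vals, floor)
    return vals, Q


def penalized_loglik(delta, lambdas, design: DesignSet, data, order=COPULA_PARAMS):
    """l_p = sum_i l_i - 0.5 delta' S delta at the given coefficients."""
    y1, y2 = data
    stacked = StackedDesign(design, order)
    obj = CopulaEtaObjective(y1, y2)
    vals = obj.value(stacked.etas(np.asarray(delta, float)))
    if not np.all(np.isfinite(vals)):
        bad = int(np.flatnonzero(~np.isfinite(vals))[0])
        raise FloatingPointError(f"non-finite log-likelihood at cell {bad}")
    S = assemble_penalty(design, lambdas, order)
    delta = np.asarray(delta, float)
    return float(vals.sum() - 0.5 * delta @ S @ delta)


def grad_hessian(delta, lambdas, design: DesignSet, data, order=COPULA_PARAMS):
    """Gradient vector and (symmetric) Hessian matrix of ``penalized_loglik``."""
    y1, y2 = data
    stacked = StackedDesign(design, order)
    obj = CopulaEtaObjective(y1, y2)
    delta = np.asarray(delta, float)
    d1, d2 = obj.derivs(stacked.etas(delta))
    g0, H0 = stacked.chain(d1, d2)
    S = assemble_penalty(design, lambdas, order)
    g = g0 - S @ delta
    H = H0 - S
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(H))):
        raise FloatingPointError("non-finite derivative entries")
    return g, (H + H.T) / 2.0


# ---------------------------------------------------------------------------
# trust region


@dataclass
class FitState:
    """Mutable optimizer state (one instance per fit)."""

    delta: np.ndarray
    lambdas: np.ndarray
    penalized_loglik: float = -np.inf
    gradient: np.ndarray | None = None
    penalized_hessian: np.ndarray | None = None
    trust_radius: float = 1.0
    iteration: int = 0


def _solve_tr_subproblem(G, vals, Q, radius):
    """Minimize G's + 0.5 s'Bs over ||s|| <= radius, B = Q diag(vals) Q'."""
    a = Q.T @ G
    s = -Q @ (a / vals)
    if np.linalg.norm(s) <= radius:
        return s, False
    anorm = np.linalg.norm(a)

    def excess(nu):
        return np.sqrt(np.sum((a / (vals + nu)) ** 2)) - radius

    hi = anorm / radius
    while excess(hi) > 0:          # guard against roundoff at the bracket end
        hi *= 2.0
    nu = brentq(excess, 0.0, hi, xtol=1e-12, rtol=1e-10)
    return -Q @ (a / (vals + nu)), True


def trust_region_step(state: FitState, lp_fun, g, H):
    """One accepted trust-region update of ``state.delta``.

    ``lp_fun`` evaluates the penalized log-likelihood; ``g``/``H`` are its
    current derivatives.  The quadratic model of ``-l_p`` is minimized within
    the radius; the step is accepted or rejected by the ratio of actual to
    predicted improvement, with the usual radius adjustments.
    """
    vals, Q = _floor_pd(-H)
    G = -g
    rejections = 0
    while True:
        s, at_boundary = _solve_tr_subproblem(G, vals, Q, state.trust_radius)
        predicted = -(G @ s + 0.5 * s @ (Q @ ((Q.T @ s) * vals)))
        lp_new = lp_fun(state.delta + s)
        actual = lp_new - state.penalized_loglik
        ratio = actual / predicted if (np.isfinite(lp_new) and predicted > 0) else -np.inf
        if ratio > 1e-4 and actual > -1e-10:
            if ratio > 0.75 and at_boundary:
                state.trust_radius *= 2.0
            elif ratio < 0.25:
                state.trust_radius *= 0.25
            state.delta = state.delta + s
            state.penalized_loglik = lp_new
            return state
        rejections += 1
        state.trust_radius *= 0.25
        if rejections > 30:
            raise RuntimeError("trust region: 30 consecutive step rejections")
        if np.linalg.norm(s) < 1e-14:
            # radius collapsed: we are numerically at a stationary point
            return state


# ---------------------------------------------------------------------------
# smoothing parameter selection (UBRE-type working-model criterion)


class _LambdaSelector:
    """Coordinate-descent minimization of the working-model criterion.

    At the current coefficients, with unpenalized gradient ``g0`` and
    floored negative Hessian ``B0``, the penalized update for a candidate
    set of smoothing parameters is ``delta_lam = (B0 + S)^{-1} (B0 d + g0)``
    and the criterion is

        V = ||z - R delta_lam||^2 / n - 1 + 2 * gamma * edf / n,

    with ``R'R = B0``, working data ``z = R d + R^{-T} g0`` and
    ``edf = tr((B0 + S)^{-1} B0)``.  Each penalty block is optimized on the
    log scale by bounded scalar search; rank-r Woodbury updates make every
    candidate evaluation O(r^3) after one factorization per sweep.
    """

    def __init__(self, blocks, p, n, gamma, lam_min, lam_max):
        self.n = n
        self.gamma = gamma
        self.lo, self.hi = np.log10(lam_min), np.log10(lam_max)
        self.factors = []
        for _, t, gcols in blocks:
            vals, Q = np.linalg.eigh(t.penalty)
            keep = vals > max(1e-12, 1e-10 * vals.max())
            V = np.zeros((p, int(keep.sum())))
            V[gcols] = Q[:, keep] * np.sqrt(vals[keep])
            self.factors.append(V)

    def update(self, lambdas, delta, g0, B0, S):
        n = self.n
        b = B0 @ delta + g0
        zTz = float(delta @ B0 @ delta + 2.0 * (delta @ g0)
                    + g0 @ np.linalg.solve(B0, g0))
        lambdas = lambdas.copy()
        Minv = np.linalg.inv(B0 + S)
        for j, V in enumerate(self.factors):
            A = Minv @ V
            K = V.T @ A
            T1 = A.T @ (B0 @ A)
            x0 = Minv @ b
            Vx0 = V.T @ x0
            edf0 = float(np.trace(Minv @ B0))
            lam_j = lambdas[j]
            r = K.shape[0]
            eye = np.eye(r)

            def crit(log10lam):
                dl = 10.0 ** log10lam - lam_j
                if abs(dl) < 1e-300:
                    dj, edf = x0, edf0
                else:
                    C = K + eye / dl
                    try:
                        sol = np.linalg.solve(C, np.column_stack([Vx0[:, None], T1]))
                    except np.linalg.LinAlgError:
                        return np.inf
                    dj = x0 - A @ sol[:, 0]
                    edf = edf0 - float(np.trace(sol[:, 1:]))
                rss = zTz - 2.0 * b @ dj + dj @ (B0 @ dj)
                return rss / n - 1.0 + 2.0 * self.gamma * edf / n

            res = minimize_scalar(crit, bounds=(self.lo, self.hi),
                                  method="bounded",
                                  options={"xatol": 0.02, "maxiter": 25})
            cand = float(10.0 ** res.x)
            if crit(np.log10(cand)) <= crit(np.log10(lam_j)) - 1e-12:
                dl = cand - lam_j
                C = K + eye / dl
                Minv = Minv - A @ np.linalg.solve(C, A.T)
                Minv = (Minv + Minv.T) / 2.0
                lambdas[j] = cand
        return lambdas


def select_lambda(state: FitState, design: DesignSet, data,
                  order=COPULA_PARAMS, config: FitConfig | None = None):
    """One sweep of smoothing-parameter updates at the current coefficients.

    Deterministic given the state; returns the updated vector (the state is
    not modified).  With ``config.lambda_fixed`` set this is a no-op.
    """
    config = config or FitConfig()
    if config.lambda_fixed is not None:
        return state.lambdas
    y1, y2 = data
    stacked = StackedDesign(design, order)
    obj = CopulaEtaObjective(y1, y2)
    d1, d2 = obj.derivs(stacked.etas(state.delta))
    g0, H0 = stacked.chain(d1, d2)
    return _select_lambda_inner(state, design, order, config, g0, H0)


def _select_lambda_inner(state, design, order, config, g0, H0):
    blocks = penalized_blocks(design, order)
    if not blocks:
        return state.lambdas
    p = total_cols(design, order)
    vals, Q = _floor_pd(-H0)
    B0 = Q @ (Q * vals).T
    S = assemble_penalty(design, state.lambdas, order)
    sel = _LambdaSelector(blocks, p, stacked_n(design), config.smoothness_inflation,
                          config.lambda_min, config.lambda_max)
    try:
        new = sel.update(state.lambdas, state.delta, g0, B0, S)
    except np.linalg.LinAlgError:
        logger.warning("smoothing criterion non-finite; keeping previous lambdas")
        return state.lambdas
    if not np.all(np.isfinite(new)):
        logger.warning("smoothing criterion non-finite; keeping previous lambdas")
        return state.lambdas
    return np.clip(new, config.lambda_min, config.lambda_max)


def stacked_n(design: DesignSet) -> int:
    return design.z.size


# ---------------------------------------------------------------------------
# generic penalized fit loop


@dataclass
class ComponentFit:
    """Result of one penalized-likelihood maximization."""

    order: list
    design: DesignSet
    delta: np.ndarray
    lambdas: np.ndarray
    penalized_loglik: float
    loglik: float
    gradient: np.ndarray
    covariance: np.ndarray          # (B0 + S)^{-1}, the penalized covariance
    edf_by_col: np.ndarray
    converged: bool
    iterations: int
    slices: dict

    def edf(self, parameter: str) -> float:
        sl = self.slices[parameter]
        return float(self.edf_by_col[sl].sum())

    def coef(self, parameter: str) -> np.ndarray:
        return self.delta[self.slices[parameter]]

    def predict_eta(self, parameter: str, z, group: int = 1):
        """Predictor curve and standard error on a grid, for one group."""
        pd_ = self.design[parameter]
        Xg = pd_.matrix_at(z, group)
        sl = self.slices[parameter]
        eta = Xg @ self.delta[sl]
        cov = self.covariance[sl, sl]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, cov, Xg), 0.0))
        return eta, se


def _fit_penalized(objective, design: DesignSet, order, config: FitConfig,
                   delta0, lambdas0) -> ComponentFit:
    stacked = StackedDesign(design, order)
    blocks = penalized_blocks(design, order)
    n_blocks = len(blocks)
    if config.lambda_fixed is not None:
        lam = np.broadcast_to(np.asarray(config.lambda_fixed, float),
                              (n_blocks,)).astype(float).copy()
    else:
        lam = np.asarray(lambdas0, float).copy() if lambdas0 is not None else \
            np.full(n_blocks, config.lambda_init)

    state = FitState(delta=np.asarray(delta0, float).copy(), lambdas=lam,
                     trust_radius=config.trust_radius_init)

    def lp_fun(delta, S):
        vals = objective.value(stacked.etas(delta))
        if not np.all(np.isfinite(vals)):
            return -np.inf
        return float(vals.sum() - 0.5 * delta @ S @ delta)

    S = assemble_penalty(design, state.lambdas, order) if n_blocks else \
        np.zeros((stacked.p, stacked.p))
    state.penalized_loglik = lp_fun(state.delta, S)
    if not np.isfinite(state.penalized_loglik):
        raise FloatingPointError("non-finite log-likelihood at the start values")

    d1, d2 = objective.derivs(stacked.etas(state.delta))
    g0, H0 = stacked.chain(d1, d2)
    converged = False
    stagnant = 0
    for it in range(config.max_outer_iter):
        state.iteration = it + 1
        S = assemble_penalty(design, state.lambdas, order) if n_blocks else S
        g = g0 - S @ state.delta
        H = H0 - S
        state.gradient, state.penalized_hessian = g, H
        lp_before = lp_fun(state.delta, S)
        state.penalized_loglik = lp_before
        try:
            trust_region_step(state, lambda dl: lp_fun(dl, S), g, H)
        except RuntimeError:
            break
        d1, d2 = objective.derivs(stacked.etas(state.delta))
        g0, H0 = stacked.chain(d1, d2)
        # smoothing-parameter update on the fresh working model
        if n_blocks and config.lambda_fixed is None:
            vals_B, Q_B = _floor_pd(-H0)
            B0 = Q_B @ (Q_B * vals_B).T
            S_cur = assemble_penalty(design, state.lambdas, order)
            sel = _LambdaSelector(blocks, stacked.p, stacked.n,
                                  config.smoothness_inflation,
                                  config.lambda_min, config.lambda_max)
            try:
                new_lam = sel.update(state.lambdas, state.delta, g0, B0, S_cur)
                if np.all(np.isfinite(new_lam)):
                    state.lambdas = np.clip(new_lam, config.lambda_min,
                                            config.lambda_max)
            except np.linalg.LinAlgError:
                logger.warning("lambda update failed; keeping previous values")
        S = assemble_penalty(design, state.lambdas, order) if n_blocks else S
        lp_after = lp_fun(state.delta, S)
        g = g0 - S @ state.delta
        gmax = float(np.max(np.abs(g)))
        if abs(lp_after - lp_before) < config.tol_loglik and gmax < config.tol_grad:
            converged = True
            state.penalized_loglik = lp_after
            break
        if abs(lp_after - lp_before) < max(config.tol_loglik, 1e-9 * (1 + abs(lp_after))):
            stagnant += 1
            if stagnant >= 3:
                converged = gmax < max(config.tol_grad, 1e-3)
                state.penalized_loglik = lp_after
                break
        else:
            stagnant = 0
        state.penalized_loglik = lp_after

    S = assemble_penalty(design, state.lambdas, order) if n_blocks else S
    g = g0 - S @ state.delta
    vals_B, Q_B = _floor_pd(-H0)
    B0 = Q_B @ (Q_B * vals_B).T
    Vp = np.linalg.inv(B0 + S)
    Vp = (Vp + Vp.T) / 2.0
    edf_by_col = np.einsum("ij,ji->i", Vp, B0)
    loglik = float(objective.value(stacked.etas(state.delta)).sum())
    slices = {name: sl for name, sl in zip(order, stacked.slices)}
    return ComponentFit(order=list(order), design=design, delta=state.delta,
                        lambdas=state.lambdas,
                        penalized_loglik=state.penalized_loglik,
                        loglik=loglik, gradient=g, covariance=Vp,
                        edf_by_col=edf_by_col, converged=converged,
                        iterations=state.iteration, slices=slices)


# ---------------------------------------------------------------------------
# public fitting interface


@dataclass
class PairFit:
    """Joint fit of one gene pair: copula side plus two zero-inflation fits."""

    copula_fit: ComponentFit
    zi_fits: dict
    formulas: dict
    config: FitConfig
    n_cells: int
    group_counts: dict
    converged: bool = True

    def edf(self, parameter: str) -> float:
        if parameter in ("p1", "p2"):
            return self.zi_fits[parameter].edf(parameter)
        return self.copula_fit.edf(parameter)

    def _component(self, parameter: str) -> ComponentFit:
        return self.zi_fits[parameter] if parameter in ("p1", "p2") \
            else self.copula_fit


def default_formulas(n_groups: int, basis_dim: int = 10,
                     shared_sigma_smooth: bool = False,
                     parameters=("mu1", "sigma1", "mu2", "sigma2",
                                 "rho", "p1", "p2")) -> dict:
    """The standard model: ``~ group + s(z, by=group)`` for every parameter."""
    return {p: ParamFormula.default(p, n_groups, basis_dim=basis_dim,
                                    shared_sigma_smooth=shared_sigma_smooth)
            for p in parameters}


def _initial_delta(stacked: StackedDesign, y1, y2) -> np.ndarray:
    """Method-of-moments start values on the pooled non-zero data."""
    delta = np.zeros(stacked.p)
    nz1, nz2 = y1[y1 > 0], y2[y2 > 0]
    both = (y1 > 0) & (y2 > 0)
    start = {
        "mu1": np.log(max(nz1.mean(), 1e-8)) if nz1.size else 0.0,
        "mu2": np.log(max(nz2.mean(), 1e-8)) if nz2.size else 0.0,
        "sigma1": np.log(np.clip(nz1.std() / nz1.mean(), 0.05, 5.0))
        if nz1.size > 1 else 0.0,
        "sigma2": np.log(np.clip(nz2.std() / nz2.mean(), 0.05, 5.0))
        if nz2.size > 1 else 0.0,
    }
    if both.sum() > 5:
        rs = spearmanr(y1[both], y2[both]).statistic
        if not np.isfinite(rs):
            rs = 0.0
        rho0 = np.clip(2.0 * np.sin(np.pi * rs / 6.0), -0.9, 0.9)
    else:
        rho0 = 0.0
    start["rho"] = np.arctanh(rho0)
    for name, sl in zip(stacked.order, stacked.slices):
        delta[sl.start] = start.get(name, 0.0)   # intercept column is first
    return delta


def fit_zero_inflation(zero_indicator, formula: ParamFormula, z, group=None,
                       config: FitConfig | None = None,
                       design: DesignSet | None = None) -> ComponentFit:
    """Penalized logistic additive fit of P(Y = 0) on the zero indicator.

    Shares the design / penalty / trust-region machinery of the copula fit;
    independent of it because the zero-inflation rate is exactly the marginal
    zero probability.
    """
    if formula.link != "logit":
        raise ValueError("zero-inflation fits require the logit link")
    config = config or FitConfig()
    d = np.asarray(zero_indicator, dtype=float)
    if design is None:
        design = build_design([formula], z, group, max_knots=config.max_knots)
    order = [formula.parameter]
    stacked = StackedDesign(design, order)
    delta0 = np.zeros(stacked.p)
    frac = d.mean()
    if frac in (0.0, 1.0):
        warnings.warn("gene has no zeros (or only zeros); zero-inflation fit "
                      "is non-informative", RuntimeWarning)
        frac = np.clip(frac, 1e-3, 1 - 1e-3)
    delta0[0] = np.log(frac / (1 - frac))
    return _fit_penalized(BernoulliEtaObjective(d), design, order, config,
                          delta0, None)


def fit_pair(y1, y2, z, group=None, formulas: dict | None = None,
             config: FitConfig | None = None) -> PairFit:
    """Fit the full zero-inflated copula regression for one gene pair.

    Alternates trust-region coefficient updates with smoothing-parameter
    selection until the penalized log-likelihood stabilizes, then fits the
    two zero-inflation curves by penalized logistic regression.
    """
    config = config or FitConfig()
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    z = np.asarray(z, float)
    if group is None:
        group = np.ones(z.size, dtype=int)
    group = np.asarray(group, int)
    n_groups = int(group.max())
    both = int(((y1 > 0) & (y2 > 0)).sum())
    if both < config.min_cells:
        raise ValueError(
            f"only {both} cells have both genes non-zero "
            f"(min_cells={config.min_cells})")
    if formulas is None:
        formulas = default_formulas(n_groups, basis_dim=config.basis_dim,
                                    shared_sigma_smooth=config.shared_sigma_smooth)
    cop_forms = [formulas[p] for p in COPULA_PARAMS]
    design = build_design(cop_forms, z, group, max_knots=config.max_knots)
    stacked = StackedDesign(design, COPULA_PARAMS)
    delta0 = _initial_delta(stacked, y1, y2)
    objective = CopulaEtaObjective(y1, y2)
    converged = True
    try:
        cop = _fit_penalized(objective, design, COPULA_PARAMS, config,
                             delta0, None)
        converged = cop.converged
    except (RuntimeError, FloatingPointError, np.linalg.LinAlgError) as err:
        logger.warning("copula fit failed: %s", err)
        cop = _fit_penalized(objective, design, COPULA_PARAMS,
                             FitConfig(**{**config.__dict__,
                                          "lambda_fixed": 1.0,
                                          "max_outer_iter": 25}),
                             delta0, None)
        converged = False
    zi_fits = {}
    for j, pname in enumerate(("p1", "p2"), start=1):
        y = y1 if j == 1 else y2
        if pname in formulas:
            zi_fits[pname] = fit_zero_inflation((y == 0).astype(float),
                                                formulas[pname], z, group,
                                                config)
    counts = {int(g): int((group == g).sum()) for g in np.unique(group)}
    return PairFit(copula_fit=cop, zi_fits=zi_fits, formulas=formulas,
                   config=config, n_cells=z.size, group_counts=counts,
                   converged=converged and all(f.converged for f in zi_fits.values()))


def predict_curves(fit, grid, group: int = 1, parameters=None,
                   level: float = 0.95) -> dict:
    """Fitted parameter curves with pointwise confidence intervals.

    Predictors are evaluated on the grid, mapped through the inverse links;
    intervals come from the penalized coefficient covariance on the
    predictor scale and therefore always respect the parameter domains.
    """
    from scipy.stats import norm

    if isinstance(fit, ComponentFit):
        components = {p: fit for p in fit.order}
    else:
        components = {p: fit._component(p)
                      for p in list(fit.copula_fit.order) + list(fit.zi_fits)}
    grid = np.asarray(grid, float)
    if parameters is None:
        parameters = list(components)
    zcrit = norm.ppf(0.5 + level / 2.0)
    out = {}
    for p in parameters:
        comp = components[p]
        pdesign = comp.design[p]
        if group > comp.design.n_groups:
            raise ValueError(f"group {group} absent from fit")
        zmin, zmax = comp.design.z[comp.design.group == group].min(), \
            comp.design.z[comp.design.group == group].max()
        if grid.min() < zmin - 1e-9 or grid.max() > zmax + 1e-9:
            warnings.warn(f"grid extrapolates beyond the observed pseudotime "
                          f"range [{zmin:.3g}, {zmax:.3g}] of group {group}",
                          RuntimeWarning)
        eta, se = comp.predict_eta(p, grid, group)
        out[p] = {
            "grid": grid,
            "eta": eta,
            "value": link_invert(eta, pdesign.link),
            "lower": link_invert(eta - zcrit * se, pdesign.link),
            "upper": link_invert(eta + zcrit * se, pdesign.link),
            "se_eta": se,
        }
    return out
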