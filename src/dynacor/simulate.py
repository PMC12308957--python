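"""Synthetic data from the zero-inflated Gamma Gaussian-copula model.

Four study scenarios define pseudotime-varying parameter functions:

I    linear predictors (exponential mean trends, linear Fisher-z
     correlation), constant CV and zero-inflation;
II   non-linear single-group trends mimicking pituitary development
     (cosine-shaped second mean, saturating correlation);
III  two groups (wild-type 55% / mutant 45%) with distinct non-linear
     means, dispersions, correlations and zero-inflation trajectories;
IV   constant margins with correlation tanh(C * (0.5 sin(2 pi z) - 0.8
     + 1.6 z)), z ~ U(0, 1): the scale constant C sweeps from the exact
     zero-correlation null (C = 0) to strong dependence, for type-I error
     and power experiments.

Sampling draws a latent bivariate standard normal with the cell's
correlation, maps it through the normal CDF and Gamma quantiles, then
applies independent Bernoulli "off" masks to create exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .types import CellParams

_SIGMOID = lambda x: 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


@dataclass
class SimulatedData:
    """A simulated dataset together with its generating cell parameters."""

    y1: np.ndarray
    y2: np.ndarray
    z: np.ndarray
    group: np.ndarray
    truth: dict                  # parameter name -> per-cell true values
    scenario: str = "custom"

    @property
    def n(self) -> int:
        return self.z.size

    def truth_params(self) -> CellParams:
        t = self.truth
        return CellParams.from_arrays(t["mu1"], t["sigma1"], t["mu2"],
                                      t["sigma2"], t["rho"], t["p1"], t["p2"])


def sample_zi_gamma_copula(params: CellParams | dict, seed=0) -> tuple:
    """Draw zero-inflated Gamma-copula observations for given cell params.

    Returns ``(y1, y2)``.  Accepts a :class:`CellParams` (fields may be
    arrays) or a plain dict of per-cell parameter arrays; fully reproducible
    from the seed (which may also be a ``numpy.random.Generator``).
    """
    t = params.as_dict() if isinstance(params, CellParams) else \
        {k: np.asarray(v, float) for k, v in params.items()}
    n = max(np.size(t[k]) for k in t)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rho = np.broadcast_to(t["rho"], (n,))
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    x1 = e1
    x2 = rho * e1 + np.sqrt(1.0 - rho**2) * e2
    u1 = special.ndtr(x1)
    u2 = special.ndtr(x2)
    w1 = special.gammaincinv(1.0 / t["sigma1"]**2, u1) * t["mu1"] * t["sigma1"]**2
    w2 = special.gammaincinv(1.0 / t["sigma2"]**2, u2) * t["mu2"] * t["sigma2"]**2
    d1 = rng.uniform(size=n) < np.broadcast_to(t["p1"], (n,))
    d2 = rng.uniform(size=n) < np.broadcast_to(t["p2"], (n,))
    return np.where(d1, 0.0, w1), np.where(d2, 0.0, w2)


def _simulate(z, group, truth, seed, scenario) -> SimulatedData:
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    y1, y2 = sample_zi_gamma_copula(truth, rng)
    return SimulatedData(y1=y1, y2=y2, z=z, group=group, truth=truth,
                         scenario=scenario)


def scenario_I(n: int = 1000, seed=0) -> SimulatedData:
    """Linear predictors: eta_mu1 = 0.02 z - 0.4, eta_mu2 = -0.03 z + 0.3,
    eta_rho = -0.02 z; sigma = (0.2, 0.27), p = (0.45, 0.3), z ~ U(0, 27)."""
    if n < 100:
        raise ValueError("n must be at least 100")
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, 27.0, n)
    truth = {
        "mu1": np.exp(0.02 * z - 0.4),
        "mu2": np.exp(-0.03 * z + 0.3),
        "sigma1": np.full(n, 0.2),
        "sigma2": np.full(n, 0.27),
        "rho": np.tanh(-0.02 * z),
        "p1": np.full(n, 0.45),
        "p2": np.full(n, 0.30),
    }
    return _simulate(z, np.ones(n, int), truth, rng, "I")


def scenario_II(n: int = 1000, seed=0) -> SimulatedData:
    """Non-linear single-group trends: mu2 is cosine-shaped with a minimum
    near pseudotime 16, rho rises from about -0.46 to +0.46."""
    if n < 100:
        raise ValueError("n must be at least 100")
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, 27.0, n)
    truth = {
        "mu1": np.exp(0.02 * z - 0.3),
        "mu2": 0.5 * np.cos(0.2 * z - 0.1) + 1.0,
        "sigma1": np.full(n, 0.2),
        "sigma2": np.full(n, 0.27),
        "rho": np.tanh(0.5 - np.exp(-0.2 * z)),
        "p1": np.full(n, 0.40),
        "p2": np.full(n, 0.35),
    }
    return _simulate(z, np.ones(n, int), truth, rng, "II")


def scenario_III_truth(z, group) -> dict:
    """Two-group parameter functions (group 1 wild-type, group 2 mutant)."""
    z = np.asarray(z, float)
    wt = np.asarray(group, int) == 1
    truth = {
        "mu1": np.where(wt, 0.008 * z**2 - 0.2 * z + 2.5,
                        np.exp(0.08 * np.exp(0.1 * z) + 0.2)),
        "mu2": np.where(wt, np.exp(np.sin(0.1 * (z - 16.0))),
                        np.exp(-0.02 * z + 0.6)),
        "sigma1": np.where(wt, 0.2, 0.3),
        "sigma2": np.where(wt, 0.3, 0.4),
        "rho": np.where(wt, np.tanh(0.4 * (0.2 * z - 1.0)),
                        np.tanh(-0.01 * z + 0.2)),
        "p1": np.where(wt, _SIGMOID(-0.004 * z**2 + 0.037 * z - 0.2),
                       _SIGMOID(0.01 * z - 0.9)),
        "p2": np.where(wt, _SIGMOID(-0.05 * z + 0.3),
                       _SIGMOID(0.01 * z**2 - 0.3 * z - 0.1)),
    }
    return truth


def scenario_III(n: int = 2000, seed=0, wt_fraction: float = 0.55) -> SimulatedData:
    """Two-group design: wild-type and mutant with distinct trajectories."""
    if n < 200:
        raise ValueError("n must be at least 200")
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, 27.0, n)
    n_wt = int(round(wt_fraction * n))
    group = np.concatenate([np.ones(n_wt, int), np.full(n - n_wt, 2, int)])
    truth = scenario_III_truth(z, group)
    return _simulate(z, group, truth, rng, "III")


def scenario_IV(n: int = 1000, seed=0, C: float = 0.0) -> SimulatedData:
    """Constant margins, correlation tanh(C(0.5 sin(2 pi z) - 0.8 + 1.6 z)).

    ``C = 0`` is the exact zero-correlation null; z ~ U(0, 1).
    """
    if n < 100:
        raise ValueError("n must be at least 100")
    if C < 0:
        raise ValueError("C must be non-negative")
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, 1.0, n)
    truth = {
        "mu1": np.full(n, 5.0),
        "mu2": np.full(n, 3.0),
        "sigma1": np.full(n, 1.0 / 3.0),
        "sigma2": np.full(n, 0.5),
        "rho": np.tanh(C * (0.5 * np.sin(2.0 * np.pi * z) - 0.8 + 1.6 * z)),
        "p1": np.full(n, 0.3),
        "p2": np.full(n, 0.4),
    }
    return _simulate(z, np.ones(n, int), truth, rng, "IV")


SCENARIOS = {"I": scenario_I, "II": scenario_II, "III": scenario_III,
             "IV": scenario_IV}


def bias_rmse(estimates: np.ndarray, truth: np.ndarray) -> dict:
    """Cell-averaged bias and RMSE of an (N x I) estimate matrix.

    bias = (1/N) sum_i | mean_l est_il - truth_i |
    rmse = (1/N) sum_i sqrt( mean_l (est_il - truth_i)^2 )
    """
    est = np.asarray(estimates, float)
    truth = np.asarray(truth, float)
    if est.ndim != 2 or est.shape[0] != truth.size:
        raise ValueError("estimates must be (N x I) matching the truth length")
    if est.shape[1] < 2:
        raise ValueError("need at least two replicates")
    bias = float(np.mean(np.abs(est.mean(axis=1) - truth)))
    rmse = float(np.mean(np.sqrt(np.mean((est - truth[:, None]) ** 2, axis=1))))
    return {"bias": bias, "rmse": rmse}


def scenario_formulas(scenario: str, basis_dim: int = 10) -> dict:
    """Fit formulas mirroring each scenario's generating structure.

    Parameters that are constant (per group) in the generator are modelled
    as intercepts (plus group effects where there are two groups);
    parameters with pseudotime trends get spline smooths.  Scenario I is a
    linear setting and is fitted with unpenalized linear predictors.
    """
    from .types import ParamFormula, SmoothTermSpec

    sm = lambda **kw: (SmoothTermSpec(basis_dim=basis_dim, **kw),)
    if scenario == "I":
        f = {p: ParamFormula(p, include_group_intercept=False,
                             linear_terms=("z",))
             for p in ("mu1", "mu2", "rho")}
        f.update({p: ParamFormula(p, include_group_intercept=False)
                  for p in ("sigma1", "sigma2", "p1", "p2")})
    elif scenario == "II":
        f = {p: ParamFormula(p, include_group_intercept=False,
                             smooth_terms=sm())
             for p in ("mu1", "mu2", "rho")}
        f.update({p: ParamFormula(p, include_group_intercept=False)
                  for p in ("sigma1", "sigma2", "p1", "p2")})
    elif scenario == "III":
        f = {p: ParamFormula(p, smooth_terms=sm(by_group=True))
             for p in ("mu1", "mu2", "rho", "p1", "p2")}
        f.update({p: ParamFormula(p) for p in ("sigma1", "sigma2")})
    elif scenario == "IV":
        f = {p: ParamFormula(p, include_group_intercept=False)
             for p in ("mu1", "mu2", "sigma1", "sigma2", "p1", "p2")}
        f["rho"] = ParamFormula("rho", include_group_intercept=False,
                                smooth_terms=sm())
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return f


def scenario_study(scenario: str, n: int, replicates: int, seed: int = 0,
                   parameters=None, config=None, basis_dim: int = 10) -> dict:
    """Replicated parameter-recovery study for one scenario.

    One pseudotime draw (and group assignment) is fixed across replicates so
    that every cell has a well-defined true parameter value; each replicate
    re-samples the expression pair, refits, and stores the fitted cell-wise
    parameters.  Returns cell-averaged bias and RMSE per parameter (per
    group for two-group scenarios) plus the estimate matrices.
    """
    from .estimation import FitConfig, fit_pair, predict_curves

    config = config or FitConfig(basis_dim=basis_dim)
    rng = np.random.default_rng(seed)
    base = SCENARIOS[scenario](n=n, seed=int(rng.integers(2**31)))
    z, group, truth = base.z, base.group, base.truth
    formulas = scenario_formulas(scenario, basis_dim=basis_dim)
    if parameters is None:
        parameters = list(truth)
    est = {p: np.empty((n, replicates)) for p in parameters}
    n_converged = 0
    for l in range(replicates):
        y1, y2 = sample_zi_gamma_copula(truth, rng)
        fit = fit_pair(y1, y2, z, group, formulas=formulas, config=config)
        n_converged += fit.converged
        for g in np.unique(group):
            rows = group == g
            curves = predict_curves(fit, z[rows], group=int(g),
                                    parameters=parameters)
            for p in parameters:
                est[p][rows, l] = curves[p]["value"]
    out = {"scenario": scenario, "n": n, "replicates": replicates,
           "n_converged": n_converged, "metrics": {}, "estimates": est,
           "z": z, "group": group, "truth": truth}
    for p in parameters:
        if group.max() > 1:
            out["metrics"][p] = {
                int(g): bias_rmse(est[p][group == g], truth[p][group == g])
                for g in np.unique(group)}
        else:
            out["metrics"][p] = bias_rmse(est[p], truth[p])
    return out


def power_experiment(C_grid, n: int = 1000, replicates: int = 60,
                     alpha: float = 0.05, seed: int = 0,
                     config=None) -> dict:
    """Empirical rejection rate of the zero-correlation test per value of C.

    For each scale constant the scenario-IV generator is sampled, the model
    fitted, and the correlation-zero test applied at level ``alpha``.
    Non-converged replicates are excluded (and counted).  ``replicates``
    may be a single count or one count per value of C.
    """
    from .estimation import FitConfig, fit_pair
    from .inference import test_rho_zero

    C_grid = list(C_grid)
    if np.isscalar(replicates):
        replicates = [int(replicates)] * len(C_grid)
    replicates = [int(r) for r in replicates]
    if min(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    config = config or FitConfig()
    formulas = scenario_formulas("IV", basis_dim=config.basis_dim)
    root = np.random.default_rng(seed)
    out = {"C": list(C_grid), "rejection_rate": [], "n_failed": [],
           "replicates": replicates, "alpha": alpha}
    for C, reps in zip(C_grid, replicates):
        seeds = root.integers(0, 2**31 - 1, size=reps)
        rej, failed = 0, 0
        for s in seeds:
            sim = scenario_IV(n=n, seed=int(s), C=float(C))
            try:
                fit = fit_pair(sim.y1, sim.y2, sim.z, formulas=formulas,
                               config=config)
                t = test_rho_zero(fit)
            except Exception:
                failed += 1
                continue
            if not np.isfinite(t.p_value):
                failed += 1
                continue
            rej += t.p_value < alpha
        used = reps - failed
        out["rejection_rate"].append(rej / used if used else np.nan)
        out["n_failed"].append(failed)
    return out
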