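"""Hypothesis tests, multiplicity adjustment, and screening metrics.

Two families of nulls are tested:

* the zero-correlation null ``rho(z) = 0`` for a fitted pair, via a
  Wald-type quadratic form in the correlation-predictor coefficients with
  the penalized coefficient covariance and a chi-square reference whose
  degrees of freedom are the effective degrees of freedom of those terms;
* curve-identity nulls across groups (for the correlation trajectory or a
  gene's zero-inflation trajectory), via a likelihood-ratio comparison of
  the by-group model against a shared-curve null, again on an
  effective-degrees-of-freedom chi-square scale.

Screening metrics summarize how far apart two groups' fitted correlation
curves are on a shared evenly spaced pseudotime grid: their mean absolute
difference, its maximum (bounded by 2), and the area under the absolute
difference curve (AUD = grid span times the mean absolute difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimation import ComponentFit, FitConfig, PairFit, fit_pair, \
    fit_zero_inflation
from .types import ParamFormula, SmoothTermSpec


@dataclass
class CurveTest:
    """A single curve hypothesis test."""

    statistic: float
    reference_df: float
    p_value: float


@dataclass
class PairScreenResult:
    """Per-pair screening record (one row of the results table)."""

    gene1: str
    gene2: str
    p_value: float
    p_adjusted: float
    delta_rho_bar: float
    max_abs_diff: float
    aud: float
    converged: bool


def _not_a_pytest_case(fn):
    """These public test functions share pytest's naming convention;
    keep the collector away from them."""
    fn.__test__ = False
    return fn


def _wald_edf(coefs, cov, edf):
    """Rank-truncated Wald quadratic form with chi-square(edf) reference."""
    rank = int(min(len(coefs), max(1, round(edf + 0.25))))
    vals, Q = np.linalg.eigh((cov + cov.T) / 2.0)
    order = np.argsort(vals)[::-1][:rank]
    vals = np.maximum(vals[order], 1e-12)
    a = Q[:, order].T @ coefs
    stat = float(np.sum(a**2 / vals))
    df = max(edf, 1e-3)
    return stat, df, float(stats.chi2.sf(stat, df))


@_not_a_pytest_case
def test_rho_zero(fit: PairFit | ComponentFit) -> CurveTest:
    """Test the null that the correlation function is identically zero.

    All coefficients of the correlation predictor (intercept included)
    enter a Wald-type quadratic form with the penalized covariance.
    """
    comp = fit.copula_fit if isinstance(fit, PairFit) else fit
    if isinstance(fit, PairFit) and not fit.converged:
        return CurveTest(np.nan, np.nan, np.nan)
    sl = comp.slices["rho"]
    stat, df, p = _wald_edf(comp.delta[sl], comp.covariance[sl, sl],
                            comp.edf("rho"))
    return CurveTest(stat, df, p)


def _null_formulas(formulas: dict, parameter: str) -> dict:
    """Replace ``parameter``'s formula by a single shared smooth, no group terms."""
    full = formulas[parameter]
    basis_dim = full.smooth_terms[0].basis_dim if full.smooth_terms else 10
    shared = ParamFormula(parameter, include_group_intercept=False,
                          smooth_terms=(SmoothTermSpec(basis_dim=basis_dim),))
    out = dict(formulas)
    out[parameter] = shared
    return out


@_not_a_pytest_case
def test_group_difference_rho(y1, y2, z, group, formulas: dict | None = None,
                              config: FitConfig | None = None,
                              full_fit: PairFit | None = None) -> CurveTest:
    """Likelihood-ratio test that both groups share one correlation curve.

    The full model carries a group fixed effect and by-group smooths on the
    correlation predictor; the null replaces them with a single shared
    smooth, leaving all other parameters' formulas unchanged.
    """
    from .estimation import default_formulas

    config = config or FitConfig()
    group = np.asarray(group, int)
    if group.max() < 2:
        raise ValueError("group-difference test needs two groups")
    if formulas is None:
        formulas = default_formulas(int(group.max()), basis_dim=config.basis_dim,
                                    shared_sigma_smooth=config.shared_sigma_smooth)
    if full_fit is None:
        full_fit = fit_pair(y1, y2, z, group, formulas, config)
    null_fit = fit_pair(y1, y2, z, group, _null_formulas(formulas, "rho"), config)
    if not (full_fit.converged and null_fit.converged):
        return CurveTest(np.nan, np.nan, np.nan)
    stat = 2.0 * (full_fit.copula_fit.loglik - null_fit.copula_fit.loglik)
    df = max(full_fit.edf("rho") - null_fit.edf("rho"), 0.5)
    stat = max(stat, 0.0)
    return CurveTest(stat, df, float(stats.chi2.sf(stat, df)))


@_not_a_pytest_case
def test_group_difference_zeroinflation(y, z, group, gene_label: str = "p1",
                                        formulas: dict | None = None,
                                        config: FitConfig | None = None) -> CurveTest:
    """Likelihood-ratio test that both groups share one zero-inflation curve."""
    config = config or FitConfig()
    group = np.asarray(group, int)
    y = np.asarray(y, float)
    d = (y == 0).astype(float)
    if d.sum() == 0 or d.sum() == d.size:
        return CurveTest(np.nan, np.nan, np.nan)
    n_groups = int(group.max())
    if formulas is None:
        full_formula = ParamFormula.default(gene_label, n_groups,
                                            basis_dim=config.basis_dim)
    else:
        full_formula = formulas[gene_label]
    shared = _null_formulas({gene_label: full_formula}, gene_label)[gene_label]
    full = fit_zero_inflation(d, full_formula, z, group, config)
    null = fit_zero_inflation(d, shared, z, group, config)
    if not (full.converged and null.converged):
        return CurveTest(np.nan, np.nan, np.nan)
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    df = max(full.edf(gene_label) - null.edf(gene_label), 0.5)
    return CurveTest(stat, df, float(stats.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# screening metrics


def _check_curves(curve_wt, curve_mut):
    a = np.asarray(curve_wt, float)
    b = np.asarray(curve_mut, float)
    if a.shape != b.shape:
        raise ValueError("curves must share one grid (equal lengths)")
    return a, b


def delta_rho_bar(curve_wt, curve_mut) -> float:
    """Mean absolute difference of two correlation curves on a shared grid."""
    a, b = _check_curves(curve_wt, curve_mut)
    return float(np.mean(np.abs(a - b)))


def max_abs_diff(curve_wt, curve_mut) -> float:
    """Maximum absolute difference between the two curves (at most 2)."""
    a, b = _check_curves(curve_wt, curve_mut)
    return float(np.max(np.abs(a - b)))


def aud(curve_wt, curve_mut, grid) -> float:
    """Area under the absolute difference curve over the grid span.

    On an evenly spaced grid this equals span * delta_rho_bar.
    """
    a, b = _check_curves(curve_wt, curve_mut)
    grid = np.asarray(grid, float)
    if grid.shape != a.shape:
        raise ValueError("grid must match the curves")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    span = float(grid[-1] - grid[0])
    return span * delta_rho_bar(a, b)


def shared_grid(z, group, n_time: int = 100, mode: str = "overlap") -> np.ndarray:
    """Evenly spaced pseudotime grid for cross-group curve comparison.

    ``overlap`` spans [max of group minima, min of group maxima] so neither
    group's curve is extrapolated; ``union`` spans the full range.
    """
    z = np.asarray(z, float)
    group = np.asarray(group, int)
    mins = [z[group == g].min() for g in np.unique(group)]
    maxs = [z[group == g].max() for g in np.unique(group)]
    if mode == "overlap":
        lo, hi = max(mins), min(maxs)
    elif mode == "union":
        lo, hi = min(mins), max(maxs)
    else:
        raise ValueError("mode must be 'overlap' or 'union'")
    if hi <= lo:
        raise ValueError("groups do not overlap in pseudotime")
    return np.linspace(lo, hi, n_time)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs propagate as NaN and do not count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
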