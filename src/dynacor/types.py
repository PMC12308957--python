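"""Domain types shared across the package.

The dataclasses here are thin, validated containers.  Numerical routines
operate on plain numpy arrays; the types exist so that single observations
and parameter sets can be passed around and validated explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Parameters modelled by the distributional regression, in the order used
#: for the concatenated coefficient vector (copula side first, then the two
#: zero-inflation rates which are fitted separately by penalized logistic
#: regression).
COPULA_PARAMS = ("mu1", "sigma1", "mu2", "sigma2", "rho")
ZI_PARAMS = ("p1", "p2")
ALL_PARAMS = COPULA_PARAMS + ZI_PARAMS

#: Canonical link for each parameter: positivity for the Gamma mean and CV,
#: Fisher-z (atanh) for the copula correlation, logit for zero-inflation.
PARAM_LINKS = {
    "mu1": "log", "sigma1": "log", "mu2": "log", "sigma2": "log",
    "rho": "atanh", "p1": "logit", "p2": "logit",
}


@dataclass(frozen=True)
class CellObservation:
    """One cell's pair of expression values with pseudotime and group."""

    y1: float
    y2: float
    z: float
    group: int = 1

    def __post_init__(self) -> None:
        for name in ("y1", "y2", "z"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.y1 < 0 or self.y2 < 0:
            raise ValueError("expression values must be non-negative")
        if self.group < 1:
            raise ValueError("groups are coded 1..G")


@dataclass(frozen=True)
class GammaParam:
    """Gamma marginal in the mean / coefficient-of-variation form.

    ``mu`` is the mean and ``sigma`` the coefficient of variation, so the
    implied shape is ``1/sigma**2`` and scale ``mu*sigma**2`` with
    ``E(W) = mu`` and ``Var(W) = sigma**2 * mu**2``.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.mu) <= 0) or np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("mu and sigma must be positive")

    @property
    def shape(self):
        return 1.0 / np.asarray(self.sigma) ** 2

    @property
    def scale(self):
        return np.asarray(self.mu) * np.asarray(self.sigma) ** 2


@dataclass(frozen=True)
class CellParams:
    """The seven distributional parameters at one cell.

    Fields may be scalars or equal-length arrays (one entry per cell).
    """

    gene1: GammaParam
    gene2: GammaParam
    rho: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if np.any(np.abs(np.asarray(self.rho)) >= 1):
            raise ValueError("|rho| must be < 1")
        for name in ("p1", "p2"):
            p = np.asarray(getattr(self, name))
            if np.any(p <= 0) or np.any(p >= 1):
                raise ValueError(f"{name} must lie strictly inside (0, 1)")

    @classmethod
    def from_arrays(cls, mu1, sigma1, mu2, sigma2, rho, p1, p2) -> "CellParams":
        return cls(GammaParam(mu1, sigma1), GammaParam(mu2, sigma2), rho, p1, p2)

    def as_dict(self) -> dict:
        return {
            "mu1": np.asarray(self.gene1.mu), "sigma1": np.asarray(self.gene1.sigma),
            "mu2": np.asarray(self.gene2.mu), "sigma2": np.asarray(self.gene2.sigma),
            "rho": np.asarray(self.rho),
            "p1": np.asarray(self.p1), "p2": np.asarray(self.p2),
        }


@dataclass(frozen=True)
class SmoothTermSpec:
    """Specification of one spline smooth in an additive predictor.

    ``by_group=True`` requests a separate smooth (with its own smoothing
    parameter) for every group, implementing group-specific trajectories.
    """

    covariate: str = "z"
    by_group: bool = False
    basis_dim: int = 10
    spline_type: str = "thin_plate"

    def __post_init__(self) -> None:
        if self.basis_dim < 3:
            raise ValueError("basis_dim must be >= 3")
        if self.spline_type != "thin_plate":
            raise NotImplementedError(
                "only thin plate regression splines are implemented"
            )


@dataclass(frozen=True)
class ParamFormula:
    """Additive-predictor formula for one distributional parameter.

    Mirrors the R-style call ``gene_j ~ group + s(z, by=group)``: an
    intercept (always present), optional group fixed effects, optional
    unpenalized linear terms, and penalized smooth terms.
    """

    parameter: str
    link: str | None = None
    include_group_intercept: bool = True
    linear_terms: tuple = ()
    smooth_terms: tuple = ()

    def __post_init__(self) -> None:
        if self.parameter not in ALL_PARAMS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        link = self.link or PARAM_LINKS[self.parameter]
        object.__setattr__(self, "link", link)
        if link != PARAM_LINKS[self.parameter]:
            raise ValueError(
                f"link {link!r} does not match the domain of {self.parameter}"
            )
        object.__setattr__(self, "linear_terms", tuple(self.linear_terms))
        object.__setattr__(self, "smooth_terms", tuple(self.smooth_terms))

    @classmethod
    def default(cls, parameter: str, n_groups: int, basis_dim: int = 10,
                shared_sigma_smooth: bool = False) -> "ParamFormula":
        """The two-group model: ``~ group + s(z, by=group)`` per parameter.

        With ``shared_sigma_smooth`` the CV parameters use a single smooth
        shared across groups and no group intercept.
        """
        if n_groups == 1:
            return cls(parameter, smooth_terms=(SmoothTermSpec(basis_dim=basis_dim),),
                       include_group_intercept=False)
        if shared_sigma_smooth and parameter in ("sigma1", "sigma2"):
            return cls(parameter, include_group_intercept=False,
                       smooth_terms=(SmoothTermSpec(basis_dim=basis_dim),))
        return cls(parameter,
                   smooth_terms=(SmoothTermSpec(by_group=True, basis_dim=basis_dim),))
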