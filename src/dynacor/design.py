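"""Link functions, per-parameter design matrices, and penalty assembly.

Each distributional parameter gets an additive predictor

    eta = intercept + group effects + linear terms + sum of smooths,

built column-by-column into a model matrix.  By-group smooths place each
group's spline block in disjoint columns, with rows of cells outside the
group set to zero, so every group has its own trajectory and its own
smoothing parameter.  Fixed effects (intercept, group dummies, linear terms)
are never penalized: the assembled penalty has exactly zero rows/columns at
their positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .smooths import TPRSBasis
from .types import ParamFormula

_LINKS = {
    "log": (np.log, np.exp, lambda x: x > 0),
    "atanh": (np.arctanh, np.tanh, lambda x: np.abs(x) < 1),
    "logit": (lambda p: np.log(p / (1.0 - p)),
              lambda e: 1.0 / (1.0 + np.exp(-e)),
              lambda x: (x > 0) & (x < 1)),
}


def link_apply(value, link: str):
    """Map a parameter value to its additive-predictor scale."""
    fwd, _, dom = _LINKS[link]
    value = np.asarray(value, dtype=float)
    if not np.all(dom(value)):
        raise ValueError(f"value outside the open domain of the {link} link")
    out = fwd(value)
    return out[()] if out.ndim == 0 else out


def link_invert(eta, link: str):
    """Map an additive predictor back into the parameter domain."""
    _, inv, _ = _LINKS[link]
    eta = np.asarray(eta, dtype=float)
    out = inv(eta)
    return out[()] if out.ndim == 0 else out


@dataclass
class TermInfo:
    """One column-block of a parameter's model matrix."""

    kind: str                     # "intercept" | "group" | "linear" | "smooth"
    label: str
    cols: np.ndarray              # column indices within the parameter design
    penalty: np.ndarray | None = None     # for smooth terms
    group: int | None = None              # for group dummies / by-group smooths
    basis: TPRSBasis | None = None
    covariate: str | None = None

    @property
    def penalized(self) -> bool:
        return self.penalty is not None


@dataclass
class ParamDesign:
    """Model matrix and term map for a single distributional parameter."""

    parameter: str
    link: str
    X: np.ndarray
    terms: list = field(default_factory=list)

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    def smooth_terms(self):
        return [t for t in self.terms if t.kind == "smooth"]

    def matrix_at(self, z, group: int) -> np.ndarray:
        """Model-matrix rows for new covariate values in a given group."""
        z = np.asarray(z, dtype=float)
        X = np.zeros((z.size, self.n_cols))
        for t in self.terms:
            if t.kind == "intercept":
                X[:, t.cols[0]] = 1.0
            elif t.kind == "group":
                X[:, t.cols[0]] = 1.0 if group == t.group else 0.0
            elif t.kind == "linear":
                X[:, t.cols[0]] = z
            elif t.kind == "smooth":
                if t.group is None or t.group == group:
                    X[:, t.cols] = t.basis.matrix(z)
        return X


@dataclass
class DesignSet:
    """Per-parameter designs plus the shared cell covariates."""

    params: dict
    z: np.ndarray
    group: np.ndarray
    n_groups: int

    def __getitem__(self, parameter: str) -> ParamDesign:
        return self.params[parameter]


def _build_param_design(formula: ParamFormula, z, group, n_groups,
                        basis_cache: dict, max_knots: int) -> ParamDesign:
    n = z.size
    cols: list[np.ndarray] = []
    terms: list[TermInfo] = []
    j = 0

    def add(block: np.ndarray, info_kwargs: dict) -> None:
        nonlocal j
        block = np.atleast_2d(block.T).T if block.ndim == 1 else block
        idx = np.arange(j, j + block.shape[1])
        cols.append(block)
        terms.append(TermInfo(cols=idx, **info_kwargs))
        j += block.shape[1]

    add(np.ones((n, 1)), dict(kind="intercept", label="intercept"))
    if formula.include_group_intercept and n_groups > 1:
        for g in range(2, n_groups + 1):
            add((group == g).astype(float)[:, None],
                dict(kind="group", label=f"group{g}", group=g))
    for cov in formula.linear_terms:
        if cov != "z":
            raise ValueError(f"unknown covariate {cov!r}")
        add(z[:, None], dict(kind="linear", label="z", covariate="z"))
    for st in formula.smooth_terms:
        if st.covariate != "z":
            raise ValueError(f"unknown covariate {st.covariate!r}")
        if st.by_group:
            for g in range(1, n_groups + 1):
                rows = group == g
                if not np.any(rows):
                    raise ValueError(f"group {g} has no cells")
                key = (g, st.basis_dim)
                if key not in basis_cache:
                    basis_cache[key] = TPRSBasis(z[rows], st.basis_dim,
                                                 max_knots=max_knots)
                basis = basis_cache[key]
                block = np.zeros((n, basis.n_cols))
                block[rows] = basis.matrix(z[rows])
                add(block, dict(kind="smooth", label=f"s(z):g{g}", group=g,
                                basis=basis, penalty=basis.penalty,
                                covariate="z"))
        else:
            key = (None, st.basis_dim)
            if key not in basis_cache:
                basis_cache[key] = TPRSBasis(z, st.basis_dim,
                                             max_knots=max_knots)
            basis = basis_cache[key]
            add(basis.matrix(z), dict(kind="smooth", label="s(z)", group=None,
                                      basis=basis, penalty=basis.penalty,
                                      covariate="z"))
    return ParamDesign(formula.parameter, formula.link,
                       np.column_stack(cols), terms)


def build_design(formulas, z, group=None, max_knots: int = 2000) -> DesignSet:
    """Build per-parameter model matrices for a set of formulas.

    Parameters
    ----------
    formulas:
        Sequence of :class:`ParamFormula`, one per modelled parameter.
    z:
        Pseudotime per cell (non-negative reals).
    group:
        Group labels coded ``1..G`` (group 1 is the reference / wild-type);
        ``None`` means a single group.
    """
    z = np.asarray(z, dtype=float)
    if group is None:
        group = np.ones(z.size, dtype=int)
    group = np.asarray(group, dtype=int)
    if group.size != z.size:
        raise ValueError("z and group must have equal length")
    labels = np.unique(group)
    n_groups = int(labels.max())
    if labels.min() < 1 or not np.array_equal(labels, np.arange(1, n_groups + 1)):
        raise ValueError(f"groups must be coded 1..G without gaps, got {labels}")
    basis_cache: dict = {}
    params = {}
    for f in formulas:
        if f.parameter in params:
            raise ValueError(f"duplicate formula for {f.parameter}")
        params[f.parameter] = _build_param_design(
            f, z, group, n_groups, basis_cache, max_knots)
    return DesignSet(params=params, z=z, group=group, n_groups=n_groups)


def penalized_blocks(design: DesignSet, order) -> list:
    """Flat list of (parameter, TermInfo, global column slice) for each
    penalized smooth block, with parameters stacked in ``order``."""
    out = []
    offset = 0
    for name in order:
        pd = design[name]
        for t in pd.terms:
            if t.penalized:
                out.append((name, t, t.cols + offset))
        offset += pd.n_cols
    return out


def total_cols(design: DesignSet, order) -> int:
    return sum(design[name].n_cols for name in order)


def assemble_penalty(design: DesignSet, lambdas, order=None) -> np.ndarray:
    """Block-diagonal penalty ``S = diag(lambda_b * D_b)`` on the stacked
    coefficient vector; fixed-effect rows/columns are exactly zero.

    ``lambdas`` holds one positive smoothing parameter per smooth block, in
    the order returned by :func:`penalized_blocks`.
    """
    if order is None:
        order = list(design.params)
    blocks = penalized_blocks(design, order)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size != len(blocks):
        raise ValueError(f"expected {len(blocks)} smoothing parameters, "
                         f"got {lambdas.size}")
    if np.any(lambdas <= 0):
        raise ValueError("smoothing parameters must be positive")
    p = total_cols(design, order)
    S = np.zeros((p, p))
    for lam, (_, t, gcols) in zip(lambdas, blocks):
        S[np.ix_(gcols, gcols)] = lam * t.penalty
    return S
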