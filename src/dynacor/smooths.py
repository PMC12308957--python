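"""Low-rank thin plate regression splines for one continuous covariate.

The construction follows the eigen-truncation idea: the full thin plate
spline problem on the knots (here, the unique covariate values, quantile
down-sampled above ``max_knots``) is

    min ||y - E d - T a||^2 + lam * d' E d,   subject to T' d = 0,

with ``E_ij = |x_i - x_j|^3 / 12`` (the 1-D Green's function whose quadratic
form is the integrated squared second derivative) and null space
``T = [1, x]``.  The coefficient vector ``d`` is restricted to the span of
the leading ``J`` eigenvectors of ``E`` (largest magnitude), the two null
space constraints are absorbed, and the constant is left to the model
intercept by column-centering.  The resulting basis has ``J - 1`` columns
(``J - 2`` penalized "wiggly" directions plus an unpenalized linear trend),
its penalty is positive semidefinite and annihilates straight lines.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space
from scipy.sparse.linalg import eigsh


def _tps_kernel(x, knots):
    """1-D thin plate (cubic) Green's function eta(r) = r^3 / 12."""
    r = np.abs(np.subtract.outer(np.asarray(x, float), np.asarray(knots, float)))
    return r**3 / 12.0


def _leading_eigs(E, k):
    """Leading-|eigenvalue| pairs of a symmetric matrix, deterministic signs."""
    n = E.shape[0]
    if n <= max(3 * k, 200):
        vals, vecs = np.linalg.eigh(E)
        order = np.argsort(-np.abs(vals))[:k]
        vals, vecs = vals[order], vecs[:, order]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = eigsh(E, k=k, which="LM", v0=v0)
        order = np.argsort(-np.abs(vals))
        vals, vecs = vals[order], vecs[:, order]
    # fix signs: largest-magnitude component of each eigenvector positive
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs


class TPRSBasis:
    """Thin plate regression spline basis for a vector of covariate values.

    Parameters
    ----------
    z_values:
        Covariate values the smooth will be trained on (defines the knots).
    basis_dim:
        Total basis dimension ``J`` of the underlying truncated spline; the
        matrix returned by :meth:`matrix` has ``J - 1`` columns because the
        constant is absorbed by the model intercept.
    max_knots:
        Knots are all unique covariate values up to this cap, beyond which a
        quantile subsample of this size is used (eigen-decomposition cost).
    """

    def __init__(self, z_values, basis_dim: int = 10, max_knots: int = 2000):
        z = np.asarray(z_values, dtype=float)
        uniq = np.unique(z)
        if uniq.size <= basis_dim:
            raise ValueError(
                f"basis_dim={basis_dim} requires more than {basis_dim} "
                f"distinct covariate values, got {uniq.size}")
        if uniq.size > max_knots:
            qs = np.linspace(0.0, 1.0, max_knots)
            knots = np.unique(np.quantile(uniq, qs))
        else:
            knots = uniq
        self.basis_dim = int(basis_dim)
        self.knots = knots
        E = _tps_kernel(knots, knots)
        vals, U = _leading_eigs(E, self.basis_dim)
        # absorb the null-space constraints T' d = 0, T = [1, x]
        T = np.column_stack([np.ones_like(knots), knots])
        C = T.T @ U                      # 2 x J
        Z = null_space(C)                # J x (J - 2)
        self._W = U @ Z                  # knot-coefficient map for wiggly part
        self._penalty_wiggly = (Z.T * vals) @ Z
        # raw (uncentered, unscaled) training matrix: wiggly columns + linear
        raw = np.column_stack([_tps_kernel(z, knots) @ self._W, z])
        self._col_means = raw.mean(axis=0)
        centered = raw - self._col_means
        scales = centered.std(axis=0)
        scales[scales <= 0] = 1.0
        self._col_scales = scales
        self._train_matrix = centered / scales
        # congruence-transform the penalty to the scaled coordinates
        S = np.zeros((raw.shape[1], raw.shape[1]))
        S[:-1, :-1] = self._penalty_wiggly
        D = S / np.outer(scales, scales)
        self._penalty = (D + D.T) / 2.0

    @property
    def n_cols(self) -> int:
        return self.basis_dim - 1

    @property
    def penalty(self) -> np.ndarray:
        """PSD penalty matrix; zero row/column for the linear trend."""
        return self._penalty

    def matrix(self, z=None) -> np.ndarray:
        """Model matrix (rows = values of ``z``, columns = basis functions).

        With ``z=None`` the (cached) training matrix is returned; its columns
        sum to zero, which is the identifiability constraint that leaves the
        constant to the intercept.
        """
        if z is None:
            return self._train_matrix
        z = np.asarray(z, dtype=float)
        raw = np.column_stack([_tps_kernel(z, self.knots) @ self._W, z])
        return (raw - self._col_means) / self._col_scales


def tprs_basis(z_values, basis_dim: int = 10, max_knots: int = 2000):
    """Convenience wrapper returning ``(basis matrix, penalty matrix)``."""
    b = TPRSBasis(z_values, basis_dim=basis_dim, max_knots=max_knots)
    return b.matrix(), b.penalty
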