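"""Cyclic cubic regression splines over day-of-year.

The basis uses the value-at-knots parametrization of periodic interpolating
cubic splines: with knots x_1 < ... < x_k on [d_min, d_max] and x_k
identified with x_1, a coefficient vector gamma in R^(k-1) holds the
function values at the first k-1 knots and the spline is the unique periodic
cubic interpolant.  The roughness penalty is the exact integrated squared
second derivative, S = D' B^{-1} D, where B and D are the cyclic banded
matrices linking knot values to knot second derivatives (B m = D gamma).

Periodicity of the value and first two derivatives at the domain endpoints is
built in, which is what pins the fitted phenology curve to a common level at
the start and end of the modelled season.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CyclicBasis:
    """Evaluation rule + quadratic penalty for a cyclic cubic spline basis.

    Attributes
    ----------
    knots : (k,) array, knots spanning [d_min, d_max]; the last knot is
        identified with the first, so the basis dimension is k - 1.
    penalty : (k-1, k-1) symmetric PSD matrix; gamma' S gamma equals the
        integral of the squared second derivative over one period.
    """

    knots: np.ndarray
    penalty: np.ndarray = field(repr=False)
    _F: np.ndarray = field(repr=False)  # B^{-1} D: knot values -> knot 2nd derivs

    @property
    def dim(self) -> int:
        return len(self.knots) - 1

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def design_matrix(self, x) -> np.ndarray:
        """Evaluate all basis functions at points ``x`` -> (n, k-1) matrix.

        Row i dotted with a coefficient vector gives the spline value at
        x[i].  Points are wrapped into the periodic domain.
        """
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain
        period = hi - lo
        xw = lo + np.mod(x - lo, period)
        knots = self.knots
        k = len(knots)
        j = np.clip(np.searchsorted(knots, xw, side="right") - 1, 0, k - 2)
        x0, x1 = knots[j], knots[j + 1]
        h = x1 - x0
        a_minus = (x1 - xw) / h
        a_plus = (xw - x0) / h
        # Interpolating-spline form on [x_j, x_{j+1}]:
        # f(x) = a_minus*g_j + a_plus*g_{j+1}
        #        - (x1-x)(x-x0)/6 * [(1 + a_minus) m_j + (1 + a_plus) m_{j+1}]
        w = (x1 - xw) * (xw - x0) / 6.0
        c_minus = -w * (1.0 + a_minus)
        c_plus = -w * (1.0 + a_plus)
        n = len(xw)
        dim = k - 1
        X = np.zeros((n, dim))
        jp1 = (j + 1) % dim
        np.add.at(X, (np.arange(n), j % dim), a_minus)
        np.add.at(X, (np.arange(n), jp1), a_plus)
        # second-derivative contributions couple every coefficient via F
        X += c_minus[:, None] * self._F[j % dim, :]
        X += c_plus[:, None] * self._F[jp1, :]
        return X

    def evaluate(self, coefs, x) -> np.ndarray:
        """Spline value(s) at x for coefficient vector(s) ``coefs``."""
        X = self.design_matrix(np.atleast_1d(x))
        return X @ np.asarray(coefs)


def build_cyclic_basis(domain: tuple[float, float] = (60.0, 304.0), n_knots: int = 12) -> CyclicBasis:
    """Construct a cyclic cubic regression spline basis.

    Parameters
    ----------
    domain : (d_min, d_max), the periodic day-of-year interval.
    n_knots : number of knots including both (identified) endpoints; the
        basis dimension is n_knots - 1.
    """
    if n_knots < 4:
        raise ValueError("cyclic cubic spline needs n_knots >= 4")
    lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        raise ValueError("domain length must be positive")
    knots = np.linspace(lo, hi, n_knots)
    h = np.diff(knots)  # (k-1,)
    dim = n_knots - 1
    B = np.zeros((dim, dim))
    D = np.zeros((dim, dim))
    for i in range(dim):
        h_prev = h[i - 1]  # wraps: interval ending at knot i
        h_next = h[i]
        ip1 = (i + 1) % dim
        im1 = (i - 1) % dim
        B[i, i] = (h_prev + h_next) / 3.0
        B[i, ip1] += h_next / 6.0
        B[i, im1] += h_prev / 6.0
        D[i, i] = -(1.0 / h_prev + 1.0 / h_next)
        D[i, ip1] += 1.0 / h_next
        D[i, im1] += 1.0 / h_prev
    F = np.linalg.solve(B, D)
    S = D.T @ F
    S = 0.5 * (S + S.T)  # symmetrize against round-off
    return CyclicBasis(knots=knots, penalty=S, _F=F)


def penalized_null_transform(basis: CyclicBasis) -> tuple[np.ndarray, np.ndarray]:
    """Reparametrize away the penalty null space (constants).

    Returns (U, lam): columns of U span the penalized subspace of the
    coefficient space and lam are the corresponding positive penalty
    eigenvalues, so that for delta = U' gamma the penalty is
    sum(lam * delta**2) and the constant function is excluded from the span.
    Used to combine an explicit intercept with smoothers without confounding.
    """
    w, V = np.linalg.eigh(basis.penalty)
    keep = w > w[-1] * 1e-10
    return V[:, keep], w[keep]
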