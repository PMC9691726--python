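"""Natural cubic smoothing splines in the value-space (Reinsch) formulation.

The smoother minimises

    sum_i w_i (y_i - f(t_i))^2 + lam * int f''(u)^2 du

over natural cubic splines with knots at the data points.  Following the
classic Green & Silverman formulation, the fitted values ``f`` at the knots
solve ``(W + lam K) f = W y`` with ``K = Q R^{-1} Q^T`` built from the knot
spacings, and the curve between knots is the natural cubic interpolant of
``f`` with second derivatives ``gamma = R^{-1} Q^T f``.

The penalty is exposed through a ``spar``-style smoothing parameter in
(0, 1), mapped monotonically onto ``lam`` the way R's ``smooth.spline``
does it: ``lam = r * 256**(3*spar - 1)`` where ``r`` balances the scales of
the fidelity and roughness terms.  ``spar -> 0`` approaches interpolation,
``spar -> 1`` approaches the least-squares line.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "spline_matrices",
    "spar_to_lambda",
    "fit_smoothing_spline",
    "spline_design",
    "evaluate_spline",
    "evaluate_spline_derivative",
]


def spline_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (K, G) for knot vector ``knots`` (strictly increasing, n >= 4).

    K is the n x n roughness matrix (f' K f = integrated squared second
    derivative of the natural interpolant); G maps fitted knot values to the
    interior second derivatives, ``gamma_interior = G @ f``.
    """
    t = np.asarray(knots, dtype=float)
    n = t.size
    if n < 4:
        raise ValueError(f"need at least 4 knots, got {n}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    h = np.diff(t)
    # Q: n x (n-2) second-difference matrix, R: (n-2) x (n-2) tridiagonal.
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        c = j - 1
        Q[j - 1, c] = 1.0 / h[j - 1]
        Q[j, c] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, c] = 1.0 / h[j]
        R[c, c] = (h[j - 1] + h[j]) / 3.0
        if c + 1 < n - 2:
            R[c, c + 1] = h[j] / 6.0
            R[c + 1, c] = h[j] / 6.0
    G = np.linalg.solve(R, Q.T)
    K = Q @ G
    # K is symmetric up to roundoff; enforce it.
    K = 0.5 * (K + K.T)
    return K, G


def spar_to_lambda(spar: float, weights: np.ndarray, K: np.ndarray) -> float:
    """Map the (0, 1) smoothing parameter onto the roughness penalty."""
    r = float(np.sum(weights)) / float(np.trace(K))
    return r * 256.0 ** (3.0 * float(spar) - 1.0)


def fit_smoothing_spline(
    knots: np.ndarray,
    values: np.ndarray,
    weights: np.ndarray,
    lam: float,
    matrices: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the smoother; returns (fitted knot values, interior 2nd derivs)."""
    t = np.asarray(knots, dtype=float)
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    K, G = spline_matrices(t) if matrices is None else matrices
    M = lam * K
    M[np.diag_indices_from(M)] += w
    f = np.linalg.solve(M, w * y)
    gamma = G @ f
    return f, gamma


def spline_design(
    knots: np.ndarray, query: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Linear maps from (knot values, interior gammas) to values/derivatives.

    Returns dense matrices (Af, Ag, Df, Dg) such that the spline and its
    first derivative at ``query`` are ``Af @ f + Ag @ gamma`` and
    ``Df @ f + Dg @ gamma``.  Outside the knot range the natural spline is
    linear (zero second derivative at and beyond the boundary knots).
    """
    t = np.asarray(knots, dtype=float)
    q = np.asarray(query, dtype=float)
    n = t.size
    m = q.size
    Af = np.zeros((m, n))
    Ag = np.zeros((m, n - 2))
    Df = np.zeros((m, n))
    Dg = np.zeros((m, n - 2))

    # gamma_full index j corresponds to interior column j-1 (gamma_0 = gamma_{n-1} = 0)
    def add_gamma(row: np.ndarray, j: int, coef: float) -> None:
        if 1 <= j <= n - 2:
            row[j - 1] += coef

    seg = np.clip(np.searchsorted(t, q, side="right") - 1, 0, n - 2)
    for k in range(m):
        i = seg[k]
        h = t[i + 1] - t[i]
        x = q[k]
        if x <= t[0]:
            # linear extrapolation with the boundary slope
            d_f = np.zeros(n)
            d_g = np.zeros(n - 2)
            # slope at t0 of the first cubic segment (gamma_0 = 0)
            d_f[0] = -1.0 / h
            d_f[1] = 1.0 / h
            add_gamma(d_g, 1, -h / 6.0)
            Af[k, 0] = 1.0
            Af[k] += (x - t[0]) * d_f
            Ag[k] += (x - t[0]) * d_g
            Df[k] = d_f
            Dg[k] = d_g
            continue
        if x >= t[-1]:
            h = t[-1] - t[-2]
            d_f = np.zeros(n)
            d_g = np.zeros(n - 2)
            d_f[-2] = -1.0 / h
            d_f[-1] = 1.0 / h
            add_gamma(d_g, n - 2, h / 6.0)
            Af[k, n - 1] = 1.0
            Af[k] += (x - t[-1]) * d_f
            Ag[k] += (x - t[-1]) * d_g
            Df[k] = d_f
            Dg[k] = d_g
            continue
        a = (t[i + 1] - x) / h  # weight of left knot
        b = (x - t[i]) / h
        Af[k, i] = a
        Af[k, i + 1] = b
        # value cubic terms
        add_gamma(Ag[k], i, (a**3 - a) * h * h / 6.0)
        add_gamma(Ag[k], i + 1, (b**3 - b) * h * h / 6.0)
        # derivative
        Df[k, i] = -1.0 / h
        Df[k, i + 1] = 1.0 / h
        add_gamma(Dg[k], i, -(3.0 * a * a - 1.0) * h / 6.0)
        add_gamma(Dg[k], i + 1, (3.0 * b * b - 1.0) * h / 6.0)
    return Af, Ag, Df, Dg


def evaluate_spline(
    knots: np.ndarray, f: np.ndarray, gamma: np.ndarray, query: np.ndarray
) -> np.ndarray:
    Af, Ag, _, _ = spline_design(knots, np.atleast_1d(query))
    return Af @ f + Ag @ gamma


def evaluate_spline_derivative(
    knots: np.ndarray, f: np.ndarray, gamma: np.ndarray, query: np.ndarray
) -> np.ndarray:
    _, _, Df, Dg = spline_design(knots, np.atleast_1d(query))
    return Df @ f + Dg @ gamma
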