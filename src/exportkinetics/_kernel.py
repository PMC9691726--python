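"""Numba-compiled numerical core.

Two pieces live here because they sit in the innermost loop of multi-start
fitting and profile likelihoods:

* an exponential integrator for the linear two-compartment cascade that is
  exact for piecewise-linear input sampled on a grid, and
* the full per-gene cost function (spline smoothing of the chromatin input,
  trajectory propagation, negative-binomial log-likelihood, nuisance
  priors) operating on pre-packed arrays.

A readable NumPy/SciPy implementation of the same cost lives in
:mod:`exportkinetics.likelihood`; the test suite asserts the two agree.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LN2 = math.log(2.0)

# prior hyperparameters (log2/minute scales, see likelihood.prior_logpdf)
SPAR_MU = 0.45
SPAR_VAR = 0.0025
SIGMA_T_VAR = 25.0
SIGMA_B_VAR = 0.01
CA0_VAR = 0.25

_C_SPAR = -0.5 * math.log(2.0 * math.pi * SPAR_VAR)
_C_ST = 0.5 * math.log(2.0 / (math.pi * SIGMA_T_VAR))
_C_SB = 0.5 * math.log(2.0 / (math.pi * SIGMA_B_VAR))
_C_CA0 = -0.5 * math.log(2.0 * math.pi * CA0_VAR)

_MU_FLOOR_COUNTS = 1e-6  # floor on predicted counts: finite penalty, never -inf
_SIGMA2_CAP = 200.0
_SLOPE_CAP = 1e6


@njit(cache=True)
def _phi_psi(k: float, h: float) -> tuple[float, float]:
    """phi = int_0^h e^{-k(h-s)} ds, psi = int_0^h e^{-k(h-s)} s ds (stable)."""
    u = k * h
    if u > 1e-4:
        phi = -math.expm1(-u) / k
        psi = (h - phi) / k
    else:
        phi = h * (1.0 - 0.5 * u + u * u / 6.0)
        psi = h * h * (0.5 - u / 6.0 + u * u / 24.0)
    return phi, psi


@njit(cache=True)
def integrate_linear_cascade(t, x, k1, k2, k2p, kd, y0, z0):
    """Propagate dy/dt = k1 x - k2 y, dz/dt = k2p y - kd z on grid t.

    x is taken piecewise-linear between grid points, for which the update is
    exact (segment-wise variation of constants with closed-form integrals).
    """
    n = t.size
    y = np.empty(n)
    z = np.empty(n)
    y[0] = y0
    z[0] = z0
    yi = y0
    zi = z0
    for i in range(n - 1):
        h = t[i + 1] - t[i]
        a = x[i]
        b = (x[i + 1] - x[i]) / h
        E2 = math.exp(-k2 * h)
        Ed = math.exp(-kd * h)
        phi2, psi2 = _phi_psi(k2, h)
        phid, psid = _phi_psi(kd, h)
        # eta = (e^{-k2 h} - e^{-kd h})/(kd - k2) = e^{-kd h} h exprel((kd-k2) h)
        u = (kd - k2) * h
        if abs(u) > 1e-6:
            eta = Ed * math.expm1(u) / (kd - k2)
        else:
            eta = Ed * h * (1.0 + 0.5 * u + u * u / 6.0)
        # on the segment y(s) = A + B s + C e^{-k2 s}
        A = k1 * (a - b / k2) / k2
        B = k1 * b / k2
        C = yi - A
        ynew = yi * E2 + k1 * (a * phi2 + b * psi2)
        znew = zi * Ed + k2p * (A * phid + B * psid + C * eta)
        yi = ynew
        zi = znew
        y[i + 1] = yi
        z[i + 1] = zi
    return y, z


@njit(cache=True)
def _nb_loglik(count: float, c_med: float, sigma2: float, variant: int) -> float:
    """Negative-binomial log-pmf of an observed count.

    c_med is the median of the latent log-normal count intensity (predicted
    FPKM scaled to counts); the distribution mean is mu = c_med e^{sigma2/2}.
    variant 0: exact Gamma-Poisson mixture, theta = mu * (e^{sigma2} - 1).
    variant 1: the as-printed form, theta = mu * (e^{sigma2} - 1) * sigma2/2.
    """
    if sigma2 > _SIGMA2_CAP:
        sigma2 = _SIGMA2_CAP
    if c_med < _MU_FLOOR_COUNTS:
        c_med = _MU_FLOOR_COUNTS
    mu = c_med * math.exp(0.5 * sigma2)
    if sigma2 < 1e-10:
        # Poisson limit
        return count * math.log(mu) - mu - math.lgamma(count + 1.0)
    em1 = math.expm1(sigma2)
    r = 1.0 / em1
    theta = mu * em1
    if variant == 1:
        theta *= 0.5 * sigma2
    log1pt = math.log1p(theta)
    return (
        math.lgamma(count + r)
        - math.lgamma(r)
        - math.lgamma(count + 1.0)
        - r * log1pt
        + count * (math.log(theta) - log1pt)
    )


@njit(cache=True)
def cost_kernel(
    p,  # [l10k1, l10k2, l10k2p, l10kd, spar, sigma_t, sigma_b, (ca0_log2)]
    has_ca0,  # 0/1
    yk,  # log2(caFPKM + pc) at the chromatin timepoints
    ca_slope,  # data-derived ln-slope at the chromatin points (for weights)
    K,  # roughness matrix (nk x nk)
    G,  # gamma = G @ f
    trK,
    Af,
    Ag,  # fine-grid spline design
    pc_ca,  # chromatin pseudocount, FPKM units
    grid,  # fine time grid (contains all observation times)
    np_idx,
    np_counts,
    np_scale,
    cyto_idx,
    cyto_counts,
    cyto_scale,
    Dk_f,
    Dk_g,  # spline derivative design at the chromatin timepoints
    ca_counts,
    ca_scale,
    ca0_mu,
    variant,
):
    l10k1 = p[0]
    l10k2 = p[1]
    l10k2p = p[2]
    l10kd = p[3]
    spar = p[4]
    sigma_t = p[5]
    sigma_b = p[6]
    k1 = 10.0**l10k1
    k2 = 10.0**l10k2
    k2p = 10.0**l10k2p
    kd = 10.0**l10kd

    nk = yk.size
    ykw = yk.copy()
    if has_ca0 == 1:
        ykw[0] = p[7]

    # chromatin spline at the current nuisance parameters
    sb2 = sigma_b * sigma_b
    st2 = sigma_t * sigma_t
    w = np.empty(nk)
    wsum = 0.0
    for i in range(nk):
        w[i] = 1.0 / (sb2 + ca_slope[i] * ca_slope[i] * st2)
        wsum += w[i]
    lam = (wsum / trK) * 256.0 ** (3.0 * spar - 1.0)
    M = lam * K
    rhs = np.empty(nk)
    for i in range(nk):
        M[i, i] += w[i]
        rhs[i] = w[i] * ykw[i]
    f = np.linalg.solve(M, rhs)
    gam = G @ f
    lf = Af @ f + Ag @ gam

    m = grid.size
    x = np.empty(m)
    for i in range(m):
        v = 2.0 ** lf[i] - pc_ca
        x[i] = v if v > 0.0 else 0.0

    y0 = k1 * x[0] / k2
    z0 = k2p * y0 / kd
    y, z = integrate_linear_cascade(grid, x, k1, k2, k2p, kd, y0, z0)

    loglik = 0.0
    # chromatin term: the spline is the model's prediction for this fraction
    if ca_counts.size > 0:
        dlf = Dk_f @ f + Dk_g @ gam  # d log2 / dt at the knots
        for j in range(ca_counts.size):
            i0 = j + has_ca0  # knot row (knot 0 is the ca0 parameter if present)
            g = 2.0 ** f[i0] - pc_ca
            if g < 1e-300:
                g = 1e-300
            slope = dlf[i0] * 0.6931471805599453
            if slope > _SLOPE_CAP:
                slope = _SLOPE_CAP
            elif slope < -_SLOPE_CAP:
                slope = -_SLOPE_CAP
            s2 = sb2 + slope * slope * st2
            loglik += _nb_loglik(ca_counts[j], g * ca_scale[j], s2, variant)
    for j in range(np_idx.size):
        i = np_idx[j]
        g = y[i]
        if g < 1e-300:
            g = 1e-300
        slope = (k1 * x[i] - k2 * g) / g
        if slope > _SLOPE_CAP:
            slope = _SLOPE_CAP
        elif slope < -_SLOPE_CAP:
            slope = -_SLOPE_CAP
        s2 = sb2 + slope * slope * st2
        loglik += _nb_loglik(np_counts[j], g * np_scale[j], s2, variant)
    for j in range(cyto_idx.size):
        i = cyto_idx[j]
        g = z[i]
        if g < 1e-300:
            g = 1e-300
        slope = (k2p * y[i] - kd * g) / g
        if slope > _SLOPE_CAP:
            slope = _SLOPE_CAP
        elif slope < -_SLOPE_CAP:
            slope = -_SLOPE_CAP
        s2 = sb2 + slope * slope * st2
        loglik += _nb_loglik(cyto_counts[j], g * cyto_scale[j], s2, variant)

    # nuisance priors
    logprior = _C_SPAR - (spar - SPAR_MU) ** 2 / (2.0 * SPAR_VAR)
    logprior += _C_ST - sigma_t * sigma_t / (2.0 * SIGMA_T_VAR)
    logprior += _C_SB - sigma_b * sigma_b / (2.0 * SIGMA_B_VAR)
    if has_ca0 == 1:
        logprior += _C_CA0 - (p[7] - ca0_mu) ** 2 / (2.0 * CA0_VAR)

    return -loglik - logprior
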