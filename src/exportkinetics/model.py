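"""Two-compartment model of mRNA flow from chromatin to cytoplasm.

The measured chromatin-associated signal x(t) (caFPKM) drives the
nucleoplasmic signal y(t) (npFPKM) and the cytoplasmic signal z(t)
(cytoFPKM):

    dy/dt = k1' * x(t) - k2 * y
    dz/dt = k2' * y    - k_cyto_deg * z

All four rate constants are fractional rates in FPKM-ratio units per
minute; the unknown per-fraction normalisation factors of the underlying
absolute copy-number model are folded into k1' and k2' and are not
separately estimable.  Three algebraically equivalent parameterizations are
supported so that profile likelihoods can be computed for the composite
quantities chromatin-release efficiency (k1'/k2), export efficiency
(k2'/k2) and the effective transport rate (k1'*k2'/k2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import smoothing
from ._kernel import integrate_linear_cascade

__all__ = [
    "KineticParams",
    "ChromatinInput",
    "interpolate_chromatin",
    "simulate",
    "simulate_reparam_efficiency",
    "simulate_reparam_effective",
    "steady_state",
    "analytic_step_response",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class KineticParams:
    """The four rate constants of the transport model.

    k1_prime : (npFPKM/caFPKM)/min, chromatin -> nucleoplasm appearance
    k2 : 1/min, total disappearance from the nucleoplasm (export + decay)
    k2_prime : (cytoFPKM/npFPKM)/min, nucleoplasm -> cytoplasm appearance
    k_cyto_deg : 1/min, cytoplasmic degradation
    """

    k1_prime: float
    k2: float
    k2_prime: float
    k_cyto_deg: float

    def __post_init__(self) -> None:
        for name in ("k1_prime", "k2", "k2_prime", "k_cyto_deg"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {v}")

    # ---- derived composite parameters -------------------------------------
    @property
    def chromatin_release_efficiency(self) -> float:
        """k1'/k2, npFPKM/caFPKM."""
        return self.k1_prime / self.k2

    @property
    def export_efficiency(self) -> float:
        """k2'/k2, cytoFPKM/npFPKM."""
        return self.k2_prime / self.k2

    @property
    def effective_transport(self) -> float:
        """k1'*k2'/k2, the chromatin-to-cytoplasm rate constant, (cytoFPKM/caFPKM)/min."""
        return self.k1_prime * self.k2_prime / self.k2

    @property
    def half_life(self) -> float:
        """Cytoplasmic mRNA half-life ln(2)/k_cyto_deg, minutes."""
        return LN2 / self.k_cyto_deg

    # ---- alternative parameterizations ------------------------------------
    @classmethod
    def from_efficiency(
        cls, k2: float, release_efficiency: float, export_efficiency: float, k_cyto_deg: float
    ) -> "KineticParams":
        """Build from (k2, k1'/k2, k2'/k2, k_cyto_deg)."""
        return cls(release_efficiency * k2, k2, export_efficiency * k2, k_cyto_deg)

    @classmethod
    def from_effective(
        cls, k2: float, effective_transport: float, export_efficiency: float, k_cyto_deg: float
    ) -> "KineticParams":
        """Build from (k2, k1'*k2'/k2, k2'/k2, k_cyto_deg)."""
        return cls(
            effective_transport / export_efficiency, k2, export_efficiency * k2, k_cyto_deg
        )

    def to_log10_array(self) -> np.ndarray:
        return np.log10([self.k1_prime, self.k2, self.k2_prime, self.k_cyto_deg])

    @classmethod
    def from_log10_array(cls, arr: Sequence[float]) -> "KineticParams":
        k1, k2, k2p, kd = (10.0 ** float(a) for a in arr)
        return cls(k1, k2, k2p, kd)


@dataclass
class ChromatinInput:
    """Smoothed chromatin-associated expression used to drive the ODEs.

    The smoothing spline is fitted to log2(FPKM + pseudocount); on
    evaluation the curve is exponentiated, the pseudocount removed and the
    result clipped at zero.
    """

    knots: np.ndarray
    log2_values: np.ndarray  # fitted log2(FPKM + pc) at the knots
    gamma: np.ndarray  # interior second derivatives of the spline
    spar: float
    lam: float
    pseudocount_fpkm: float = 0.0
    _design_cache: dict = field(default_factory=dict, repr=False)

    def log2_curve(self, t: np.ndarray) -> np.ndarray:
        return smoothing.evaluate_spline(self.knots, self.log2_values, self.gamma, np.atleast_1d(t))

    def evaluate(self, t: np.ndarray | float) -> np.ndarray:
        """caFPKM at times t (>= 0, pseudocount removed)."""
        val = 2.0 ** self.log2_curve(np.atleast_1d(t)) - self.pseudocount_fpkm
        return np.clip(val, 0.0, None)

    __call__ = evaluate

    def dlog_dt(self, t: np.ndarray | float) -> np.ndarray:
        """d ln(FPKM + pc)/dt, used as the error-model slope for chromatin."""
        d = smoothing.evaluate_spline_derivative(
            self.knots, self.log2_values, self.gamma, np.atleast_1d(t)
        )
        return d * LN2


def interpolate_chromatin(
    times: np.ndarray,
    fpkm: np.ndarray,
    spar: float = 0.45,
    weights: np.ndarray | None = None,
    pseudocount_fpkm: float = 0.0,
) -> ChromatinInput:
    """Fit the weighted smoothing spline to a chromatin time course.

    ``times``/``fpkm`` are the observed chromatin points; ``weights`` default
    to 1 and would normally be the inverse error-model variance of each
    point.  At least 4 timepoints are required.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(fpkm, dtype=float)
    if t.size < 4:
        raise ValueError(f"chromatin interpolation needs >= 4 timepoints, got {t.size}")
    if weights is None:
        weights = np.ones_like(t)
    w = np.asarray(weights, dtype=float)
    y = np.log2(v + pseudocount_fpkm)
    K, G = smoothing.spline_matrices(t)
    lam = smoothing.spar_to_lambda(spar, w, K)
    f, gamma = smoothing.fit_smoothing_spline(t, y, w, lam, matrices=(K, G))
    return ChromatinInput(
        knots=t,
        log2_values=f,
        gamma=gamma,
        spar=float(spar),
        lam=float(lam),
        pseudocount_fpkm=float(pseudocount_fpkm),
    )


def _input_on_grid(
    x: "ChromatinInput | Callable | float", grid: np.ndarray
) -> np.ndarray:
    if isinstance(x, ChromatinInput):
        return x.evaluate(grid)
    if callable(x):
        return np.clip(np.asarray([float(x(t)) for t in grid]), 0.0, None)
    return np.full(grid.size, float(x))


def _resolve_init(
    params: KineticParams, x0: float, init: "str | tuple[float, float]"
) -> tuple[float, float]:
    if isinstance(init, str):
        if init != "steady_state":
            raise ValueError(f"unknown init {init!r}")
        return steady_state(params, x0)
    y0, z0 = init
    return float(y0), float(z0)


def simulate(
    params: KineticParams,
    x: "ChromatinInput | Callable | float",
    times: np.ndarray,
    init: "str | tuple[float, float]" = "steady_state",
    grid_step: float = 0.5,
    method: str = "exact",
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the two ODEs driven by x over ``times``; returns (y, z).

    ``method="exact"`` samples the input on a fine grid (``grid_step``
    minutes, plus all requested times) and propagates the linear system with
    an exponential integrator that is exact for piecewise-linear input.
    ``method="lsoda"`` uses an adaptive scipy solver on the continuous input
    (rtol 1e-8, atol 1e-10) and exists mainly as an independent check of the
    fast path.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty time vector")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    t0 = min(0.0, t[0])
    grid = np.union1d(np.arange(t0, t[-1] + grid_step, grid_step), t)
    grid = grid[grid <= t[-1] + 1e-12]
    xg = _input_on_grid(x, grid)
    y0, z0 = _resolve_init(params, xg[0], init)

    if method == "exact":
        y, z = integrate_linear_cascade(
            grid, xg, params.k1_prime, params.k2, params.k2_prime, params.k_cyto_deg, y0, z0
        )
        idx = np.searchsorted(grid, t)
        return y[idx], z[idx]
    if method == "lsoda":
        from scipy.integrate import solve_ivp

        if isinstance(x, ChromatinInput):
            xf = lambda s: float(x.evaluate(s)[0])
        elif callable(x):
            xf = lambda s: float(x(s))
        else:
            xf = lambda s: float(x)

        def rhs(s, state):
            y, z = state
            return [
                params.k1_prime * xf(s) - params.k2 * y,
                params.k2_prime * y - params.k_cyto_deg * z,
            ]

        sol = solve_ivp(
            rhs,
            (t0, t[-1]),
            [y0, z0],
            method="LSODA",
            t_eval=t,
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed for params {params}: {sol.message}"
            )
        return sol.y[0], sol.y[1]
    raise ValueError(f"unknown method {method!r}")


def simulate_reparam_efficiency(
    params: dict,
    x,
    times: np.ndarray,
    init="steady_state",
    **kw,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate in the (k2, k1'/k2, k2'/k2, k_cyto_deg) parameterization.

    dy/dt = k2 * (k1'/k2) * x - k2 * y ; dz/dt = k2 * (k2'/k2) * y - kd * z.
    Identical trajectories to :func:`simulate` for equivalent parameters.
    """
    p = KineticParams.from_efficiency(
        params["k2"],
        params["release_efficiency"],
        params["export_efficiency"],
        params["k_cyto_deg"],
    )
    return simulate(p, x, times, init=init, **kw)


def simulate_reparam_effective(
    params: dict,
    x,
    times: np.ndarray,
    init="steady_state",
    **kw,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate in the (k2, k1'k2'/k2, k2'/k2, k_cyto_deg) parameterization.

    dy/dt = (k1'k2'/k2) / (k2'/k2) * x - k2 * y ; dz/dt = k2 * (k2'/k2) * y - kd * z.
    """
    p = KineticParams.from_effective(
        params["k2"],
        params["effective_transport"],
        params["export_efficiency"],
        params["k_cyto_deg"],
    )
    return simulate(p, x, times, init=init, **kw)


def steady_state(params: KineticParams, x0: float) -> tuple[float, float]:
    """Fixed point of the ODEs under constant input x0.

    y_ss = (k1'/k2) x0 and z_ss = (k1'k2'/k2)/k_cyto_deg * x0.
    """
    if x0 < 0:
        raise ValueError("x0 must be >= 0")
    y_ss = params.chromatin_release_efficiency * x0
    z_ss = params.effective_transport / params.k_cyto_deg * x0
    return y_ss, z_ss


def analytic_step_response(
    params: KineticParams, x1: float, t: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form response to a constant input x1 from zero initial state.

    y(t) = (k1'/k2) x1 (1 - e^{-k2 t});
    z(t) = k2' (k1'/k2) x1 [ (1-e^{-kd t})/kd - (e^{-k2 t} - e^{-kd t})/(kd - k2) ].

    The confluent case k2 == k_cyto_deg is evaluated through the limit
    t e^{-k t} of the second bracket term, keeping the expression continuous
    in the parameters.
    """
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    k1, k2, k2p, kd = params.k1_prime, params.k2, params.k2_prime, params.k_cyto_deg
    Y = k1 * x1 / k2
    y = Y * -np.expm1(-k2 * tt)
    # eta(t) = (e^{-k2 t} - e^{-kd t})/(kd - k2); near the confluent case the
    # difference cancels, so switch to the series e^{-kd t} t (1 + u/2 + u^2/6)
    u = (kd - k2) * tt
    small = np.abs(u) < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        direct = (np.exp(-k2 * tt) - np.exp(-kd * tt)) / np.where(u == 0.0, 1.0, kd - k2)
    series = np.exp(-kd * tt) * tt * (1.0 + u / 2.0 + u * u / 6.0)
    eta = np.where(small, series, direct)
    z = k2p * Y * (-np.expm1(-kd * tt) / kd - eta)
    return y, z
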