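"""Responsiveness and abundance of induced genes under the transport model.

Responsiveness is the time for cytoplasmic mRNA to reach half of its
maximal increase after stimulation.  Simulating a step increase of the
chromatin input from basal steady state over grids of transport and decay
rates maps out the regimes in which responsiveness is set by the
cytoplasmic half-life (fast transport: t_half -> ln2/k_cyto_deg) versus by
nuclear steps, and how peak cytoplasmic abundance scales as
effective_transport / k_cyto_deg under sustained input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import KineticParams, simulate, steady_state

__all__ = [
    "StepInput",
    "ResponsivenessResult",
    "time_to_half_induction",
    "responsiveness_grid",
    "peak_abundance_grid",
]


@dataclass(frozen=True)
class StepInput:
    """Chromatin input stepping from ``basal`` to ``induced`` at t = 0."""

    basal: float
    induced: float

    def __post_init__(self) -> None:
        if self.basal < 0 or self.induced < 0:
            raise ValueError("input levels must be >= 0")


@dataclass
class ResponsivenessResult:
    t_half_induction: float  # minutes; NaN when non-responsive
    peak_z: float
    peak_time: float
    responsive: bool


def time_to_half_induction(
    params: KineticParams,
    input_profile: StepInput,
    horizon: float = 2000.0,
    grid_step: float = 0.25,
) -> ResponsivenessResult:
    """Time at which z(t) first reaches halfway between basal and its peak.

    The system starts at the basal steady state and is driven by the
    induced input level; the crossing is linearly interpolated between
    simulation grid points.  A step that never lifts z above baseline is
    reported non-responsive.
    """
    times = np.arange(0.0, horizon + grid_step, grid_step)
    _, z0 = steady_state(params, input_profile.basal)
    y0 = params.chromatin_release_efficiency * input_profile.basal
    _, z = simulate(
        params, input_profile.induced, times, init=(y0, z0), grid_step=grid_step
    )
    ipk = int(np.argmax(z))
    peak = float(z[ipk])
    if peak <= z0 * (1.0 + 1e-12) or input_profile.induced <= input_profile.basal:
        return ResponsivenessResult(np.nan, peak, float(times[ipk]), False)
    target = z0 + 0.5 * (peak - z0)
    above = np.nonzero(z >= target)[0]
    i = int(above[0])
    if i == 0:
        t_half = 0.0
    else:
        f = (target - z[i - 1]) / (z[i] - z[i - 1])
        t_half = float(times[i - 1] + f * (times[i] - times[i - 1]))
    return ResponsivenessResult(t_half, peak, float(times[ipk]), True)


def responsiveness_grid(
    k2_prime_grid: np.ndarray,
    k_cyto_deg_grid: np.ndarray,
    k1_prime: float = 0.2,
    k2: float = 0.2,
    input_profile: StepInput = StepInput(1.0, 10.0),
    horizon: float = 2000.0,
) -> np.ndarray:
    """Matrix of t_half_induction, rows = k2' values, cols = k_cyto_deg values."""
    k2p = np.asarray(k2_prime_grid, dtype=float)
    kd = np.asarray(k_cyto_deg_grid, dtype=float)
    if np.any(k2p <= 0) or np.any(kd <= 0):
        raise ValueError("grids must be positive")
    out = np.empty((k2p.size, kd.size))
    for i, a in enumerate(k2p):
        for j, b in enumerate(kd):
            p = KineticParams(k1_prime, k2, a, b)
            out[i, j] = time_to_half_induction(p, input_profile, horizon=horizon).t_half_induction
    return out


def peak_abundance_grid(
    effective_transport_grid: np.ndarray,
    k_cyto_deg_grid: np.ndarray,
    input_profile: StepInput = StepInput(1.0, 10.0),
    horizon: float = 2000.0,
    k2: float = 0.2,
    export_efficiency: float = 0.5,
) -> np.ndarray:
    """Peak cytoplasmic abundance over (effective transport, decay) grids.

    Under sustained input the peak is the new steady state
    z = effective_transport / k_cyto_deg * x, so rows scale linearly with
    the effective transport rate and inversely with the decay rate; ``k2``
    and ``export_efficiency`` only shape the transient.
    """
    eff = np.asarray(effective_transport_grid, dtype=float)
    kd = np.asarray(k_cyto_deg_grid, dtype=float)
    if np.any(eff <= 0) or np.any(kd <= 0):
        raise ValueError("grids must be positive")
    out = np.empty((eff.size, kd.size))
    for i, a in enumerate(eff):
        for j, b in enumerate(kd):
            p = KineticParams.from_effective(k2, a, export_efficiency, b)
            out[i, j] = time_to_half_induction(p, input_profile, horizon=horizon).peak_z
    return out
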