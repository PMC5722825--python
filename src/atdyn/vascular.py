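"""Tumour dynamics with a treatment-sensitive vascular carrying capacity.

Extends the non-spatial model with the angiogenesis feedback of the
Hahnfeldt tumour-vasculature model: the Gompertz carrying capacity ``K``
is itself dynamic,

    dW/dt = lambda_W * W * log(K/N),
    dR/dt = lambda_R * f(R/N) * R * log(K/N),
    dK/dt = b*N - d*N^(2/3)*K,

with ``b`` the strength of tumour-derived vascular stimulation and ``d``
that of inhibition (the 2/3 exponent arises from inhibitor diffusion from
the surface of a three-dimensional tumour).  Note the un-normalised
Gompertz exponent ``log(K/N)`` — deliberately different from the
normalised form in :mod:`atdyn.nonspatial`.  A bolus both kills cells
(per-subpopulation IC50s) and knocks down the vasculature, multiplying
``K`` by ``1/(1 + dose/IC50_K)``.

With cells frozen at size ``N`` the carrying capacity relaxes to the
quasi-steady value ``K* = (b/d) * N^(1/3)``.

Default ``b`` and ``d`` derive from the published Hahnfeldt Lewis-lung
fit (5.85/day and 0.00873/day/mm^2), with ``d`` converted from tumour
volume in mm^3 to cell number at 1e6 cells/mm^3
(``d_cells = 0.00873 / (1e6)^(2/3)``); both are configurable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .fitness import FitnessFunctionSpec, eval_fitness
from .nonspatial import (
    LETHAL_BURDEN,
    DrugResponse,
    GrowthParams,
    Trajectory,
    TreatmentSchedule,
    apply_bolus,
    at_update_dose,
    os_time,
    pfs_time,
)

__all__ = [
    "VascularParams",
    "vascular_derivatives",
    "apply_bolus_with_vasculature",
    "simulate_vascular",
    "regimen_grid",
]


@dataclass(frozen=True)
class VascularParams:
    """Vascular stimulation/inhibition strengths and treatment sensitivity."""

    b: float = 5.85
    d: float = 0.00873 / 1e4  # mm^3-based fit converted to cells (1e6 cells/mm^3)
    ic50_K: float = 1.0
    K_init: float = 2e9

    def __post_init__(self):
        if self.ic50_K <= 0 or self.K_init <= 0:
            raise ValueError("ic50_K and K_init must be positive")
        if self.b < 0 or self.d < 0:
            raise ValueError("b and d must be non-negative")

    def steady_K(self, N: float) -> float:
        """Quasi-steady carrying capacity (b/d) * N^(1/3) for fixed N."""
        return (self.b / self.d) * N ** (1.0 / 3.0)


def vascular_derivatives(
    state: Tuple[float, float, float],
    growth: GrowthParams,
    fitness: FitnessFunctionSpec,
    vasc: VascularParams,
) -> Tuple[float, float, float]:
    """(dW/dt, dR/dt, dK/dt) of the vascular-feedback model."""
    W, R, K = state
    if W < 0 or R < 0:
        raise ValueError("populations must be non-negative")
    if K <= 0:
        raise ValueError("carrying capacity must stay positive")
    N = W + R
    if N == 0:
        return 0.0, 0.0, 0.0
    f = eval_fitness(fitness, min(R / N, 1.0))
    g = math.log(K / N)
    dW = growth.lambda_W * W * g
    dR = growth.lambda_R * f * R * g
    dK = vasc.b * N - vasc.d * N ** (2.0 / 3.0) * K
    return dW, dR, dK


def apply_bolus_with_vasculature(
    state: Tuple[float, float, float],
    dose: float,
    response: DrugResponse,
    vasc: VascularParams,
) -> Tuple[float, float, float]:
    """Bolus kill of both subpopulations plus vascular knock-down of K."""
    W, R, K = state
    W2, R2 = apply_bolus((W, R), dose, response)
    return W2, R2, K / (1.0 + dose / vasc.ic50_K)


def _integrate(y0, t0, t1, growth, fitness, vasc, record_dt, rtol):
    def rhs(t, y):
        W = max(y[0], 0.0)
        R = max(y[1], 0.0)
        K = max(y[2], 1e-300)
        return vascular_derivatives((W, R, K), growth, fitness, vasc)

    n_rec = max(int(math.ceil((t1 - t0) / record_dt)), 2)
    t_eval = np.linspace(t0, t1, n_rec + 1)
    sol = solve_ivp(
        rhs, (t0, t1), y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=1e-6
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"ODE integration failed near t={t0:.3f} d: {sol.message}")
    return sol.t, sol.y.T


def simulate_vascular(
    growth: GrowthParams,
    response: DrugResponse,
    vasc: VascularParams,
    schedule: TreatmentSchedule,
    fitness: FitnessFunctionSpec,
    initial_resistant_frequency: float = 0.0,
    horizon_days: float = 1000.0,
    record_dt: float = 1.0,
    rtol: float = 1e-8,
    lethal_burden: float = LETHAL_BURDEN,
) -> Trajectory:
    """Simulate bolus therapy in the vascular-feedback model.

    Same contract as :func:`atdyn.nonspatial.simulate` with the extended
    (W, R, K) state; the trajectory records ``K`` at every stored time.
    """
    q0 = initial_resistant_frequency
    if not 0.0 <= q0 < 1.0:
        raise ValueError("initial resistant frequency must lie in [0, 1)")
    y = np.array([growth.N0 * (1.0 - q0), growth.N0 * q0, vasc.K_init])
    times = [0.0]
    states = [y.copy()]
    bolus_times, doses = [], []

    if schedule.regime == "none":
        seg_t, seg_y = _integrate(
            y, 0.0, horizon_days, growth, fitness, vasc, record_dt, rtol
        )
        times.extend(seg_t[1:])
        states.extend(seg_y[1:])
    else:
        dose = (
            schedule.rho_MTD * schedule.at_initial_fraction
            if schedule.regime == "AT"
            else schedule.rho_MTD
        )
        t = 0.0
        N_prev_pre = growth.N0
        while t < horizon_days:
            bolus_times.append(t)
            doses.append(dose)
            y = np.array(
                apply_bolus_with_vasculature((y[0], y[1], y[2]), dose, response, vasc)
            )
            times.append(t)
            states.append(y.copy())
            t_next = min(t + schedule.cycle, horizon_days)
            seg_t, seg_y = _integrate(
                y, t, t_next, growth, fitness, vasc, record_dt, rtol
            )
            times.extend(seg_t[1:])
            states.extend(seg_y[1:])
            y = seg_y[-1].copy()
            t = t_next
            N_now = y[0] + y[1]
            if N_now >= lethal_burden:
                break
            if schedule.regime == "AT" and t < horizon_days:
                dose = at_update_dose(dose, N_now, N_prev_pre, schedule)
            N_prev_pre = N_now

    traj = Trajectory(
        times=np.array(times),
        W=np.array([s[0] for s in states]),
        R=np.array([s[1] for s in states]),
        bolus_times=np.array(bolus_times),
        dose_series=np.array(doses),
        K=np.array([s[2] for s in states]),
        horizon_days=horizon_days,
    )
    traj.pfs_days, traj.pfs_censored = pfs_time(traj, growth.N0)
    traj.os_days, traj.os_censored = os_time(traj, lethal_burden)
    return traj


def regimen_grid(
    growth: GrowthParams,
    response: DrugResponse,
    vasc: VascularParams,
    fitness: FitnessFunctionSpec,
    q0: float,
    dose_levels: Sequence[float],
    intervals: Sequence[float],
    regimes: Sequence[str] = ("AT", "metronomic"),
    horizon_days: float = 1000.0,
    lethal_burden: float = LETHAL_BURDEN,
    record_dt: float = 1.0,
):
    """Sweep regimes x doses x intervals; one row of endpoints per config.

    Returns a tidy :class:`pandas.DataFrame` with columns regime, dose,
    interval, pfs_days, os_days, censor flags and the final resistant
    frequency.
    """
    import pandas as pd

    rows = []
    for regime, rho, theta in itertools.product(regimes, dose_levels, intervals):
        sched = TreatmentSchedule(regime=regime, rho_MTD=rho, theta=theta)
        traj = simulate_vascular(
            growth,
            response,
            vasc,
            sched,
            fitness,
            initial_resistant_frequency=q0,
            horizon_days=horizon_days,
            record_dt=record_dt,
            lethal_burden=lethal_burden,
        )
        N_end = traj.N[-1]
        rows.append(
            {
                "regime": regime,
                "dose": rho,
                "interval": theta,
                "pfs_days": traj.pfs_days,
                "pfs_censored": traj.pfs_censored,
                "os_days": traj.os_days,
                "os_censored": traj.os_censored,
                "final_resistant_frequency": traj.R[-1] / N_end if N_end > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)
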