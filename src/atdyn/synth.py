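"""Synthetic data with the statistical structure of the wet-lab assays.

Every generator emits observations *and* the generating truth, so each
analysis stage can be tested end-to-end without external data:

* :func:`gen_growth_curves` — monoculture count series (deterministic
  exponential mean, multiplicative lognormal counting noise) for
  growth-rate fitting;
* :func:`gen_competition_assay` — a serial-passage two-clone competition
  (exponential growth between passages, binomial 1/10 thinning every
  3 days, exponential GFP-marker silencing, multinomial flow-cytometry
  sampling of 10^4 events) plus the matched marker-positive control
  assay needed for the marker-loss correction;
* :func:`gen_spheroid_scenarios` — a deterministic battery of small CA
  lattices (all-sensitive, 1% random resistant, resistant rim, resistant
  core) for regression tests of the spatial model.

The noise models (lognormal counting error, binomial passage thinning,
multinomial cytometry) are the minimal standard models for those
measurement processes; each is parameterised and can be switched off to
obtain exact series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .competition import CompetitionSeries
from .spheroid import CAParams, _seed_disc, solve_fields
from ._ca_core import MEDIUM, RESISTANT, SENSITIVE

__all__ = [
    "AssayDesign",
    "gen_growth_curves",
    "gen_competition_assay",
    "gen_spheroid_scenarios",
]


@dataclass(frozen=True)
class AssayDesign:
    """Design of a synthetic serial-passage competition experiment.

    Population P is the marker-positive (GFP+) sensitive line, Q the
    competitor.  Defaults emulate the experimental protocol: 1:99
    seeding ratios are expressed through ``initial_frequency_P``,
    passaging every 3 days at 1/10 dilution, 10^4 cytometry events per
    measurement, and a slow exponential GFP-silencing process.
    """

    initial_total_cells: float = 1e6
    initial_frequency_P: float = 0.5
    # growth balancing the 1/10 passage every 3 days keeps the culture
    # stationary, as in routine passaging; Q pays a ~7% fitness deficit
    rate_P: float = math.log(10) / 3
    rate_Q: float = 0.93 * math.log(10) / 3
    passage_interval: float = 3.0  # days
    dilution: float = 0.1
    marker_loss_rate: float = 0.005  # per day
    cytometry_events: Optional[int] = 10_000  # None = exact frequencies
    measurement_days: Sequence[float] = tuple(range(0, 31, 3))
    q_labelled: bool = False  # True: Q carries its own marker (e.g. mCherry)
    stochastic: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.dilution <= 1.0:
            raise ValueError("dilution must lie in (0, 1]")
        if not 0.0 < self.initial_frequency_P < 1.0:
            raise ValueError("initial frequency must lie in (0, 1)")
        if self.cytometry_events is not None and self.cytometry_events < 1:
            raise ValueError("cytometry_events must be >= 1")
        if self.marker_loss_rate < 0:
            raise ValueError("marker loss rate must be non-negative")
        if not np.all(np.isfinite([self.rate_P, self.rate_Q])):
            raise ValueError("growth rates must be finite")


def gen_growth_curves(
    rates: Dict[str, float],
    n_days: float = 6.0,
    counts_per_day: int = 1,
    noise_cv: float = 0.0,
    seed: int = 0,
    initial_count: float = 1e4,
) -> pd.DataFrame:
    """Monoculture growth curves with lognormal counting noise.

    Returns a tidy frame with columns ``clone``, ``time_hours``,
    ``count``; the deterministic mean is ``initial_count * exp(r t)`` and
    the multiplicative noise has the stated coefficient of variation
    (``noise_cv = 0`` gives the exact exponential).
    """
    rng = np.random.default_rng(seed)
    times_days = np.arange(0, n_days + 1e-9, 1.0 / counts_per_day)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    rows = []
    for clone, rate in rates.items():
        mean = initial_count * np.exp(rate * times_days)
        if sigma > 0:
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(mean))
            counts = mean * noise
        else:
            counts = mean
        for t, c in zip(times_days, counts):
            rows.append({"clone": clone, "time_hours": t * 24.0, "count": c})
    return pd.DataFrame(rows)


def _binomial_or_exact(rng, n, p, stochastic):
    if stochastic:
        return float(rng.binomial(int(round(n)), p)) if n >= 1 else 0.0
    return n * p


def gen_competition_assay(design: AssayDesign):
    """Simulate a two-clone serial-passage competition with measurement noise.

    Three compartments are tracked: marker-positive P, marker-silenced P,
    and Q.  Between passages all grow exponentially at their clone rate
    while P cells silence the marker at ``marker_loss_rate``; every
    ``passage_interval`` days the whole culture is thinned to
    ``dilution``; at each measurement day the observed frequency is a
    multinomial cytometry draw.  If ``q_labelled`` is False the observed
    marker-positive frequency is contaminated by silenced P cells and
    must be corrected with the matched marker-positive control that is
    returned alongside.

    Returns a dict with keys ``observed`` (:class:`CompetitionSeries`),
    ``control`` (marker-positive control assay, same protocol, pure P),
    and ``truth`` (true s = rate_P - rate_Q, true frequencies).
    """
    d = design
    rng = np.random.default_rng(d.seed)
    days = np.asarray(d.measurement_days, dtype=float)
    horizon = float(days.max())

    def simulate(p0_frequency: float, pure_control: bool):
        Pm = d.initial_total_cells * p0_frequency  # marker-positive P
        Pu = 0.0  # marker-silenced P
        Q = 0.0 if pure_control else d.initial_total_cells * (1.0 - p0_frequency)
        t = 0.0
        out_obs, out_true = {}, {}
        events = np.arange(0.0, horizon + 1e-9, d.passage_interval)
        for t_next in events:
            dt = t_next - t
            if dt > 0:
                grow_P = math.exp(d.rate_P * dt)
                keep = math.exp(-d.marker_loss_rate * dt)
                lost = Pm * grow_P * (1.0 - keep)
                Pm = Pm * grow_P * keep
                Pu = Pu * math.exp(d.rate_P * dt) + lost
                Q = Q * math.exp(d.rate_Q * dt)
            t = t_next
            # measure before the passage disturbs the culture
            if np.any(np.isclose(days, t)):
                total = Pm + Pu + Q
                p_true = (Pm + Pu) / total
                marked = Pm if not d.q_labelled else Pm + Pu
                p_marked = marked / total
                if d.cytometry_events is None or not d.stochastic:
                    obs = p_marked
                else:
                    obs = rng.binomial(d.cytometry_events, p_marked) / d.cytometry_events
                out_obs[t] = obs
                out_true[t] = p_true
            if t < horizon:  # passage: thin to the dilution fraction
                if d.stochastic:
                    Pm = _binomial_or_exact(rng, Pm, d.dilution, True)
                    Pu = _binomial_or_exact(rng, Pu, d.dilution, True)
                    Q = _binomial_or_exact(rng, Q, d.dilution, True)
                else:
                    Pm, Pu, Q = Pm * d.dilution, Pu * d.dilution, Q * d.dilution
        return out_obs, out_true

    obs, true = simulate(d.initial_frequency_P, pure_control=False)
    ctrl_obs, _ = simulate(1.0 - 1e-12, pure_control=True)
    times = np.array(sorted(obs))
    observed = CompetitionSeries(
        times=times, p=np.array([obs[t] for t in times]), label_P="P", label_Q="Q"
    )
    control = CompetitionSeries(
        times=times,
        p=np.clip(np.array([ctrl_obs[t] for t in times]), 1e-12, 1.0),
        label_P="P_control",
        label_Q="lost_marker",
    )
    truth = {
        "s": d.rate_P - d.rate_Q,
        "rate_P": d.rate_P,
        "rate_Q": d.rate_Q,
        "marker_loss_rate": d.marker_loss_rate,
        "times": times,
        "true_p": np.array([true[t] for t in times]),
    }
    return {"observed": observed, "control": control, "truth": truth}


def gen_spheroid_scenarios(seed: int = 0, grid_size: int = 80) -> List[Dict]:
    """Deterministic fixture battery for the spatial model.

    Four small lattices at the seed volume: all-sensitive, 1% resistant
    at random, a resistant rim at the periphery, and a resistant core.
    Reproducible from the seed; fields are pre-solved.
    """
    params = CAParams(grid_size=grid_size, seed=seed)
    rng = np.random.default_rng(seed)
    scenarios = []

    def make(name, mutate):
        lattice = _seed_disc(params, 0.0, 0.07, rng)
        mutate(lattice)
        solve_fields(lattice, params)
        scenarios.append({"name": name, "params": params, "lattice": lattice})

    def random_1pct(lat):
        cells = np.argwhere(lat.grid == SENSITIVE)
        k = max(1, int(round(0.01 * len(cells))))
        picks = cells[rng.choice(len(cells), size=k, replace=False)]
        lat.grid[picks[:, 0], picks[:, 1]] = RESISTANT

    def rim(lat):
        from scipy import ndimage

        mass = lat.grid != MEDIUM
        dist = ndimage.distance_transform_edt(mass)
        lat.grid[(dist > 0) & (dist <= 2.0) & mass] = RESISTANT

    def core(lat):
        from scipy import ndimage

        mass = lat.grid != MEDIUM
        dist = ndimage.distance_transform_edt(mass)
        lat.grid[dist >= dist.max() * 0.7] = RESISTANT

    make("all_sensitive", lambda lat: None)
    make("random_1pct", random_1pct)
    make("resistant_rim", rim)
    make("resistant_core", core)
    return scenarios
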