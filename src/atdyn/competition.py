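"""Selection-coefficient estimation from two-clone competition assays.

For populations P and Q with frequencies p = P/(P+Q), q = 1 - p, the
selection coefficient of P relative to Q is the rate of change of the
log-ratio of frequencies,

    s = d/dt log(p / (1 - p)),

estimated as the least-squares slope of logit(p) against time.  For
non-interacting exponentially growing clones this equals the difference
in their monoculture growth rates, s = r_P - r_Q, so the coefficient
measured in competition can be compared against a prediction from
separately measured growth curves (log-linear fit over the first 72 h).

Fluorescent-marker loss: when one clone is identified by a GFP marker
that is silenced over time, the GFP+ control assay yields a correction
factor c(t) = exp(a t + b) from a log-linear regression of the GFP+
frequency.  :func:`adjust_marker_loss` applies the published adjustment
(multiply GFP+ frequencies by 1/c and GFP- frequencies by (1-c)/c, then
renormalise).  That recipe is not a mass-conserving inversion of the
loss process — at c = 1 the GFP- multiplier degenerates to zero (a guard
passes the GFP- frequency through unchanged and warns) — so the exact
inversion (which moves the measured GFP- excess p*(1/c - 1) back to the
GFP+ compartment and exactly undoes the loss process) is available via
``conserve_mass=True``.

Also here: the projected-area volumetry used for spheroids,
V = (4/3) pi R^3 with R = sqrt(S / pi).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass


import numpy as np
from scipy import stats

__all__ = [
    "CompetitionSeries",
    "GrowthRateEstimate",
    "MarkerLossModel",
    "selection_coefficient_observed",
    "selection_coefficient_predicted",
    "estimate_growth_rate",
    "fit_marker_loss",
    "adjust_marker_loss",
    "spheroid_volume_from_area",
]


@dataclass
class CompetitionSeries:
    """Timestamped two-clone frequencies (or counts) for populations P, Q."""

    times: np.ndarray  # days
    p: np.ndarray  # frequency of population P (or raw counts, see from_counts)
    label_P: str = "P"
    label_Q: str = "Q"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.times.shape != self.p.shape:
            raise ValueError("times and frequencies must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @classmethod
    def from_counts(cls, times, counts_P, counts_Q, **kw) -> "CompetitionSeries":
        counts_P = np.asarray(counts_P, dtype=float)
        counts_Q = np.asarray(counts_Q, dtype=float)
        if np.any(counts_P < 0) or np.any(counts_Q < 0):
            raise ValueError("counts must be non-negative")
        total = counts_P + counts_Q
        if np.any(total <= 0):
            raise ValueError("each time point needs a positive total count")
        return cls(times=np.asarray(times, dtype=float), p=counts_P / total, **kw)


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Log-linear growth rate (per day) fitted over a time window."""

    rate: float
    window_hours: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class MarkerLossModel:
    """Exponential marker-loss correction c(t) = exp(a t + b)."""

    a: float  # slope, per day (negative for marker loss)
    b: float  # intercept, log scale
    r_squared: float = math.nan

    def c(self, t):
        return np.exp(self.a * np.asarray(t, dtype=float) + self.b)


def selection_coefficient_observed(
    series: CompetitionSeries,
    per_interval: bool = False,
    drop_boundary: bool = False,
):
    """Selection coefficient s = d/dt log(p/(1-p)) from a competition series.

    By default returns the least-squares slope of logit(p) on time (per
    day).  With ``per_interval=True`` returns the array of pairwise
    coefficients between consecutive time points instead — one estimate
    per assay interval.

    Frequencies of exactly 0 or 1 have no logit; by default they raise,
    naming the offending time points.  ``drop_boundary=True`` instead
    excludes them from the regression with a warning (no pseudo-counts
    are ever added), provided at least two interior points remain.
    """
    times, p = series.times, series.p
    if len(p) < 2:
        raise ValueError("need at least two time points")
    boundary = (p <= 0.0) | (p >= 1.0)
    if np.any(boundary):
        bad = times[boundary]
        if not drop_boundary:
            raise ValueError(
                f"logit undefined at frequency 0 or 1 (time points {bad.tolist()})"
            )
        warnings.warn(
            f"excluding boundary frequencies at time points {bad.tolist()}",
            stacklevel=2,
        )
        times, p = times[~boundary], p[~boundary]
        if len(p) < 2:
            raise ValueError("fewer than two interior points after exclusion")
    logit = np.log(p / (1.0 - p))
    if per_interval:
        return np.diff(logit) / np.diff(times)
    slope, _ = np.polyfit(times, logit, 1)
    return float(slope)


def selection_coefficient_predicted(rate_P: float, rate_Q: float) -> float:
    """Predicted s = r_P - r_Q for non-interacting exponential clones."""
    return rate_P - rate_Q


def estimate_growth_rate(
    times_hours, counts, window_hours: float = 72.0
) -> GrowthRateEstimate:
    """Exponential growth rate from the log-linear fit within the window.

    ``times_hours`` are in hours from seeding; the least-squares slope of
    log(count) over [0, window_hours] is reported per day.
    """
    t = np.asarray(times_hours, dtype=float)
    y = np.asarray(counts, dtype=float)
    mask = (t >= 0) & (t <= window_hours)
    t, y = t[mask], y[mask]
    if len(t) < 2:
        raise ValueError("need at least two points within the fitting window")
    if np.any(y <= 0):
        raise ValueError("counts must be positive for a log-linear fit")
    res = stats.linregress(t / 24.0, np.log(y))
    return GrowthRateEstimate(
        rate=float(res.slope),
        window_hours=window_hours,
        r_squared=float(res.rvalue**2) if len(t) > 2 else 1.0,
        n_points=len(t),
    )


def fit_marker_loss(control_series: CompetitionSeries) -> MarkerLossModel:
    """Fit c(t) = exp(a t + b) to the marker-positive control frequencies.

    Log-linear regression of the marker-positive frequency of a pure
    marker-positive control assay on time.
    """
    p = control_series.p
    if np.any(p <= 0):
        raise ValueError("control marker-positive frequencies must be positive")
    res = stats.linregress(control_series.times, np.log(p))
    return MarkerLossModel(
        a=float(res.slope), b=float(res.intercept), r_squared=float(res.rvalue**2)
    )


def adjust_marker_loss(
    series: CompetitionSeries,
    model: MarkerLossModel,
    conserve_mass: bool = False,
) -> CompetitionSeries:
    """Correct marker-positive/negative frequencies for marker loss.

    Default (published recipe): p -> p/c, q -> q*(1-c)/c, renormalise.
    When |1 - c| < 1e-12 the degenerate (1-c)/c multiplier would zero the
    marker-negative compartment, so q is passed through unchanged and a
    warning is recorded.

    ``conserve_mass=True`` instead inverts the loss process exactly:
    the marker-negative excess p*(1/c - 1) created by silencing is moved
    back to the marker-positive compartment before renormalisation.
    """
    c = model.c(series.times)
    p, q = series.p, series.q
    if conserve_mass:
        p_adj = p / c
        q_adj = np.clip(q - p * (1.0 / c - 1.0), 0.0, None)
    else:
        p_adj = p / c
        degenerate = np.abs(1.0 - c) < 1e-12
        if np.any(degenerate):
            warnings.warn(
                "marker-loss factor c = 1 at some time points; marker-negative "
                "frequencies passed through unchanged there",
                stacklevel=2,
            )
        q_adj = np.where(degenerate, q, q * (1.0 - c) / c)
    total = p_adj + q_adj
    if np.any(total <= 0):
        raise ValueError("adjustment produced an empty frequency vector")
    return CompetitionSeries(
        times=series.times.copy(),
        p=np.clip(p_adj / total, 0.0, 1.0),
        label_P=series.label_P,
        label_Q=series.label_Q,
    )


def spheroid_volume_from_area(projected_area_mm2: float) -> float:
    """Volume (mm^3) of the sphere equivalent to a 2D projected area (mm^2).

    R = sqrt(S/pi); V = (4/3) pi R^3.  Scales as S^(3/2).
    """
    if projected_area_mm2 < 0:
        raise ValueError("area must be non-negative")
    radius = math.sqrt(projected_area_mm2 / math.pi)
    return (4.0 / 3.0) * math.pi * radius**3
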