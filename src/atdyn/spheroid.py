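"""Hybrid cellular-automaton model of a tumour-spheroid cross-section.

Discrete sensitive/resistant cells live on a 2D square lattice (one site
per cell, 15 um default) coupled to continuous oxygen and CDK-inhibitor
fields that diffuse in from the surrounding medium and are consumed by
living cells.  Cells divide and die stochastically (Gillespie algorithm)
at rates set by local oxygen, local drug, and crowding: a cell can divide
only if a free site lies within the crowding radius, which confines
proliferation to the spheroid rim and is the mechanism by which sensitive
cells spatially suppress rare resistant cells.

Rate model (per day):

* sensitive:  P = lambda_S * [o2/(o2+o2_half)] * [1/(1 + rho/IC_p)] * crowd,
  M = M_max * rho^h / (rho^h + EC^h)  (Hill drug kill, h = 4);
* resistant:  P = cost * lambda_S * [o2/(o2+o2_half)] * crowd, M = 0 —
  refractory to the inhibitor, paying only the proliferation cost
  (default 90% of the sensitive rate), oxygen, and crowding.

Default drug constants are calibrated to the two experimental anchors:
20 uM arrests net growth of well-oxygenated sensitive cells and 50 uM
causes strong net death.  Cells below the oxygen survival threshold die
in a sweep at the start of each update loop and persist as necrotic
debris (the necrotic core) unless replaced by daughters of dividing
neighbours; drug-killed cells free their site.  For efficiency, the
fields are re-solved only after 10% of the population has divided or
died.

Volumes follow the experimental volumetry convention: the living +
necrotic cross-section area is converted to the volume of the sphere
with the equivalent-circle radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import _ca_core as core
from ._ca_core import MEDIUM, NECROTIC, RESISTANT, SENSITIVE

__all__ = [
    "CAParams",
    "SpheroidLattice",
    "CohortSummary",
    "init_spheroid",
    "solve_fields",
    "compute_rates",
    "gillespie_step",
    "attempt_division",
    "necrosis_sweep",
    "run_spheroid",
    "volume_mm3",
    "run_cohort",
    "escape_by_distance",
]


@dataclass(frozen=True)
class CAParams:
    """Rates, field constants and lattice geometry of the CA.

    Oxygen is dimensionless (fraction of the medium boundary level); drug
    concentrations are in uM; times in days; the diffusion/uptake ratios
    are expressed per lattice site, so ``sqrt(diffusion/uptake)`` is the
    penetration depth in sites.
    """

    lambda_S_max: float = math.log(2) / 1.1  # HCT-116 doubling ~26 h
    fitness_cost: float = 0.9
    oxygen_boundary: float = 1.0
    oxygen_death_threshold: float = 0.08
    oxygen_diffusion: float = 1.0
    oxygen_consumption: float = 1.0 / 81.0  # penetration depth 9 sites (135 um)
    oxygen_halfsat: float = 0.05  # ~1% O2 given a 21% O2 medium boundary
    drug_boundary: float = 0.0  # uM in the medium
    drug_diffusion: float = 1.0
    drug_uptake: float = 1.0 / 6400.0  # penetration depth 80 sites (1.2 mm)
    drug_prolif_ic: float = 0.75  # uM halving sensitive proliferation
    drug_death_rate_max: float = 0.85  # per day
    drug_death_ec: float = 50.0  # uM
    drug_death_hill: float = 4.0
    crowding_radius: float = 2.0  # sites
    batch_fraction: float = 0.1
    cell_diameter: float = 15.0  # um per site
    grid_size: int = 150
    field_tol: float = 1e-6
    field_max_iter: int = 50000
    sor_omega: float = 1.95
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.batch_fraction <= 1.0:
            raise ValueError("batch_fraction must lie in (0, 1]")
        if not 0.0 < self.fitness_cost <= 1.0:
            raise ValueError("fitness_cost must lie in (0, 1]")
        for name in (
            "lambda_S_max",
            "oxygen_boundary",
            "oxygen_diffusion",
            "oxygen_consumption",
            "drug_prolif_ic",
            "drug_death_ec",
            "cell_diameter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.drug_boundary < 0 or self.drug_death_rate_max < 0:
            raise ValueError("drug parameters must be non-negative")


@dataclass
class SpheroidLattice:
    """The CA's mutable world: site states plus oxygen and drug fields."""

    grid: np.ndarray  # int8, codes MEDIUM/SENSITIVE/RESISTANT/NECROTIC
    oxygen: np.ndarray  # fraction of boundary level
    drug_norm: np.ndarray  # drug field normalised to a unit boundary
    cell_diameter: float
    drug_boundary: float = 0.0
    initial_resistant_distances_um: np.ndarray = dc_field(
        default_factory=lambda: np.empty(0)
    )

    @property
    def drug(self) -> np.ndarray:
        """Drug concentration field in uM."""
        return self.drug_boundary * self.drug_norm

    @property
    def origin(self) -> Tuple[int, int]:
        return self.grid.shape[0] // 2, self.grid.shape[1] // 2

    def counts(self) -> Dict[str, int]:
        g = self.grid
        return {
            "sensitive": int(np.sum(g == SENSITIVE)),
            "resistant": int(np.sum(g == RESISTANT)),
            "necrotic": int(np.sum(g == NECROTIC)),
        }

    def resistant_frequency(self) -> float:
        c = self.counts()
        living = c["sensitive"] + c["resistant"]
        return c["resistant"] / living if living else 0.0

    def copy(self) -> "SpheroidLattice":
        return SpheroidLattice(
            grid=self.grid.copy(),
            oxygen=self.oxygen.copy(),
            drug_norm=self.drug_norm.copy(),
            cell_diameter=self.cell_diameter,
            drug_boundary=self.drug_boundary,
            initial_resistant_distances_um=self.initial_resistant_distances_um.copy(),
        )


def equivalent_sphere_radius_um(volume_mm3_value: float) -> float:
    """Radius (um) of the sphere with the given volume (mm^3)."""
    return (3.0 * volume_mm3_value / (4.0 * math.pi)) ** (1.0 / 3.0) * 1000.0


def volume_mm3(lattice_or_grid, cell_diameter: Optional[float] = None) -> float:
    """Equivalent-sphere volume of the living + necrotic cross-section.

    The occupied area (sites x cell_diameter^2) gives the radius of the
    equivalent circle, and the reported volume is that of the sphere with
    this radius — the same convention as the experimental projected-area
    volumetry.
    """
    if isinstance(lattice_or_grid, SpheroidLattice):
        grid = lattice_or_grid.grid
        d = lattice_or_grid.cell_diameter
    else:
        grid = lattice_or_grid
        d = cell_diameter
    n_sites = int(np.sum(grid != MEDIUM))
    area_um2 = n_sites * d * d
    radius_um = math.sqrt(area_um2 / math.pi)
    return (4.0 / 3.0) * math.pi * radius_um**3 / 1e9


def solve_fields(lattice: SpheroidLattice, params: CAParams) -> SpheroidLattice:
    """Steady-state reaction-diffusion solve of oxygen and drug (in place).

    Dirichlet boundary at the domain edge, linear uptake at living-cell
    sites, warm-started checkerboard SOR.  Because uptake is linear, the
    drug field is solved with a unit boundary and scaled by the dose.
    """
    living = ((lattice.grid == SENSITIVE) | (lattice.grid == RESISTANT)).view(np.uint8)
    it_o2 = core.sor_solve(
        lattice.oxygen,
        living,
        params.oxygen_consumption / params.oxygen_diffusion,
        params.oxygen_boundary,
        params.sor_omega,
        params.field_tol * params.oxygen_boundary,
        params.field_max_iter,
    )
    it_dr = core.sor_solve(
        lattice.drug_norm,
        living,
        params.drug_uptake / params.drug_diffusion,
        1.0,
        params.sor_omega,
        params.field_tol,
        params.field_max_iter,
    )
    if it_o2 < 0 or it_dr < 0:
        raise RuntimeError(
            "field solver did not converge below tolerance "
            f"{params.field_tol:g} within {params.field_max_iter} iterations"
        )
    np.clip(lattice.oxygen, 0.0, None, out=lattice.oxygen)
    np.clip(lattice.drug_norm, 0.0, None, out=lattice.drug_norm)
    lattice.drug_boundary = params.drug_boundary
    return lattice


def compute_rates(
    lattice: SpheroidLattice,
    params: CAParams,
    no_cost: bool = False,
    no_crowding: bool = False,
):
    """Per-cell proliferation and death rates from the current fields.

    Returns ``(coords, P, M)`` where coords is an (n, 2) array of (y, x)
    positions of living cells in lattice scan order.
    """
    size = lattice.grid.size
    cx = np.empty(size, dtype=np.int32)
    cy = np.empty(size, dtype=np.int32)
    ct = np.empty(size, dtype=np.int8)
    idx = np.empty(lattice.grid.shape, dtype=np.int32)
    n = core.collect_cells(lattice.grid, cx, cy, ct, idx)
    P = np.empty(size)
    M = np.empty(size)
    core.fill_rates(
        lattice.grid,
        lattice.oxygen / params.oxygen_boundary,
        lattice.drug_norm,
        cx,
        cy,
        n,
        P,
        M,
        params.drug_boundary,
        params.lambda_S_max,
        1.0 if no_cost else params.fitness_cost,
        params.oxygen_halfsat,
        params.drug_prolif_ic,
        params.drug_death_rate_max,
        params.drug_death_ec,
        params.drug_death_hill,
        params.crowding_radius,
        no_crowding,
    )
    coords = np.stack([cy[:n], cx[:n]], axis=1)
    return coords, P[:n].copy(), M[:n].copy()


def gillespie_step(lattice: SpheroidLattice, rates, rng: np.random.Generator):
    """One Gillespie draw: (event, cell index, waiting time).

    ``rates`` is the ``(coords, P, M)`` triple from :func:`compute_rates`.
    The cell is selected with probability (P_k+M_k)/sum(P_i+M_i) (sampling
    with replacement), the event is a division with probability
    P_k/(P_k+M_k), and the waiting time is exponential with mean
    1/sum(P_i+M_i).  With all rates zero a ``("quiescent", -1, inf)``
    signal is returned.
    """
    coords, P, M = rates
    total = float(np.sum(P) + np.sum(M))
    if total <= 0.0:
        return "quiescent", -1, math.inf
    wait = rng.exponential(1.0 / total)
    k = int(rng.choice(len(P), p=(P + M) / total))
    event = "division" if rng.random() * (P[k] + M[k]) < P[k] else "death"
    return event, k, wait


def attempt_division(
    lattice: SpheroidLattice,
    cell_yx: Tuple[int, int],
    params: CAParams,
    rng: np.random.Generator,
) -> bool:
    """Place a same-type daughter on the nearest free site, if any.

    Free sites (medium or necrotic) within the crowding radius are
    candidates; the nearest ones are tied and broken uniformly at random.
    Returns True if a daughter was placed, False if the attempt failed.
    """
    y, x = cell_yx
    if lattice.grid[y, x] not in (SENSITIVE, RESISTANT):
        raise ValueError("division attempted from a non-living site")
    core.seed_rng(int(rng.integers(0, 2**31 - 1)))
    dy, dx = core.choose_daughter_site(lattice.grid, y, x)
    if dy < 0:
        return False
    lattice.grid[dy, dx] = lattice.grid[y, x]
    return True


def necrosis_sweep(lattice: SpheroidLattice, params: CAParams) -> int:
    """Kill living cells below the oxygen survival threshold; returns count."""
    return core.necrosis_sweep_grid(
        lattice.grid,
        lattice.oxygen / params.oxygen_boundary,
        params.oxygen_death_threshold,
    )


def _seed_disc(
    params: CAParams, resistant_fraction: float, volume: float, rng: np.random.Generator
) -> SpheroidLattice:
    n = params.grid_size
    grid = np.zeros((n, n), dtype=np.int8)
    r_sites = equivalent_sphere_radius_um(volume) / params.cell_diameter
    cy0, cx0 = n // 2, n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    inside = (yy - cy0) ** 2 + (xx - cx0) ** 2 <= r_sites**2
    grid[inside] = SENSITIVE
    if resistant_fraction > 0:
        res = inside & (rng.random((n, n)) < resistant_fraction)
        grid[res] = RESISTANT
    lattice = SpheroidLattice(
        grid=grid,
        oxygen=np.full((n, n), params.oxygen_boundary),
        drug_norm=np.ones((n, n)),
        cell_diameter=params.cell_diameter,
        drug_boundary=params.drug_boundary,
    )
    return lattice


def _distances_to_periphery_um(lattice: SpheroidLattice) -> np.ndarray:
    """Distance from each living resistant cell to the nearest medium site."""
    mass = lattice.grid != MEDIUM
    dist = ndimage.distance_transform_edt(mass)
    return dist[lattice.grid == RESISTANT] * lattice.cell_diameter


def _advance(
    lattice: SpheroidLattice,
    params: CAParams,
    days: float,
    no_cost: bool,
    no_crowding: bool,
    record_interval: Optional[float] = None,
    stop_volume_mm3: Optional[float] = None,
    t0: float = 0.0,
):
    """Drive the CA for ``days`` simulated days.

    Update loop: solve fields -> necrosis sweep -> recompute all rates ->
    Gillespie events (frozen fields) until 10% of the population has
    turned over -> repeat.  Optionally records (time, volume, resistant
    frequency) every ``record_interval`` days and stops early when the
    cross-section volume reaches ``stop_volume_mm3``.
    """
    size = lattice.grid.size
    cx = np.empty(size, dtype=np.int32)
    cy = np.empty(size, dtype=np.int32)
    ct = np.empty(size, dtype=np.int8)
    P = np.empty(size)
    M = np.empty(size)
    idx = np.empty(lattice.grid.shape, dtype=np.int32)

    t = t0
    t_end = t0 + days
    records: List[Tuple[float, float, float]] = []

    def record(time):
        records.append((time, volume_mm3(lattice), lattice.resistant_frequency()))

    next_rec = t0 + record_interval if record_interval else math.inf
    if record_interval:
        record(t0)

    n = 0
    total = 0.0
    turnover_left = 0
    oxy_norm = None
    while t < t_end - 1e-12:
        if turnover_left <= 0:
            solve_fields(lattice, params)
            necrosis_sweep(lattice, params)
            n = core.collect_cells(lattice.grid, cx, cy, ct, idx)
            if n == 0:
                t = t_end
                break
            total = core.fill_rates(
                lattice.grid,
                lattice.oxygen / params.oxygen_boundary,
                lattice.drug_norm,
                cx,
                cy,
                n,
                P,
                M,
                params.drug_boundary,
                params.lambda_S_max,
                1.0 if no_cost else params.fitness_cost,
                params.oxygen_halfsat,
                params.drug_prolif_ic,
                params.drug_death_rate_max,
                params.drug_death_ec,
                params.drug_death_hill,
                params.crowding_radius,
                no_crowding,
            )
            turnover_left = max(1, int(math.ceil(params.batch_fraction * n)))
        t_stop = min(t_end, next_rec)
        n, total, t, turnover_left, _ = core.run_batch(
            lattice.grid,
            lattice.oxygen / params.oxygen_boundary,
            lattice.drug_norm,
            cx,
            cy,
            ct,
            P,
            M,
            idx,
            n,
            total,
            t,
            t_stop,
            turnover_left,
            params.drug_boundary,
            params.lambda_S_max,
            1.0 if no_cost else params.fitness_cost,
            params.oxygen_halfsat,
            params.drug_prolif_ic,
            params.drug_death_rate_max,
            params.drug_death_ec,
            params.drug_death_hill,
            params.crowding_radius,
            no_crowding,
        )
        if record_interval and t >= next_rec - 1e-9:
            record(next_rec)
            next_rec += record_interval
        if stop_volume_mm3 is not None and volume_mm3(lattice) >= stop_volume_mm3:
            break
    if record_interval:
        while next_rec <= t_end + 1e-9:  # population extinct before horizon
            record(next_rec)
            next_rec += record_interval
    return records


def init_spheroid(
    params: CAParams,
    resistant_fraction: float,
    target_volume_mm3: float = 0.3,
    rng_seed: int = 0,
    seed_volume_mm3: float = 0.07,
    pregrow: bool = True,
) -> SpheroidLattice:
    """Seed a spheroid disc and grow it untreated to the target volume.

    A disc with the equivalent-sphere volume ``seed_volume_mm3`` is seeded
    at the grid centre, each cell independently resistant with probability
    ``resistant_fraction``; the untreated CA then runs until the
    cross-section volume reaches ``target_volume_mm3``.  The returned
    lattice carries each resistant cell's distance to the periphery at
    treatment start.
    """
    if not 0.0 <= resistant_fraction < 1.0:
        raise ValueError("resistant fraction must lie in [0, 1)")
    if pregrow and target_volume_mm3 < seed_volume_mm3:
        raise ValueError("target volume smaller than the seed volume")
    ss = np.random.SeedSequence(rng_seed)
    py_seed, nb_seed = ss.spawn(2)
    rng = np.random.default_rng(py_seed)
    core.seed_rng(int(nb_seed.generate_state(1, np.uint32)[0] % (2**31 - 1)))
    start_volume = seed_volume_mm3 if pregrow else target_volume_mm3
    untreated = replace(params, drug_boundary=0.0)
    lattice = _seed_disc(untreated, resistant_fraction, start_volume, rng)
    if pregrow:
        _advance(
            lattice,
            untreated,
            days=1000.0,
            no_cost=False,
            no_crowding=False,
            stop_volume_mm3=target_volume_mm3,
        )
    else:
        solve_fields(lattice, untreated)
    lattice.initial_resistant_distances_um = _distances_to_periphery_um(lattice)
    return lattice


def run_spheroid(
    params: CAParams,
    resistant_fraction: float = 0.01,
    treatment_dose_uM: float = 20.0,
    days: float = 24.0,
    no_cost: bool = False,
    no_pregrowth: bool = False,
    no_crowding: bool = False,
    rng_seed: int = 0,
    record_interval: float = 1.0,
    pregrown: Optional[SpheroidLattice] = None,
    target_volume_mm3: float = 0.3,
) -> Dict:
    """One full stochastic run: pre-growth (unless ablated) plus treatment.

    Returns a per-run record with day-resolution volume and resistance
    series, the initial resistant-cell distances to the periphery (um),
    and the escape flag (resistance > 10% at the final day).  Passing a
    ``pregrown`` lattice (from :func:`init_spheroid`) reuses the same
    competition phase across treatment arms.
    """
    if pregrown is not None:
        lattice = pregrown.copy()
        ss = np.random.SeedSequence((rng_seed, 1))
        core.seed_rng(int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1)))
    else:
        lattice = init_spheroid(
            params,
            resistant_fraction,
            target_volume_mm3=target_volume_mm3,
            rng_seed=rng_seed,
            pregrow=not no_pregrowth,
        )
    treated = replace(params, drug_boundary=treatment_dose_uM)
    lattice.drug_boundary = treatment_dose_uM
    v0 = volume_mm3(lattice)
    records = _advance(
        lattice,
        treated,
        days=days,
        no_cost=no_cost,
        no_crowding=no_crowding,
        record_interval=record_interval,
    )
    times = np.array([r[0] for r in records])
    vols = np.array([r[1] for r in records])
    freqs = np.array([r[2] for r in records])
    dists = lattice.initial_resistant_distances_um
    return {
        "days": times,
        "volume_mm3": vols,
        "resistant_frequency": freqs,
        "volume_ratio": vols[-1] / v0 if v0 > 0 else math.nan,
        "initial_resistant_distances_um": dists,
        "outermost_resistant_distance_um": float(dists.min()) if len(dists) else math.nan,
        "escaped": bool(freqs[-1] > 0.10),
        "final_lattice": lattice,
    }


@dataclass
class CohortSummary:
    """Aggregated outcomes of a cohort of stochastic runs."""

    runs: "object"  # tidy DataFrame: regime, run, day, volume_mm3, resistant_frequency
    summary: "object"  # per regime/day: median, mean, q25, q75 of both outcomes
    escape: "object"  # per regime/run: outermost distance (um), escape flag

    def escape_proportion(self, regime: str, bins) -> "object":
        return escape_by_distance(self.escape[self.escape.regime == regime], bins)


def escape_by_distance(escape_frame, bins):
    """Escape proportion binned by the outermost resistant cell's initial
    distance to the periphery."""
    import pandas as pd

    df = escape_frame.dropna(subset=["outermost_distance_um"]).copy()
    df["bin"] = pd.cut(df["outermost_distance_um"], bins=bins)
    out = (
        df.groupby("bin", observed=False)["escaped"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "escape_proportion", "count": "n"})
        .reset_index()
    )
    return out


def run_cohort(
    params: CAParams,
    n_runs: int,
    regimes: Sequence[Dict],
    base_seed: int = 0,
    resistant_fraction: float = 0.01,
    days: float = 24.0,
    share_pregrowth: bool = True,
    progress: bool = False,
) -> CohortSummary:
    """Seeded replicate cohort over one or more treatment regimes.

    ``regimes`` is a list of dicts with keys ``name``, ``dose_uM`` and
    optional flags ``no_cost``/``no_pregrowth``/``no_crowding``.  Runs are
    reproducible from ``base_seed``; regimes that share the default
    pre-growth protocol reuse the same pre-grown spheroid per seed, so
    arms differ only in treatment.
    """
    import pandas as pd

    seeds = [int(s.generate_state(1, np.uint32)[0] % (2**31 - 1))
             for s in np.random.SeedSequence(base_seed).spawn(n_runs)]
    rows, esc_rows = [], []
    iterator = range(n_runs)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="cohort")
    for i in iterator:
        seed = seeds[i]
        pregrown = None
        needs_pregrowth = any(not r.get("no_pregrowth", False) for r in regimes)
        if share_pregrowth and needs_pregrowth:
            pregrown = init_spheroid(
                params, resistant_fraction, rng_seed=seed, pregrow=True
            )
        for reg in regimes:
            rec = run_spheroid(
                params,
                resistant_fraction=resistant_fraction,
                treatment_dose_uM=reg["dose_uM"],
                days=days,
                no_cost=reg.get("no_cost", False),
                no_pregrowth=reg.get("no_pregrowth", False),
                no_crowding=reg.get("no_crowding", False),
                rng_seed=seed,
                pregrown=(
                    pregrown
                    if (share_pregrowth and not reg.get("no_pregrowth", False))
                    else None
                ),
            )
            for d, v, f in zip(
                rec["days"], rec["volume_mm3"], rec["resistant_frequency"]
            ):
                rows.append(
                    {
                        "regime": reg["name"],
                        "run": i,
                        "day": d,
                        "volume_mm3": v,
                        "resistant_frequency": f,
                    }
                )
            esc_rows.append(
                {
                    "regime": reg["name"],
                    "run": i,
                    "outermost_distance_um": rec["outermost_resistant_distance_um"],
                    "escaped": rec["escaped"],
                    "volume_ratio": rec["volume_ratio"],
                    "final_resistant_frequency": rec["resistant_frequency"][-1],
                }
            )
    runs = pd.DataFrame(rows)
    summary = (
        runs.groupby(["regime", "day"])[["volume_mm3", "resistant_frequency"]]
        .agg(["median", "mean", lambda s: s.quantile(0.25), lambda s: s.quantile(0.75)])
        .rename(columns={"<lambda_0>": "q25", "<lambda_1>": "q75"})
        .reset_index()
    )
    return CohortSummary(runs=runs, summary=summary, escape=pd.DataFrame(esc_rows))
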