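"""Hybrid CA spheroid model: lattice setup, field solver, stochastic
engine and single-run behaviour."""

import math

import numpy as np
import pytest
from scipy import stats

from atdyn import (
    CAParams,
    SpheroidLattice,
    attempt_division,
    compute_rates,
    gillespie_step,
    init_spheroid,
    necrosis_sweep,
    run_spheroid,
    solve_fields,
    volume_mm3,
)
from atdyn.spheroid import equivalent_sphere_radius_um
from atdyn._ca_core import MEDIUM, NECROTIC, RESISTANT, SENSITIVE


def _lattice_from_grid(grid, params):
    return SpheroidLattice(
        grid=grid.astype(np.int8),
        oxygen=np.full(grid.shape, params.oxygen_boundary),
        drug_norm=np.ones(grid.shape),
        cell_diameter=params.cell_diameter,
        drug_boundary=params.drug_boundary,
    )


class TestGeometry:
    def test_seed_disc_radius_matches_equivalent_sphere(self, small_ca_params):
        """0.07 mm^3 with 15 um cells gives a disc of ~17 sites radius."""
        assert equivalent_sphere_radius_um(0.07) == pytest.approx(255.6, abs=0.5)
        lat = init_spheroid(small_ca_params, 0.0, rng_seed=0, pregrow=False,
                            target_volume_mm3=0.07)
        n_cells = np.sum(lat.grid != MEDIUM)
        assert n_cells == pytest.approx(math.pi * 17.04**2, rel=0.03)
        assert volume_mm3(lat) == pytest.approx(0.07, rel=0.05)

    def test_volume_of_exact_circle(self, small_ca_params):
        grid = np.zeros((60, 60), dtype=np.int8)
        yy, xx = np.mgrid[0:60, 0:60]
        r = 255.6 / 15.0
        grid[(yy - 30) ** 2 + (xx - 30) ** 2 <= r * r] = SENSITIVE
        lat = _lattice_from_grid(grid, small_ca_params)
        assert volume_mm3(lat) == pytest.approx(0.07, rel=0.05)

    def test_empty_lattice_volume_zero(self, small_ca_params):
        lat = _lattice_from_grid(np.zeros((60, 60)), small_ca_params)
        assert volume_mm3(lat) == 0.0

    def test_zero_resistant_fraction(self, small_ca_params):
        lat = init_spheroid(small_ca_params, 0.0, rng_seed=1, pregrow=False,
                            target_volume_mm3=0.07)
        assert np.sum(lat.grid == RESISTANT) == 0
        assert len(lat.initial_resistant_distances_um) == 0

    def test_determinism_under_fixed_seed(self, small_ca_params):
        a = init_spheroid(small_ca_params, 0.05, rng_seed=7, pregrow=False,
                          target_volume_mm3=0.07)
        b = init_spheroid(small_ca_params, 0.05, rng_seed=7, pregrow=False,
                          target_volume_mm3=0.07)
        assert np.array_equal(a.grid, b.grid)

    def test_target_below_seed_volume_rejected(self, small_ca_params):
        with pytest.raises(ValueError):
            init_spheroid(small_ca_params, 0.0, target_volume_mm3=0.01,
                          seed_volume_mm3=0.07)


class TestFieldSolver:
    def test_no_cells_uniform_boundary_value(self, small_ca_params):
        lat = _lattice_from_grid(np.zeros((60, 60)), small_ca_params)
        solve_fields(lat, small_ca_params)
        assert np.allclose(lat.oxygen, small_ca_params.oxygen_boundary, atol=1e-5)
        assert np.allclose(lat.drug_norm, 1.0, atol=1e-5)

    def test_single_cell_minimum_at_cell(self, small_ca_params):
        grid = np.zeros((60, 60), dtype=np.int8)
        grid[30, 30] = SENSITIVE
        lat = _lattice_from_grid(grid, small_ca_params)
        solve_fields(lat, small_ca_params)
        assert lat.oxygen.argmin() == 30 * 60 + 30
        # radially non-decreasing along an axis away from the cell
        ray = lat.oxygen[30, 30:]
        assert np.all(np.diff(ray) >= -1e-9)

    def test_radial_monotonicity_on_disc(self, small_ca_params):
        lat = init_spheroid(small_ca_params, 0.0, rng_seed=0, pregrow=False,
                            target_volume_mm3=0.07)
        solve_fields(lat, small_ca_params)
        centre = lat.oxygen[30, 30]
        ray = lat.oxygen[30, 30:]
        assert centre == ray.min()
        assert np.all(np.diff(ray) >= -1e-9)

    def test_doubling_consumption_weakly_decreases_oxygen(self, small_ca_params):
        from dataclasses import replace

        grid = np.zeros((60, 60), dtype=np.int8)
        yy, xx = np.mgrid[0:60, 0:60]
        grid[(yy - 30) ** 2 + (xx - 30) ** 2 <= 16] = SENSITIVE  # ~50 cells
        lat1 = _lattice_from_grid(grid, small_ca_params)
        solve_fields(lat1, small_ca_params)
        hungry = replace(
            small_ca_params,
            oxygen_consumption=2 * small_ca_params.oxygen_consumption,
        )
        lat2 = _lattice_from_grid(grid, hungry)
        solve_fields(lat2, hungry)
        assert np.all(lat2.oxygen <= lat1.oxygen + 1e-6)


class TestRates:
    def test_free_cells_base_rates_and_fitness_cost(self, small_ca_params):
        """Uncrowded, oxygen-rich, drug-free: sensitive P = lambda*g_O2,
        resistant P is 90% of that, death rates zero."""
        grid = np.zeros((60, 60), dtype=np.int8)
        grid[20, 20] = SENSITIVE
        grid[40, 40] = RESISTANT
        lat = _lattice_from_grid(grid, small_ca_params)
        coords, P, M = compute_rates(lat, small_ca_params)
        g_o2 = 1.0 / (1.0 + small_ca_params.oxygen_halfsat)
        expected_s = small_ca_params.lambda_S_max * g_o2
        by_type = {tuple(c): (p, m) for c, p, m in zip(coords.tolist(), P, M)}
        pS, mS = by_type[(20, 20)]
        pR, mR = by_type[(40, 40)]
        assert pS == pytest.approx(expected_s, rel=1e-12)
        assert pR == pytest.approx(0.9 * expected_s, rel=1e-12)
        assert mS == 0.0 and mR == 0.0

    def test_enclosed_cell_cannot_divide(self, small_ca_params):
        grid = np.zeros((60, 60), dtype=np.int8)
        grid[27:34, 27:34] = SENSITIVE  # 7x7 block: centre has no space within 2
        lat = _lattice_from_grid(grid, small_ca_params)
        coords, P, M = compute_rates(lat, small_ca_params)
        centre = {tuple(c): p for c, p in zip(coords.tolist(), P)}[(30, 30)]
        assert centre == 0.0

    def test_drug_halves_sensitive_not_resistant(self, small_ca_params):
        from dataclasses import replace

        grid = np.zeros((60, 60), dtype=np.int8)
        grid[20, 20] = SENSITIVE
        grid[40, 40] = RESISTANT
        params = replace(small_ca_params,
                         drug_boundary=small_ca_params.drug_prolif_ic)
        lat = _lattice_from_grid(grid, params)
        coords, P, M = compute_rates(lat, params)
        ref_coords, refP, _ = compute_rates(
            _lattice_from_grid(grid, small_ca_params), small_ca_params
        )
        by = {tuple(c): p for c, p in zip(coords.tolist(), P)}
        ref = {tuple(c): p for c, p in zip(ref_coords.tolist(), refP)}
        assert by[(20, 20)] == pytest.approx(ref[(20, 20)] / 2, rel=1e-9)
        assert by[(40, 40)] == pytest.approx(ref[(40, 40)], rel=1e-9)

    def test_no_cost_flag_removes_resistant_penalty(self, small_ca_params):
        grid = np.zeros((60, 60), dtype=np.int8)
        grid[20, 20] = SENSITIVE
        grid[40, 40] = RESISTANT
        lat = _lattice_from_grid(grid, small_ca_params)
        coords, P, _ = compute_rates(lat, small_ca_params, no_cost=True)
        by = {tuple(c): p for c, p in zip(coords.tolist(), P)}
        assert by[(20, 20)] == pytest.approx(by[(40, 40)], rel=1e-12)


class TestGillespie:
    def test_selection_probabilities_chi_square(self, small_ca_params):
        """Two cells with total rates (3, 1) must be selected 3:1."""
        grid = np.zeros((60, 60), dtype=np.int8)
        grid[10, 10] = SENSITIVE
        grid[50, 50] = SENSITIVE
        lat = _lattice_from_grid(grid, small_ca_params)
        coords = np.array([[10, 10], [50, 50]])
        P = np.array([3.0, 1.0])
        M = np.array([0.0, 0.0])
        rng = np.random.default_rng(0)
        counts = np.zeros(2)
        for _ in range(10_000):
            _, k, _ = gillespie_step(lat, (coords, P, M), rng)
            counts[k] += 1
        chi2 = np.sum((counts - np.array([7500, 2500])) ** 2 / np.array([7500, 2500]))
        assert chi2 < stats.chi2.ppf(0.99, df=1)

    def test_single_cell_always_divides_with_unit_waiting_time(self, small_ca_params):
        grid = np.zeros((60, 60), dtype=np.int8)
        grid[30, 30] = SENSITIVE
        lat = _lattice_from_grid(grid, small_ca_params)
        rates = (np.array([[30, 30]]), np.array([1.0]), np.array([0.0]))
        rng = np.random.default_rng(1)
        waits = []
        for _ in range(10_000):
            event, k, wait = gillespie_step(lat, rates, rng)
            assert event == "division" and k == 0
            waits.append(wait)
        waits = np.asarray(waits)
        se = waits.std(ddof=1) / math.sqrt(len(waits))
        assert abs(waits.mean() - 1.0) < 3 * se

    def test_event_type_conditional_probability(self, small_ca_params):
        grid = np.zeros((60, 60), dtype=np.int8)
        grid[30, 30] = SENSITIVE
        lat = _lattice_from_grid(grid, small_ca_params)
        rates = (np.array([[30, 30]]), np.array([0.25]), np.array([0.75]))
        rng = np.random.default_rng(2)
        divisions = sum(
            gillespie_step(lat, rates, rng)[0] == "division" for _ in range(10_000)
        )
        assert divisions == pytest.approx(2500, abs=4 * math.sqrt(2500 * 0.75))

    def test_quiescence_signal_when_all_rates_zero(self, small_ca_params):
        lat = _lattice_from_grid(np.zeros((60, 60)), small_ca_params)
        event, k, wait = gillespie_step(
            lat, (np.empty((0, 2)), np.empty(0), np.empty(0)),
            np.random.default_rng(0),
        )
        assert event == "quiescent" and k == -1 and math.isinf(wait)


class TestDivisionAndNecrosis:
    def test_daughter_placed_on_adjacent_free_site(self, small_ca_params):
        grid = np.zeros((60, 60), dtype=np.int8)
        grid[30, 30] = RESISTANT
        lat = _lattice_from_grid(grid, small_ca_params)
        ok = attempt_division(lat, (30, 30), small_ca_params, np.random.default_rng(0))
        assert ok
        assert np.sum(lat.grid == RESISTANT) == 2
        placed = np.argwhere(lat.grid == RESISTANT)
        d = np.abs(placed - 30).max()
        assert d <= 1  # Moore neighbourhood

    def test_sealed_cell_division_fails(self, small_ca_params):
        grid = np.zeros((60, 60), dtype=np.int8)
        grid[28:33, 28:33] = SENSITIVE
        lat = _lattice_from_grid(grid, small_ca_params)
        before = lat.grid.copy()
        ok = attempt_division(lat, (30, 30), small_ca_params, np.random.default_rng(0))
        assert not ok
        assert np.array_equal(lat.grid, before)

    def test_daughter_may_replace_necrotic_debris(self, small_ca_params):
        grid = np.zeros((60, 60), dtype=np.int8)
        grid[28:33, 28:33] = SENSITIVE
        grid[30, 31] = NECROTIC
        lat = _lattice_from_grid(grid, small_ca_params)
        ok = attempt_division(lat, (30, 30), small_ca_params, np.random.default_rng(0))
        assert ok
        assert lat.grid[30, 31] == SENSITIVE

    def test_necrosis_sweep_thresholds(self, small_ca_params):
        from dataclasses import replace

        grid = np.zeros((60, 60), dtype=np.int8)
        grid[20:40, 20:40] = SENSITIVE
        lat = _lattice_from_grid(grid, small_ca_params)
        lat.oxygen[:] = 0.0  # fully anoxic
        n = necrosis_sweep(lat, small_ca_params)
        assert n == 400
        assert np.sum(lat.grid == NECROTIC) == 400
        lat2 = _lattice_from_grid(grid, small_ca_params)
        lat2.oxygen[:] = 0.0
        none = necrosis_sweep(lat2, replace(small_ca_params, oxygen_death_threshold=0.0))
        assert none == 0

    def test_dense_disc_develops_connected_necrotic_core(self):
        """Once the mass outgrows the oxygen penetration depth, a central
        connected necrotic region appears."""
        from scipy import ndimage

        params = CAParams(grid_size=100)
        grid = np.zeros((100, 100), dtype=np.int8)
        yy, xx = np.mgrid[0:100, 0:100]
        grid[(yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2] = SENSITIVE
        lat = _lattice_from_grid(grid, params)
        solve_fields(lat, params)
        necrosis_sweep(lat, params)
        core = lat.grid == NECROTIC
        assert core[50, 50]
        labels, n_comp = ndimage.label(core)
        assert n_comp == 1


class TestRunSpheroid:
    def test_run_record_structure_and_invariants(self, small_ca_params):
        from dataclasses import replace

        params = replace(small_ca_params, grid_size=100)
        rec = run_spheroid(
            params, resistant_fraction=0.01, treatment_dose_uM=20.0, days=4.0,
            rng_seed=3, no_pregrowth=True,
        )
        assert len(rec["days"]) == 5  # day-resolution records incl. day 0
        assert np.all(rec["volume_mm3"] > 0)
        f = rec["resistant_frequency"]
        assert np.all((f >= 0) & (f <= 1))
        assert rec["volume_ratio"] > 0
        d = rec["initial_resistant_distances_um"]
        assert rec["outermost_resistant_distance_um"] == pytest.approx(d.min())

    def test_reproducible_runs(self, small_ca_params):
        from dataclasses import replace

        params = replace(small_ca_params, grid_size=100)
        kw = dict(resistant_fraction=0.01, treatment_dose_uM=20.0, days=3.0,
                  rng_seed=11, no_pregrowth=True)
        a = run_spheroid(params, **kw)
        b = run_spheroid(params, **kw)
        assert np.array_equal(a["final_lattice"].grid, b["final_lattice"].grid)
        assert a["volume_mm3"] == pytest.approx(b["volume_mm3"].tolist())
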