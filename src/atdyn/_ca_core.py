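"""Numba kernels for the hybrid cellular-automaton spheroid simulator.

Site codes on the lattice: 0 = medium, 1 = sensitive cell, 2 = resistant
cell, 3 = necrotic debris.  Chemical fields are solved to steady state on
the same grid (checkerboard successive over-relaxation with Dirichlet
boundary at the domain edge, linear uptake at living-cell sites).  The
Gillespie event loop uses rejection sampling: a uniformly proposed cell is
accepted with probability (P+M)/rate_max, which realises the required
selection probability (P_k+M_k)/sum(P_i+M_i) exactly.

Everything here operates on plain arrays and scalars so it can be JIT
compiled; :mod:`atdyn.spheroid` provides the user-facing layer.
"""

import numpy as np
from numba import njit

MEDIUM = 0
SENSITIVE = 1
RESISTANT = 2
NECROTIC = 3


@njit(cache=False)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False)
def sor_solve(c, uptake, k_uptake, boundary, omega, tol, max_iter):
    """Steady-state diffusion with linear uptake: laplacian(c) = k*c*uptake.

    ``c`` is modified in place (warm start); Dirichlet ``boundary`` value is
    imposed on the domain edge.  Returns the iteration count, or -1 if the
    maximum per-site update never fell below ``tol``.
    """
    ny, nx = c.shape
    for x in range(nx):
        c[0, x] = boundary
        c[ny - 1, x] = boundary
    for y in range(ny):
        c[y, 0] = boundary
        c[y, nx - 1] = boundary
    for it in range(max_iter):
        maxdiff = 0.0
        for parity in range(2):
            for y in range(1, ny - 1):
                x0 = 1 + ((y + parity) & 1)
                for x in range(x0, nx - 1, 2):
                    k = k_uptake if uptake[y, x] else 0.0
                    gs = (c[y - 1, x] + c[y + 1, x] + c[y, x - 1] + c[y, x + 1]) / (
                        4.0 + k
                    )
                    new = c[y, x] + omega * (gs - c[y, x])
                    d = new - c[y, x]
                    if d < 0.0:
                        d = -d
                    if d > maxdiff:
                        maxdiff = d
                    c[y, x] = new
        if maxdiff < tol:
            return it + 1
    return -1


@njit(cache=False, inline="always")
def _has_space(grid, y, x, r):
    """True if a medium or necrotic site lies within Euclidean distance r."""
    ny, nx = grid.shape
    ri = int(r)
    r2 = r * r
    for dy in range(-ri, ri + 1):
        yy = y + dy
        if yy < 0 or yy >= ny:
            continue
        for dx in range(-ri, ri + 1):
            if dy * dy + dx * dx > r2:
                continue
            xx = x + dx
            if xx < 0 or xx >= nx:
                continue
            if dy == 0 and dx == 0:
                continue
            t = grid[yy, xx]
            if t == MEDIUM or t == NECROTIC:
                return True
    return False


@njit(cache=False)
def cell_rates(
    grid,
    oxy,
    drgn,
    y,
    x,
    dose,
    lam_s,
    cost,
    o2_half,
    prolif_ic,
    death_max,
    death_ec,
    death_hill,
    crowd_r,
    no_crowding,
):
    """(P, M) for the cell at (y, x) given the current fields."""
    t = grid[y, x]
    o2 = oxy[y, x]
    if o2 < 0.0:
        o2 = 0.0
    g_o2 = o2 / (o2 + o2_half)
    rho = dose * drgn[y, x]
    if rho < 0.0:
        rho = 0.0
    if no_crowding:
        crowd = 1.0
    else:
        crowd = 1.0 if _has_space(grid, y, x, crowd_r) else 0.0
    if t == SENSITIVE:
        P = lam_s * g_o2 * crowd / (1.0 + rho / prolif_ic)
        rn = rho**death_hill
        M = death_max * rn / (rn + death_ec**death_hill)
    else:  # resistant: refractory to the drug, pays the fitness cost
        P = cost * lam_s * g_o2 * crowd
        M = 0.0
    return P, M


@njit(cache=False)
def collect_cells(grid, cx, cy, ct, idx_grid):
    """Scan the lattice into the cell list; returns the living-cell count."""
    ny, nx = grid.shape
    n = 0
    for y in range(ny):
        for x in range(nx):
            t = grid[y, x]
            if t == SENSITIVE or t == RESISTANT:
                cx[n] = x
                cy[n] = y
                ct[n] = t
                idx_grid[y, x] = n
                n += 1
            else:
                idx_grid[y, x] = -1
    return n


@njit(cache=False)
def fill_rates(
    grid,
    oxy,
    drgn,
    cx,
    cy,
    n,
    P,
    M,
    dose,
    lam_s,
    cost,
    o2_half,
    prolif_ic,
    death_max,
    death_ec,
    death_hill,
    crowd_r,
    no_crowding,
):
    total = 0.0
    for i in range(n):
        p, m = cell_rates(
            grid,
            oxy,
            drgn,
            cy[i],
            cx[i],
            dose,
            lam_s,
            cost,
            o2_half,
            prolif_ic,
            death_max,
            death_ec,
            death_hill,
            crowd_r,
            no_crowding,
        )
        P[i] = p
        M[i] = m
        total += p + m
    return total


@njit(cache=False)
def necrosis_sweep_grid(grid, oxy, threshold):
    """Living cells below the oxygen survival threshold become necrotic."""
    ny, nx = grid.shape
    n_dead = 0
    for y in range(ny):
        for x in range(nx):
            t = grid[y, x]
            if (t == SENSITIVE or t == RESISTANT) and oxy[y, x] < threshold:
                grid[y, x] = NECROTIC
                n_dead += 1
    return n_dead


@njit(cache=False)
def choose_daughter_site(grid, y, x, r=1.5):
    """Choose a free site in the Moore neighbourhood for the daughter.

    Free sites are medium or necrotic (dead debris may be replaced by a
    daughter of a dividing neighbour).  Cell-cell adhesion keeps
    spheroids compact, so sites inside the mass (debris) are preferred
    over open medium; within the preferred class the nearest sites are
    tied and broken uniformly at random (edge before diagonal).
    Placement is deliberately more local than the crowding check, so a
    cell that senses space within the crowding radius can still fail to
    divide if its immediate neighbourhood is sealed.
    Returns (y, x) or (-1, -1).
    """
    ny, nx = grid.shape
    ri = int(r)
    r2 = r * r
    for target in (NECROTIC, MEDIUM):
        best_d2 = 1e18
        count = 0
        for dy in range(-ri, ri + 1):
            yy = y + dy
            if yy < 0 or yy >= ny:
                continue
            for dx in range(-ri, ri + 1):
                d2 = dy * dy + dx * dx
                if d2 > r2 or d2 == 0:
                    continue
                xx = x + dx
                if xx < 0 or xx >= nx:
                    continue
                if grid[yy, xx] == target:
                    if d2 < best_d2 - 1e-9:
                        best_d2 = d2
                        count = 1
                    elif d2 <= best_d2 + 1e-9:
                        count += 1
        if count == 0:
            continue
        pick = int(np.random.random() * count)
        if pick >= count:
            pick = count - 1
        seen = 0
        for dy in range(-ri, ri + 1):
            yy = y + dy
            if yy < 0 or yy >= ny:
                continue
            for dx in range(-ri, ri + 1):
                d2 = dy * dy + dx * dx
                if d2 > r2 or d2 == 0:
                    continue
                xx = x + dx
                if xx < 0 or xx >= nx:
                    continue
                if grid[yy, xx] == target and d2 <= best_d2 + 1e-9:
                    if seen == pick:
                        return yy, xx
                    seen += 1
    return -1, -1


@njit(cache=False)
def push_line(grid, idx_grid, cx, cy, y, x):
    """Push cells along a random lattice direction to open a site at (y, x).

    Used only when the crowding rule is ablated: the cells between the
    mother and the first free site along the chosen ray each move one
    step outward; the vacated adjacent site is returned for the daughter.
    Tries the eight Moore directions in random order; returns (-1, -1)
    if every ray hits the grid edge before finding a free site.
    """
    ny, nx = grid.shape
    start = int(np.random.random() * 8)
    for a in range(8):
        k8 = (start + a) % 8
        ddy = DIRS8[k8, 0]
        ddx = DIRS8[k8, 1]
        # walk to the first free site along the ray
        steps = 0
        ty, tx = y, x
        found = False
        while True:
            ty += ddy
            tx += ddx
            if ty < 0 or ty >= ny or tx < 0 or tx >= nx:
                break
            steps += 1
            t = grid[ty, tx]
            if t == MEDIUM or t == NECROTIC:
                found = True
                break
        if not found:
            continue
        # shift occupants outward, starting from the far end
        for s in range(steps, 1, -1):
            fy = y + (s - 1) * ddy
            fx = x + (s - 1) * ddx
            gy = y + s * ddy
            gx = x + s * ddx
            grid[gy, gx] = grid[fy, fx]
            ci = idx_grid[fy, fx]
            idx_grid[gy, gx] = ci
            if ci >= 0:
                cx[ci] = gx
                cy[ci] = gy
        sy, sx = y + ddy, x + ddx
        grid[sy, sx] = MEDIUM
        idx_grid[sy, sx] = -1
        return sy, sx
    return -1, -1


DIRS8 = np.array(
    [[-1, -1], [-1, 0], [-1, 1], [0, -1], [0, 1], [1, -1], [1, 0], [1, 1]],
    dtype=np.int64,
)


@njit(cache=False)
def run_batch(
    grid,
    oxy,
    drgn,
    cx,
    cy,
    ct,
    P,
    M,
    idx_grid,
    n,
    total_rate,
    t,
    t_stop,
    turnover_left,
    dose,
    lam_s,
    cost,
    o2_half,
    prolif_ic,
    death_max,
    death_ec,
    death_hill,
    crowd_r,
    no_crowding,
):
    """Gillespie events with frozen fields until the turnover budget is
    spent or ``t_stop`` is reached.

    Rates of existing cells stay as computed at the batch start (the
    fields are only re-solved between batches); daughters get rates from
    the frozen fields at their site.  Division attempts that find no free
    site fail without consuming turnover budget.

    Returns (n, total_rate, t, turnover_left, events).
    """
    rate_cap = lam_s + death_max  # static upper bound on any P+M
    events = 0
    while turnover_left > 0 and t < t_stop:
        if total_rate <= 1e-12 or n == 0:
            t = t_stop
            break
        dt = -np.log(np.random.random()) / total_rate
        if t + dt > t_stop:
            t = t_stop
            break
        t += dt
        # rejection sampling: uniform proposal, accept with rate/rate_cap
        while True:
            i = int(np.random.random() * n)
            if i >= n:
                i = n - 1
            if np.random.random() * rate_cap < P[i] + M[i]:
                break
        ri = P[i] + M[i]
        divide = np.random.random() * ri < P[i]
        yx, xx = cy[i], cx[i]
        if divide:
            dy, dx = choose_daughter_site(grid, yx, xx)
            if dy < 0 and no_crowding:
                # crowding rule ablated: an enclosed cell still divides by
                # pushing the line of cells in a random direction outward
                # until the first free site, inflating the mass
                dy, dx = push_line(grid, idx_grid, cx, cy, yx, xx)
            if dy >= 0:
                grid[dy, dx] = ct[i]
                cx[n] = dx
                cy[n] = dy
                ct[n] = ct[i]
                p, m = cell_rates(
                    grid,
                    oxy,
                    drgn,
                    dy,
                    dx,
                    dose,
                    lam_s,
                    cost,
                    o2_half,
                    prolif_ic,
                    death_max,
                    death_ec,
                    death_hill,
                    crowd_r,
                    no_crowding,
                )
                P[n] = p
                M[n] = m
                idx_grid[dy, dx] = n
                total_rate += p + m
                n += 1
                turnover_left -= 1
                events += 1
        else:
            # drug-killed cells persist as debris (no clearance in vitro);
            # like the necrotic core, debris can be replaced by daughters
            grid[yx, xx] = NECROTIC
            idx_grid[yx, xx] = -1
            total_rate -= P[i] + M[i]
            last = n - 1
            if i != last:
                cx[i] = cx[last]
                cy[i] = cy[last]
                ct[i] = ct[last]
                P[i] = P[last]
                M[i] = M[last]
                idx_grid[cy[i], cx[i]] = i
            n = last
            turnover_left -= 1
            events += 1
    return n, total_rate, t, turnover_left, events
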