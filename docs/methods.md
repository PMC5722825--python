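# Methods

`atdyn` models when adaptive therapy (AT) — modulating drug dose to hold
tumour burden steady so that drug-sensitive cells competitively suppress
resistant ones — outperforms conventional maximum-tolerated-dose (MTD)
treatment. Four components share a common vocabulary: a non-spatial ODE
model with frequency-dependent resistant-cell fitness, a vascular-feedback
extension, a hybrid cellular-automaton (CA) tumour-spheroid simulator, and
the statistics of two-clone competition assays, together with synthetic-data
generators that stand in for the wet-lab inputs.

## Frequency-dependent fitness

Resistant cells divide at `lambda_R * f(p)` where `p` is their frequency.
The `linear` family is `f(p) = p`. The `sigmoidal` family is the scaled
logistic

    f(p) = f_min + (1 - f_min) / (1 + exp(-k (p - c))),

with lower asymptote `f_min` (fitness of rare resistant cells hemmed in by
sensitive neighbours), upper asymptote 1 (fitness once they have escaped
competition), midpoint `c` and steepness `k` (defaults `k = 20`, `c = 0.5`).
The logistic is the simplest two-asymptote family with an abrupt transition;
the non-spatial results are insensitive to the exact transition frequency,
and alternative shapes can be registered via `register_sigmoid` without
touching the dynamics code. A `constant` family exists for ablations.

## Non-spatial bolus-therapy model

Between treatments,

    dW/dt = lambda_W W g(N),    dR/dt = lambda_R f(R/N) R g(N),

with `g = 1` (exponential) or the normalised Gompertz factor
`log(K/N)/log(K/N0)`. A bolus at interval `theta` multiplies each
subpopulation by `1/(1 + dose/IC50)`; reference parameters are
`lambda_W = lambda_R = log(2)/10` per day, `IC50_W = 1`, `IC50_R = 100`,
`rho_MTD = 1`, `theta = 5` days, `N0 = 1e9` cells. Progression-free
survival (PFS) is the time to regain the pre-therapy size `N0` after first
dropping below it (0 if the burden never drops); overall survival (OS) is
the first crossing of 1e12 cells; both are linearly interpolated between
stored points and censored at the horizon. Integration uses LSODA restarted
at every bolus (`rtol = 1e-8`), since bolus kills are discontinuities, not
rate terms.

The analytic upper bound on the AT:MTD PFS ratio,

    1/f_min - (lambda_W / mu_W) (1/f_min - 1),

uses the continuous-time sensitive death rate under MTD. The simulator
kills by per-cycle factors, so the bound is checked with the equivalent
rate `mu_W = log(1 + rho_MTD/IC50_W) / theta`, the unique rate with the
same per-cycle survival.

### The adaptive dose controller

The controller starts at half the MTD dose and steps the dose up (down)
when the burden, measured immediately before each bolus, has grown
(shrunk) since the previous one, capped at the MTD dose, unchanged on a
tie. Two step conventions are implemented because the choice is
consequential:

* **additive** (default): a fixed step of 20% of the initial (half-MTD)
  dose. At the reference parameters the dose then oscillates between two
  levels bracketing the containment dose `e^(lambda_W theta) - 1 = 0.414`
  and the burden band *declines* slowly (about -2.4% per cycle), so PFS
  under AT is decided by resistant outgrowth — the behaviour on which the
  analytic bound and the benefit curves rest.
* **multiplicative**: the current dose is multiplied by 1.2 or 0.8. Any
  purely multiplicative rule of this kind is scale-free — it regulates
  changes in burden, never its level — and analysing the induced discrete
  map shows the level drifts *upward* by about +0.45% per cycle for every
  comparison timing, so the tumour re-reaches `N0` after ~50 days even
  with zero resistance. That spuriously truncates AT's PFS and destroys
  the benefit-vs-`f_min` structure, so it is not the default.

### Vascular feedback

The Hahnfeldt-style extension makes the carrying capacity dynamic:

    dW/dt = lambda_W W log(K/N),   dR/dt = lambda_R f R log(K/N),
    dK/dt = b N - d N^(2/3) K,

and a bolus also multiplies `K` by `1/(1 + dose/IC50_K)`. Note the
*un-normalised* Gompertz exponent `log(K/N)`: the two Gompertz variants in
this package deliberately differ, each kept exactly as its source model
defines it. With cells frozen, `K` relaxes to `(b/d) N^(1/3)`. Defaults
`b = 5.85`/day and `d = 8.73e-7`/day/cell^(2/3) derive from the published
Lewis-lung fit (5.85 and 0.00873 in mm^3 units) converted at 1e6
cells/mm^3; used as printed in volume units they would put the vascular
steady state far below a 1e9-cell tumour. "Metronomic" dosing is the MTD
machinery at lower dose and shorter interval, without burden feedback.
In regimen sweeps, frequent high-dose metronomic dosing outperforms AT
only when the antiangiogenic effect is strong (small `IC50_K`) — with it,
the vasculature never recovers between doses and even resistant cells
cannot grow; otherwise AT wins by preserving competitive suppression.

## Hybrid cellular-automaton spheroid model

A 2D cross-section of a tumour spheroid: one cell per 15 um lattice site
on a 150x150 grid (2.25 mm domain), states medium / sensitive / resistant
/ necrotic. Oxygen and drug obey steady-state diffusion with linear uptake
at living-cell sites and Dirichlet boundary at the domain edge
(checkerboard SOR, omega = 1.95, warm-started, converged when the largest
per-site update falls below 1e-6 of the boundary value). Because uptake is
linear the drug field is solved once with a unit boundary and scaled by
the dose, and the oxygen field is dose-independent.

Per-cell rates (per day):

* sensitive: `P = lambda_S g_O2 g_drug crowd`, `M = h(rho)`;
* resistant: `P = 0.9 lambda_S g_O2 crowd`, `M = 0` — refractory to the
  CDK inhibitor, paying only the 10% proliferation cost (hypoxia
  hypersensitivity of the resistant line is deliberately ignored);

with `g_O2 = o2/(o2 + 0.05)`, `g_drug = 1/(1 + rho/0.75 uM)`, and the
Hill kill `h(rho) = 0.85 rho^4/(rho^4 + (50 uM)^4)` per day. The drug
constants are solved from the two experimental anchors: net growth of a
well-oxygenated, uncrowded sensitive cell is ~0 at 20 uM (arrest, mostly
cytostatic) and strongly negative (~-0.56/day) at 50 uM (major cell
death). `lambda_S = log(2)/1.1` per day (26-h doubling). Oxygen constants
are literature-guided stand-ins: penetration depth 9 sites (135 um),
proliferation half-saturation at 5% of the medium oxygen level (~1% O2),
necrosis below 8%.

Event scheduling is the exact Gillespie algorithm: cell `k` is chosen with
probability `(P_k + M_k)/sum_i(P_i + M_i)` (implemented by rejection
sampling — uniform proposal accepted with probability proportional to its
rate — which realises the stated distribution exactly), divides with
probability `P_k/(P_k + M_k)` or dies, and time advances by an exponential
waiting time with mean `1/sum_i(P_i + M_i)`. For efficiency the fields and
rates are recomputed only after 10% of the population has divided or died;
within a batch daughters get rates from the frozen fields at their site.
At the start of each update loop every living cell below the oxygen
survival threshold becomes necrotic debris, which persists unless replaced
by a daughter.

Spatial rules, and the reasoning behind them:

* **Crowding**: a cell may divide only if a free site (medium or debris)
  lies within 2 sites (Euclidean); the daughter is placed in the Moore
  neighbourhood, nearest free sites first. A cell can therefore sense
  space yet fail to divide if its immediate ring is sealed — this is what
  buries slower resistant lineages behind the advancing sensitive front
  during pre-growth.
* **Dead cells persist**: drug-killed cells leave debris exactly like the
  necrotic core (there is no clearance in spheroid culture); the mass
  outline therefore never shrinks, matching the arrested — not shrinking —
  volume curves of treated spheroids.
* **Compaction**: daughters prefer debris sites over open medium
  (cell-cell adhesion keeps spheroids compact). Without this rule the
  death/birth turnover at an arrested rim inflates the outline into a
  debris halo, distorting volumes at the arrest dose.
* **No-crowding ablation**: `crowd = 1` everywhere and an enclosed
  daughter is accommodated by pushing the line of cells in a random
  lattice direction out to the nearest free site, so interior cells truly
  proliferate and the mass inflates.

Volumes follow the experimental convention: occupied cross-section area ->
equivalent-circle radius -> volume of the sphere with that radius (so a
0.07 mm^3 seed is a 17-site disc). A cohort run seeds 1% resistant cells
at 0.07 mm^3, grows untreated to 0.3 mm^3 (recording each resistant cell's
distance to the nearest medium site at treatment start), then treats for
24 days at constant drug concentration; arms at different doses share each
replicate's pre-grown spheroid. Escape means resistance above 10% at day
24.

### What the CA does and does not reproduce

All qualitative contrasts of the spheroid study emerge from these rules:
20 uM controls both volume and resistance while 50 uM sweeps resistance to
fixation with regrowth; escape probability falls steeply with the
outermost resistant cell's initial depth; removing pre-growth competition
or crowding releases resistance. The *absolute* volume increases are much
smaller than the reported medians (e.g. ~5% vs 38% at 20 uM, ~10% vs 930%
at 50 uM): with division confined to cells adjacent to free sites, the
radial expansion speed is ~0.7 sites/day at a 26-h doubling time, an order
of magnitude below what a 930% volume increase in 24 days implies
(+32 sites of radius). The original model's full parameterisation is not
available; reproducing those magnitudes would need a thicker proliferative
rim (larger placement range or active pushing by default) or a much faster
division rate, either of which would distort the burial dynamics that the
resistance results depend on. We kept the local-placement geometry and
report the volume medians as they come out.

## Competition-assay statistics

For populations `P, Q` with frequency `p = P/(P+Q)`, the selection
coefficient is the slope of `logit(p)` over time (least squares over all
points; per-interval pairwise slopes are also available, and the two agree
exactly for noise-free evenly spaced data). Frequencies of exactly 0 or 1
raise by default or, with `drop_boundary=True`, are excluded with a
warning — never pseudo-counted. For non-interacting exponential clones
`s = r_P - r_Q`, so monoculture growth rates (log-linear fit over the
first 72 h, reported per day) yield a prediction to compare against.

GFP-marker silencing contaminates the marker-negative gate. The
correction factor `c(t) = exp(a t + b)` is fitted to the log marker-
positive frequency of a pure GFP+ control assay. The published adjustment
multiplies GFP+ frequencies by `1/c` and GFP- frequencies by `(1-c)/c`,
then renormalises; it is implemented verbatim as the default, including a
guard at `c = 1` where the GFP- multiplier degenerates to zero (the GFP-
frequency passes through unchanged, with a warning). That recipe is not a
mass-conserving inversion of the silencing process — near `c = 1` it
crushes the GFP- compartment. The exact inversion (move the measured
GFP- excess `p (1/c - 1)` back to GFP+) is available behind
`conserve_mass=True` and is what quantitative pipeline-recovery checks
use; the verbatim form is kept as default for fidelity to the published
procedure.

Spheroid volumetry from images: `R = sqrt(S/pi)`, `V = (4/3) pi R^3` from
the projected area `S`.

## Synthetic data

`gen_growth_curves` draws multiplicative lognormal counting noise around
a deterministic exponential (log-slope estimates stay unbiased for any
noise CV). `gen_competition_assay` tracks three compartments (marker+
P, silenced P, Q) through exponential growth, binomial 1/10 thinning
every 3 days, exponential marker silencing, and a 10^4-event multinomial
cytometry draw per measurement; the default growth rate `log(10)/3` per
day balances the passage dilution so cultures are stationary, as in
routine passaging, and every dataset carries its generating truth.
Setting `stochastic=False`/`cytometry_events=None` gives exact series for
machine-precision round trips. `gen_spheroid_scenarios` builds a
deterministic battery of small lattices (all-sensitive, 1% random,
resistant rim, resistant core) for regression tests. None of these model
plating losses, gating error, or density-dependent growth in monolayer;
passing tests show the estimators are correct under the stated noise
models, not that real assays are free of systematic error.

## Problem sizes and numerics

Spheroid cohorts use 100 seeded replicates per arm in the acceptance
script and 40 in the test suite (the reference study used 1000); medians
are stable at these sizes relative to the tolerances used. Replicates
draw independent 31-bit seeds from a `SeedSequence` of the root seed, and
every run is bit-reproducible from its seed. Degenerate inputs are
defined throughout: empty populations give zero derivatives, `N >= K`
clamps the normalised Gompertz factor at zero, all-zero CA rates advance
time quiescently, and a fully sealed cell simply fails its division
attempt.

## Known limitations

The CA is a 2D cross-section with volumes reported via the equivalent-
sphere convention, not a 3D simulation; drug and oxygen medium
attenuation are therefore logarithmic rather than 1/r, which is why the
drug penetration depth is set large. Cell migration, pushing (outside the
no-crowding ablation), vasculature within the CA, and immune effects are
out of scope. The analytic benefit bound is implemented as a formula
only; the full analytic solution family behind it is not reproduced.
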