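# Methods

`nestherm` simulates the thermal environment and developmental fate of every
egg in a sea-turtle nest.  This note records the model, its assumptions, the
calibrated constants, the numerical choices, and what the synthetic test bed
does and does not demonstrate.

## Physical model

Temperature in the nest and surrounding beach obeys transient heat
conduction,

    rho C_p dT/dt = div(k grad T) + r,

over three subdomains: undisturbed **beach sand** (a 2 m diameter x 1.5 m
deep cylinder), the looser **nest-chamber sand** a female repacks around her
clutch, and the **eggs** themselves.  The source `r` is non-zero only inside
eggs, where each embryo deposits its metabolic heat.  Heat moves between
sand and eggs purely by conduction (Fourier's law); convection in air
pockets, moisture transport, evaporation and radiation are not modelled —
the measured (or synthetic) boundary series already integrate surface
radiation and weather.

### Subdomain properties

Sand is treated as a three-phase mixture of quartzite grains, water and air.
From the field measurements (dry bulk density, gravimetric moisture) the
volume fractions follow as

    f_solid = rho_dry / rho_particle,   f_water = w rho_dry / rho_water,
    f_air = 1 - f_solid - f_water.

Effective conductivity uses Mori–Tanaka effective-medium homogenisation with
the solid as matrix and water/air as spherical inclusions; effective heat
capacity uses the volumetric rule of mixtures `C = sum_i f_i rho_i c_i`.
Eggs are assigned the properties of water (they are ~80% water by mass).

Two calibration points deserve an explicit record:

* **Constituent constants.**  Water and air use handbook values (k = 0.6 and
  0.026 W m-1 K-1; rho c = 4.186 MJ and ~1.2 kJ m-3 K-1).  The quartzite
  constants are reconstructed from the published *effective* sand properties
  rather than taken from a handbook: a single quartzite conductivity of
  5.57 W m-1 K-1 (well inside the handbook quartzite range 5.4–7.7)
  reproduces the effective conductivity of *both* sands (2.2 and
  1.7 W m-1 K-1) from their distinct densities — a strong internal
  consistency check on the mixture model.  The quartzite volumetric heat
  capacity (rho c = 1.27 MJ m-3 K-1, i.e. c = 479 J kg-1 K-1 at
  2650 kg m-3) is pinned by the beach-sand value of 829.9 kJ m-3 K-1.
* **Heat-capacity units.**  The canonical subdomain heat capacities
  (829.9 / 661.3 / 4177.6) are volumetric values in kJ m-3 K-1: the egg row
  equals water's rho c exactly, and no mass-weighted specific heat can
  differ between two sands of equal moisture (mass weighting is invariant
  to bulk density).  `EffectiveProperties` therefore stores the volumetric
  value (the quantity the heat equation needs) and derives a specific heat
  against the reported bulk density.
* **Nest-sand water fraction.**  The two published sand heat capacities are
  not exactly proportional to the two published densities, which any
  equal-moisture mixture rule would force.  The canonical nest-sand water
  mass fraction is therefore set to 3.92% — inside the measured 4.0 ± 0.8%
  — which reproduces the nest value exactly and leaves its conductivity at
  1.70 W m-1 K-1.

The default subdomain table is then

| subdomain  | density (kg m-3) | k (W m-1 K-1) | rho c (kJ m-3 K-1) |
|------------|-----------------|---------------|--------------------|
| beach sand | 1282.2          | 2.2           | 829.9              |
| nest sand  | 1026.6          | 1.7           | 661.3              |
| eggs       | 1000            | 0.6           | 4177.6             |

All constituent constants and field measurements are config-overridable.

### Geometry

The egg chamber is an axisymmetric flask: a cylindrical neck (radius
0.09 m) over a truncated ellipsoidal bulb (0.13 m horizontal semi-axis,
0.12 m vertical semi-axis, base at the nest depth), 0.31 m tall in total —
the constant depth-minus-neck offset observed across field nests, so the
neck length is `depth - 0.31 m`.  The published record gives the flask
shape but not a parametric profile; these dimensions are replaceable
constants chosen to match literature averages for flatback nests.

Eggs are rigid 46.7 mm spheres packed by sequential gravity deposition:
each egg drops from the neck with a random lateral offset and settles by
steepest descent with averaged constraint projection (chamber walls shrunk
by the egg radius; pairwise non-overlap), with small seeded tangential
nudges so spheres roll off local peaks.  The procedure is deterministic
under its seed, guarantees penetration below 0.1 mm, and produces
gravity-settled random arrangements filling the chamber from the base —
the only properties of the arrangement that matter to heat transfer.  A
single egg settles exactly to the chamber's lowest point.

### Discretisation

The solver is a cell-centred finite-volume scheme on a rectilinear grid:
2 cm cells (default) in a box enclosing the chamber, geometrically
coarsening toward the domain borders (max 12 cm).  Interface conductances
use harmonic means, so material discontinuities are handled conservatively.
A cell belongs to an egg when its centre lies inside the egg sphere
(precedence egg > nest sand > beach); at 2 cm every 46.7 mm egg captures at
least one cell and typically 5–7, at 1 cm several tens.

Cells straddling an egg surface get partial-volume properties: conductivity
and volumetric heat capacity are blended by the exact egg overlap fraction
(4x4x4 subsampling), which removes the first-order staircase error of a
voxelised sphere; distributed sources weight each cell by its true overlap
volume.  Cell *tagging* (which egg owns a cell, for probes and point
deposition) remains by cell centre.

Time stepping is backward Euler at Delta-t = 1 h (optional substeps), which
is unconditionally stable and inherits a discrete maximum principle from
the M-matrix structure: with zero sources the solution can never leave the
envelope of the boundary values.  The system matrix is factorised once per
run (sparse LU, minimum-degree ordering) and each hourly step is one
triangular solve; grids beyond ~90k cells switch to preconditioned
conjugate gradients.  The per-step energy ledger (storage change minus
boundary influx minus source input) closes to linear-solver precision,
~1e-11 of turnover, against a 1e-6 acceptance bar.

Boundary conditions mirror the two-logger field setup: the 10 cm-depth
series is imposed (Dirichlet) on the top plane over the nest footprint
(the sand above 10 cm is outside the domain; the annulus beyond the
footprint is zero-flux), and the adjacent-sand series, transposed in depth
by a one-dimensional damped-wave model (amplitude exp(-dz/D), phase lag
dz/D, damping depth D = sqrt(2 alpha / omega) ~ 0.27 m for the beach sand),
is imposed on the lateral walls.  The bottom (1.5 m) is zero-flux.  The
initial field is the stationary solution under the t = 0 boundaries.  Which
model surfaces received which measured series is not documented in the
field workflow; this assignment keeps the problem well-posed and drives the
interior with both measured signals.

Each egg's wattage is deposited into the single cell containing its centre
("point" mode, mirroring a nodal heat flux), with a "distributed" mode
spreading it over the egg's overlap volume.  Point deposition has no
continuum limit at the source cell (the 1/r profile diverges), so the
source-cell temperature carries a resolution-dependent offset at 2 cm;
grid-refinement convergence is therefore demonstrated in distributed mode,
where halving the cell size moves the centre-egg temperature by < 0.05 C
(measured: 0.033 C on the reduced convergence scenario).

## Metabolic heat

Per-egg heating follows a three-step chain driven by a clutch temperature
proxy (by default the simulated centre egg, lagged one hour to keep each
step linear; a measured series can be substituted in validation mode):

1. **Development.**  Maturity integrates a development-rate thermal
   performance curve hourly, hatching at 100%.
2. **Reference heat.**  An embryo of maturity m produces
   `h(m) = h_max (e^(gamma m/100) - 1)/(e^gamma - 1)` mW at the 29.5 C
   reference (zero for a fresh egg, steeply rising toward hatching).
3. **Temperature adjustment.**  The reference heat is scaled by
   `Q10^((T-29.5)/10)`; optionally by the development-rate ratio
   `r(T)/r(29.5)`, which makes the coefficient temperature dependent and
   declines above the optimum.

Fate categories gate the flux, matching excavation practice: hatched/pipped
and full-term-dead embryos heat until hatch; pre-term-dead embryos stop at
two-thirds of development; undeveloped eggs never heat.  Category positions
are assigned randomly with a seed; proportions default to the observed
averages for modelled nests (hatched 37.8%, full-term 26.0%, pre-term
31.4%, undeveloped 4.8%).  The default ("unadjusted") model treats all eggs
as viable.

The population-specific equations behind steps 1–2 are unpublished fits, so
both are pluggable strategy objects.  The defaults are:

* development rate: asymmetric Gaussian, peak 2.4 %/day at 33.5 C, widths
  8.0 C below / 2.5 C above.  The peak sits in the 33–34 C band reported
  for flatback embryos, constant-temperature incubation anywhere in
  25–36 C completes within 80 days, and ~30 C incubation takes ~46 days.
  The sharp supra-optimal decline reproduces the counterintuitive field
  observation that hot nests (above the optimum) develop *slower* than
  nests a degree or two cooler.
* metabolic heat: h_max = 65 mW per embryo at 29.5 C, gamma = 4.  h_max was
  calibrated by running the 51-egg reference nest and matching the observed
  trimester warming pattern (~0 / ~1 / ~3 C centre-minus-adjacent by
  development trimester): 65 mW yields -0.03 / +0.40 / +3.49 C with every
  egg hatching.  Values of ~70 mW and above cross a feedback bifurcation in
  which the hottest eggs stall below 100% maturity at supra-optimal
  temperatures, their flux never terminates, and late warming inflates
  further — a regime the calibration deliberately stays below.
* Q10 = 2.0 — the canonical mid-range value for reptilian embryonic
  metabolism.

## Developmental outcomes

Per-egg temperature series (one per egg centre) are converted to:

* **Incubation duration** — hour at which maturity reaches 100%, in days.
* **Sex** — Hill TSD reaction norm on the log-temperature scale:
  `p_male = 1/(1 + exp((1/S)(ln P - ln T)))` with P = 30.3 C, S = -0.01.
  This placement is verified by the transitional range it implies:
  solving p_female = 5%/95% in closed form, `T = P exp(+/- S ln 19)`, gives
  29.4 and 31.2 C, matching the published range for this stock (a
  linear-temperature Hill with the same parameters does not).  The norm is
  applied to the mean temperature over the thermosensitive period (TSP,
  maturity 33.3–66.7%); an hourly-averaged variant is provided because a
  development model may aggregate either way and the two differ when the
  TSP spans the steep part of the norm.
* **Hatching success** — logistic in mean incubation temperature,
  `p = 1/(1 + exp(beta (T - 32.7)))`.  32.7 C is the published mortality
  inflection for sea turtles; the slope beta (default 1.0 per C) is a
  calibrated stand-in for the multispecies fit, config-overridable.

For comparison with standard field practice, the summary also predicts
outcomes from the adjacent-sand series and its +0.5 / +1.0 / +1.5 C
corrected variants.

## Synthetic test bed

The generator emulates the boundary phenomenology the simulator needs:

    T(z, t) = base + trend t + A exp(-z/D) sin(omega t - z/D) + AR(1) noise,

with defaults of 55 days, base 30.5 C, +0.055 C/day seasonal warming,
3.5 C surface diel amplitude, D derived from the beach-sand properties,
and AR(1) noise (sd 0.15 C, phi 0.7).  A 55-day scenario spans
55 x 24 + 1 hourly stamps (endpoints included), so eight-hourly validation
extracts 166 points.  Pseudo-"observed" logger series are the forward
model's own probe series plus independent Gaussian noise at the logger
accuracies (0.2 C for the base logger, 1.0 C for the button loggers).

What passing on this test bed shows: the conduction solver is quantitatively
correct (it is checked against closed forms independently), the coupling,
gating and bookkeeping are faithful, and the analysis chain recovers imposed
metabolic warming from logger-style series.  What it does not show: skill
against real beaches — the synthetic boundary has no rainfall or tidal
events, no mean temperature gradient with depth, no sand accretion, and the
pseudo-observations share the forward model's physics, so validation
metrics against them are upper bounds on field performance.

## Numerical details and edge cases

* Harmonic-mean interface conductivity; Dirichlet closures use half-cell
  conductances, so boundary values are imposed exactly in the flux sense.
* Ledger residuals are normalised by each step's energy turnover with a 1 J
  floor (a perfect-equilibrium step reads 0, not 0/0).
* Probe extraction maps a query point to the nearest egg centre; ties break
  to the lowest egg id.  Eight-hourly resampling keeps 00:00/08:00/16:00.
* Over-saturated sand (solid + water volume > 1), non-positive
  conductivities, all-Neumann boundary sets, grids too coarse to give every
  egg a cell, schedules shorter than the simulation window, and clutches
  that cannot fit the chamber all raise immediately with specific messages.
* R^2 is the squared Pearson correlation (the convention in the validation
  tables this mirrors); the 1 - SSE/SST definition is available and differs
  off the identity line.  Zero-variance series yield R^2 = NaN with a
  warning.
* All randomness (packing, fate assignment, boundary noise, logger noise)
  flows from explicit seeds; artifact files are written with fixed float
  formats so a config reproduces its outputs byte-for-byte.

## Problem sizes

The default reference simulation (51 eggs, 60 cm nest, 55 days hourly,
2 cm cells, ~45k-cell grid) runs in about a minute on one core: one sparse
factorisation plus 1320 triangular solves.  The solver verification cases
use a 1-D 240-cell column (diel wave) and a 24-cm 14k-cell box (point
source); the grid-convergence check compares 2 cm against 1 cm cells on a
reduced 8-egg nest over 1.5 days with distributed deposition.

## Known limitations

* No moisture–heat coupling; sand properties are constant in time (field
  moisture was observed stable over the season this emulates).
* Dead embryos stop heating instantly; residual metabolism and microbial
  decomposition heat are unmodelled.
* The hatching-success logistic is a clutch-level relationship applied per
  embryo; interpret per-egg values as relative thermal-stress indicators.
* Point-mode centre-egg temperatures include a resolution-dependent
  source-cell offset (see Discretisation); cross-resolution comparisons
  should use distributed mode.
* The chamber profile and physiological defaults are literature-calibrated
  stand-ins for unpublished population fits; all are config parameters.
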