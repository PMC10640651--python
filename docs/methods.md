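# Methods

`mangalmorph` is a reduced-complexity simulator of the centuries-scale
co-evolution of tidal flow, sand/mud morphology and mangrove vegetation in a
small barrier-enclosed estuary of the kind found on the North Island of New
Zealand, built to run management experiments (increased catchment mud
supply, mangrove clearance, supply reduction) on a desktop. This note
documents the model, its assumptions, the numerical choices, and what the
synthetic setting does and does not represent.

## The idealized setting

The domain is a 4 km x 2 km estuarine basin behind two non-erodible
barriers, connected through a central 300 m inlet to a 2 km x 2 km offshore
block whose bed drops linearly from the basin level to -100 m at the open
boundary (deep enough that exported sediment cannot shoal the approach).
The basin bed starts at -1.5 m MSL with a 25 m sandy substrate. Forcing is
a single semidiurnal constituent of 1.5 m range and 30 deg/hr frequency (a
12 h period exactly) at the seaward boundary, plus three rivers of 18 m3/s
each entering on the northern, landward and southern basin edges. The 30 m
river width is consistent with the hydraulic-geometry relation
`W = 7.2 Q^0.5` (30.5 m at 18 m3/s). River mud concentration is the
scenario control: 0 during spin-up, 5 mg/L pre-disturbance, 15 mg/L during
disturbance, and per-branch afterwards (the unquantified "intermediate"
management level is taken as the 10 mg/L midpoint).

The reference desk resolution is 60 m (a 100 x 33 grid); the 15 m
resolution of full research-grade runs is accepted by the grid builder but
is not the tested configuration. All reported metrics are per-area or
per-hypsometry quantities, so they remain comparable across resolutions.
The along-shore positions of the two lateral river mouths are only loosely
constrained (they enter at one and two thirds of the basin length); results
reported here do not hinge on that choice.

## Flow

Depth-averaged shallow-water flow on a staggered C-grid, with two
deliberate reductions: momentum advection is omitted (the basin is short
and friction-dominated, so the pressure-friction balance dominates; the
steady uniform-flow limit `u = C sqrt(h S)` is recovered exactly), and
horizontal momentum exchange is represented by a weak neighbour-averaging
filter on face velocities (weight 0.1) rather than an explicit eddy
viscosity. The filter leaves uniform flow untouched and exists to damp
grid-scale velocity noise at the inlet constriction, which nothing else in
an advection-free split scheme removes.

Time stepping is a Strang-split theta scheme (theta = 0.55): a half
y-sweep on either side of a full x-sweep (interior half-sweeps fused), each
sweep solving the coupled free-surface/continuity system implicitly along
its grid lines with theta-weighted surface gradients and fluxes and
implicit bed friction. This removes the surface-gravity-wave CFL limit (at
60 m and 300 s the wave Courant number is O(30) over the offshore slope)
while keeping the tidal co-oscillation essentially undamped: at dt = 300 s
the basin receives 77 % of the boundary range over the initial flat bed,
converging to the full range as dt decreases. Continuity is discretized in
flux form, so water volume is conserved to round-off against the boundary
and river ledgers. Depth positivity during wetting/drying (threshold
0.05 m) is enforced by a per-cell outflux limiter with inflow credit: a
cell may not export more volume than it stores plus what it receives, with
the scale factors relaxed monotonically so early termination never
overdraws a cell. Lateral boundaries impose a zero surface gradient, which
on a staggered wall reduces to zero normal flux; rivers enter as volume
sources distributed over their mouth cells.

Vegetation enters the momentum balance through the Baptist decomposition:
a representative Chezy value

    C_r = C_b + (sqrt(g)/kappa) ln(h/h_v) sqrt(1 + C_D n h_v C_b^2/(2 g)),  h >= h_v
    C_r = C_b,                                                              h <  h_v

with `C_b = 65 m^(1/2)/s`, and an additional momentum sink `-(lambda/2) u|u|`
with

    lambda = C_D n (h_v/h) (C_b/C_r)^2   (submerged),   C_D n   (emergent).

`n = m D` is the vegetation density (m/m2). The two object classes of a
vegetated cell (pneumatophores, then stems, ordered by height) are combined
sequentially, each submerged class taking the previous `C_r` as its bed
value; lambda contributions add. The decomposition means vegetation
*lowers* the bed shear stress felt by the sediment (`tau = rho g (u^2+v^2)/C_r^2`)
while *raising* the total flow resistance — the feedback at the heart of
the model. The drag coefficient C_D defaults to 1.

## Sediment

Two fractions. Mud follows the Partheniades-Krone law: erosion
`E = M max(tau/tau_ce - 1, 0)` scaled by the mud fraction of the 0.2 m
active surface layer and capped by what the substrate stack actually
holds; deposition `D = w_s c max(1 - tau/tau_cd, 0)` with `tau_cd` set
large, so deposition never shuts off. The mud parameters (`tau_ce = 0.2
N/m2`, `M = 1e-4 kg/m2/s`, `w_s = 0.5 mm/s`, dry density 500 kg/m3) are
calibration-grade defaults in the range reported for muddy intertidal
systems and are all config-exposed.

Sand uses a reduced-complexity capacity formulation in place of a full Van
Rijn predictor: an equilibrium suspended concentration
`c_eq = k (u^2 - u_cr^2)^1.5 / max(h, 0.5)` toward which the suspended load
relaxes at the settling rate, plus a bed-load vector aligned with the flow
and corrected for bed slope (a transverse component proportional to the
cross-flow slope, Koch-Flokstra style, and damping of upslope transport).
The `1/h` in the capacity gives channels an equilibrium depth; without it
the inlet scours without limit. Rivers carry no sand by default: at 60 m a
river's entire sand load would settle irreversibly inside its single mouth
cell (settling time seconds, residence minutes) and build an unbounded
tower — marine sand still enters through the open boundary, and the
management findings concern mud in any case.

Suspended fractions are advected donor-cell upwind with the exact face
volume fluxes realized by the flow solver, accumulated over a stride of two
flow steps, plus weak flux-limited horizontal mixing (1 m2/s). Outgoing
tracer mass per cell is capped at what the cell holds, so concentrations
stay non-negative and the global budget
(bed change + suspended change = river supply + boundary exchange)
closes to round-off; the engine records the per-season closure residual as
a first-class diagnostic.

Bed changes (erosion/deposition and bed-load divergence) are multiplied by
the morphological acceleration factor 90, so one simulated season of
morphology costs about two tidal cycles of hydrodynamics; within a season
the vegetation is frozen, which implements the seasonal coupling (four
vegetation updates per morphological year). Each accelerated flux is capped
at 0.1 m of bed change per update, a standard stability guard at scour
hot-spots. Every cell keeps a stratigraphy stack (nominal 0.1 m layers,
thickness + mud fraction): deposition grows the top layer with the
depositing sand:mud ratio, erosion consumes species volume top-down, and
the stack supplies both the erodible-composition fields and the top-1 m mud
fraction behind the "muddy region" metric. Barrier cells are non-erodible;
everywhere else erosion is floored by the 25 m substrate.

## Vegetation

A single species (the grey mangrove, *Avicennia marina*) with one cohort
per cell. Seasonal cycle: colonization at the first season of each
ecological year, growth every season, mortality at the last.

Colonization seeds every unvegetated basin cell at 3000 stems/ha when the
relative hydroperiod lies in (0, 0.5] (between mean high water and mean sea
level), the maximum bed shear stress over the representative tidal cycle is
below 0.2 N/m2 (config-switchable to the cycle mean), and growth is viable
(f C > 0.5 with C = 1 for an empty cell). Hydroperiod is measured over the
last simulated cycle of the seasonal burst with sub-step crossing
interpolation, using the wetting/drying threshold, so residual puddles do
not count as inundation. Cells cleared by a removal intervention only
reopen to seedlings the following ecological year.

Growth advances the stem diameter D (cm) by

    dD/dt = G D (1 - D H / (Dmax Hmax)) / (274 + 3 b2 D - 4 b3 D^2) * f * C

with height from the allometry `H = 137 + b2 D - b3 D^2`. G = 162 cm/yr is
a classic growth-law coefficient for the species lineage; b2 = 20.333 and
b3 = 0.56481 are fixed by requiring H(Dmax) = Hmax with a vertex at
Dmax = 18 cm, Hmax = 320 cm (the small stature of New Zealand mangroves),
making the growth bracket vanish identically at the ceiling. Integration is
explicit Euler at a quarter-year step; the rate never exceeds ~0.3 cm per
season, far from overshooting, and diameters are clipped at Dmax.

The stress factors are documented, swappable reductions, not
field-calibrated curves: the inundation fitness f ramps linearly from 0 at
hydroperiod 0 to 1 at 0.1, holds 1 through 0.5, and is 0 outside the band
(too dry above MHW, too wet below MSL); the competition factor
`C = B_half/(B_half + B)` decays with standing biomass per area, with stem
biomass `0.308 D^2.11` kg (D in cm) and `B_half = 40 kg/m2`. Both lie in
[0, 1], multiply into the growth rate, and gate mortality: a cohort whose
f C stays below 0.5 for five consecutive years self-thins to the largest
stem count at which the suppression lifts (computed in closed form; equal
to removing stems one at a time), or vanishes; one good year resets the
streak. Cells accreted above mean high water additionally taper their
density linearly over 0.5 m of excess elevation.

Roughness coupling: stems map to objects of height H and diameter D; each
tree carries `1e4 D^2` pneumatophores (D in m) of 10 cm height and 1 cm
diameter — a size-scaling chosen so a mature stand carries order 10^2
pneumatophores per m2. After a removal intervention with positive root
persistence, the pneumatophore class of cleared cells outlives the stems
for the configured number of years (field-reported persistence is ~2-5
years) before decomposing.

## Scenario engine and metrics

Every plan shares a backbone: 200 years of sand-only spin-up without
vegetation (establishing inlet and channel relief), 200 years of low mud
supply (5 mg/L), 100 years of high supply (15 mg/L), then the management
branch: continued high supply, mangrove removal of 25/50/100 % of the
vegetated area (seaward-first contiguous clearance by default, random mode
with explicit seed as the alternative), or supply reduction to 5 or
10 mg/L at years 430/450/500. Branches share a disturbance trajectory by
copying the run state at the branch year (checkpoint/restart supports the
same through files). A run is fully determined by its configuration and
seed; the only stochastic element is the optional random removal mode.

Annual metrics: accommodation space (basin volume below the +0.75 m high
water level), muddy-region fraction (basin area whose top metre of
substrate strictly exceeds 30 % mud), mangrove coverage, relative basin
area above MSL (A_MSL/A_tot: cells above 0 m and below high water over
cells below high water), annual river sediment yield SY (ledger mass;
volume through the dry mud density), and the tidal prism TP (flood-directed
inlet volume over the diagnostic cycle); SY/TP is reported as an annual
sediment volume over the prism volume. Channels are identified by residual
relief (more than 0.3 m below the 540 m moving-window median, or subtidal
below mean low water — the method the source imagery analysis leaves
unspecified), distances to them are Euclidean, and sedimentation rates are
compared between the < 100 m and 300-400 m unchannelized distance classes.

## What the synthetic setting shows — and what it does not

The generator reproduces the *structure* of the study system: geometry,
forcing, supply history and the feedback chain. It does not emulate wind
waves, storm discharge, sea-level rise, salinity, belowground organic
accretion or root-collapse, consolidation, or biostabilisation — all
excluded here as in the source design — and the desk-scale grid (60 m,
~2200 basin cells) resolves channel networks only coarsely. Emergent
percentages from full-resolution research runs are therefore treated as
directional anchors, not numeric targets: what passing tests establish is
that the coupled feedbacks run in the right directions (more mud supply →
strictly faster infilling and a strictly muddier substrate across the
5/10/15 mg/L levels; vegetation limits estuary-scale infilling relative to
a bare basin; complete removal *accelerates* net infilling and enlarges the
muddy region — the counterintuitive headline), with exact internal
conservation — not that any given percentage matches a particular real
estuary.

Two desk-scale shortfalls are known, quantified by the test suite and the
acceptance script, and deliberately left visible rather than calibrated
away:

* **Absolute infilled fraction.** With the mud supply held at 15 mg/L the
  relative basin area above MSL reaches ≈ 0.36 by year 600 (full-resolution
  runs exceed 0.5). The budget is closed: mud retention in the *domain* is
  ≈ 99 %, but roughly a third of the supply leaves the basin on the ebb jet
  and settles permanently on the deep offshore slope, and ~1.4 Mm³ of basin
  sand is exported the same way. The parameters that could raise basin
  trapping (settling velocity, dry bed density) are deliberate model
  constants, so the shortfall is reported as is; the low-supply control
  lands at ≈ 0.24 against the < 0.2 benchmark for the same reason in
  reverse (compressed sensitivity to supply). Both trajectories bracket the
  management branches correctly.
* **The levee-scale sedimentation pattern.** At 15 m resolution,
  unchannelized platforms near channels (< 100 m) accrete faster than
  platforms 300–400 m away while a forest stands, and the ordering reverses
  after clearance. At 60 m the cell width *is* the levee scale and the
  emergent channel spacing leaves almost no platform 300 m from a channel
  (the 300–400 m class holds 1–63 cells), so this contrast is not
  measurable here: rate–distance profiles are flat to non-monotone under
  every classification setting tried. The corresponding test states the
  full-resolution expectation and fails on this grid by design; the
  estuary-scale counterpart (removal ends with less accommodation space and
  a larger muddy region) does hold.

## Numerical summary

| quantity | value | note |
|---|---|---|
| dt (flow) | 300 s | theta scheme, wave-CFL free |
| theta | 0.55 | free-surface implicitness |
| sediment stride | 2 flow steps | transport/bed update interval |
| morfac | 90 | bed-change acceleration |
| burst per season | ~2 tidal cycles | 292 steps; last cycle is diagnostic |
| wet/dry threshold | 0.05 m | also the hydroperiod threshold |
| velocity filter | 0.1 | eddy-viscosity surrogate |
| bed-change cap | 0.1 m/update | per accelerated flux term |
| critical slope | 0.06 | avalanching threshold |
| deposition ceiling | high water | tidal deposition needs inundation |
| layer thickness | 0.1 m nominal | 48-layer stack, 25 m substrate |

Scaled-down problem sizes used by the test suite and the acceptance script:
60 m cells, 600-year scenario horizons, branches sharing the first 400
years; a full 600-year trajectory takes a few minutes on one core.
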