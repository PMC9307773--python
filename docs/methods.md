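# Model and methods

`biofiltersim` simulates a lab-scale packed-bed biofilter degrading a
moderately hydrophobic VOC (toluene is the motivating compound) and analyses
the steady-state structure of the biofilm that does the degrading.  This
note records the model, its assumptions, the numerical choices, and the
limits of what the shipped tests demonstrate.

## The model

**Gas phase.**  Contaminated air moves through the bed in plug flow (no
axial dispersion, no adsorption — an adsorption test on the sterile packing
showed none).  Per unit bed volume,

    dC_g/dt = ( -v dC_g/dz  -  rho_bulk * A * L * r_bar ) / eps

with superficial velocity `v` [m h^-1], bulk packing density `rho_bulk`
[kg m^-3], specific biofilm area `A` [m^2 kg^-1], local film thickness `L`
[m], depth-averaged film consumption rate `r_bar` [g m^-3 h^-1] and bed
porosity `eps`.  The inlet node is pinned to the scheduled concentration.
At steady state `eps` drops out; it only shapes transients.

**Biofilm.**  Each axial node carries one planar film on the dimensionless
coordinate x' in [0,1] (substratum at 0, gas interface at 1):

    dC/dt = (D / L^2) d2C/dx'^2 - Vmax * C * rho_bio / (Ks + C + C^2/KI)

with Henry's-law interface condition `C(1) = C_g / H` and zero flux at the
substratum.  The Haldane denominator makes the rate peak at
`C* = sqrt(Ks*KI)` (0.367 g m^-3 with the shipped kinetics) and decline
beyond it; that substrate inhibition is what allows two stable film states
to coexist over a window of gas concentrations — a diffusion-limited
high-activity state (steep internal gradient, interior near zero) and a
near-saturated low-activity state (flat profile, little consumption).

**Biomass and nitrogen.**  Film thickness follows the local biomass pool,
`L = X / (A * rho_bio)`.  Biomass grows at

    dX/dt = ( mu - a ) X,     mu = mu_haldane(C) * N / (kN + N)

and drains the packing's inorganic nitrogen, which mineralization slowly
replenishes:

    dN/dt = k_min * N_org - k_uptake * N - mu * f_N * rho_bio * A * L.

Oxygen, temperature, moisture, pressure drop and detachment are all outside
the model.  The tabulated yield `Y` is carried in `KineticParams` for
completeness but appears in none of the governing equations, so it does not
enter the dynamics.

### Which concentration drives growth (`growth_concentration_mode`)

The growth law is printed in terms of the *gas-phase* concentration while
the nitrogen drain is described as using the growth rate *averaged over the
film*.  Three readings were implemented and compared:

* `gas_literal` (default): one consistent `mu` from the local gas
  concentration drives both biomass growth and nitrogen uptake.  This is
  the literal growth law, and it reproduces the sharp one-day collapse of
  removal efficiency in the ramp scenario.
* `biofilm_average`: `mu` from the depth-averaged film concentration.
  Because the high-activity film keeps its interior near zero, growth is
  much slower; the ramp then shows a gradual multi-day decline instead of a
  sharp jump.
* The fully split reading (gas-based `mu` for growth, film-averaged for
  nitrogen uptake) removes the nitrogen brake from the fastest-growing
  nodes and lets biomass grow without bound; it is unphysical and was
  discarded.

### The ramp-jump parameter set (`ramp_jump_parameters`)

The shipped preset table lists biofilm diffusivities of 1.5e-10, 1.5e-11
and 1.5e-12 m^2 s^-1 for its three scenario columns while describing the
second scenario as differing from the first *only* in surface area
(0.95 -> 1.1 m^2 kg^-1).  These cannot both be right, and the physics
settles it: with D = 1.5e-11 m^2 s^-1 the diffusive flux into a mature film
caps whole-column removal near 7 g m^-3, so weeks of ~100 % removal at
inlet concentrations approaching 8 g m^-3 — the defining feature of the
ramp scenario — cannot occur.  `ramp_jump_parameters()` therefore combines
A = 1.1 m^2 kg^-1 with D = 1.5e-10 m^2 s^-1.  The presets themselves keep
the tabulated values.

## Numerics

**Discretization.**  Orthogonal collocation in both directions: total node
counts include the two boundary points, with interior nodes at shifted-
Legendre roots (25 axial x 10 film by default, matching the printed
counts).  Derivative matrices are built by barycentric Lagrange
differentiation and the film's average rate uses quadrature weights that
integrate the Lagrange basis exactly, so polynomials up to the grid degree
are differentiated and integrated to round-off.  The film's boundary nodes
are eliminated algebraically each evaluation — the interface from Henry's
law, the substratum from the zero-flux row of the first-derivative matrix —
leaving a pure ODE system in the interior nodes.

**Stiff integration.**  The coupled system (gas + films + biomass +
nitrogen, ~270 states at default resolution) is integrated with BDF and an
analytic dense Jacobian (verified against numerical differentiation to
~1e-9 relative error; it cut run time several-fold versus sparse finite
differencing).  The inlet schedule is piecewise constant, so integration
restarts at every breakpoint with the segment's inlet frozen; each segment
runs in local time from zero because the fast film transient after an
inlet step otherwise collides with the integrator's minimum-step floor,
which scales with |t|.  Default tolerances: rtol 1e-6, atol 1e-9.

**Negative excursions.**  Spectral advection of sharp inlet steps rings
slightly (the outlet can read a few thousandths of a g m^-3 below zero at
~100 % removal), and steep film layers undershoot on coarse node sets.
Rate laws therefore clip their concentration arguments at zero — states
are left untouched to preserve smoothness — and clip events are counted and
logged.  A first-order upwind scheme (`advection_scheme="upwind"`) is
available when monotone gas profiles matter more than spectral accuracy; it
delays the simulated collapse by ~3 days through numerical diffusion.

**Steady-state solver and continuation.**  The film boundary-value problem
is solved with a hybrid Powell root finder on the L^2/D-scaled residual
(Levenberg-Marquardt fallback), seeded either from saturation or from an
exponential boundary-layer ansatz with penetration depth
`sqrt(2 D C_s / r_peak)`.  `steady_states` multi-starts over a family of
layer steepnesses and dedupes; `multiplicity_scan` continues the
high-activity branch upward and the low-activity branch downward in gas
concentration and brackets each fold by bisection on the *distinctness* of
the two continued roots (bisecting on solver failure is unreliable: below
the lower fold a saturated seed quietly converges to the one remaining
root).  Stability labelling (optional) relaxes a 1 % perturbation for 50
film diffusion times and compares interface fluxes, which separate the
branches robustly even where interior concentrations are near zero.  At
the thickness a nitrogen-limited mature film reaches under the
two-steady-states parameters (L ~ 5.9e-5 m), the computed window spans
roughly 6.8-9.4 g m^-3, comfortably covering the 7.7-8.5 g m^-3 band where
the high-to-low transition is observed.  Interface fluxes from the 20-interior-node solver
agree with a 500-point finite-difference multi-start oracle to better than
1 % across presets (see `tests/test_acceptance.py`); at the default
10-node film the flux error can reach ~10 % in strongly diffusion-limited
regimes, which matches the resolution of the printed node counts.

## The ramp scenario: what the model reproduces and what it does not

Under a daily inlet staircase of +0.272 g m^-3 (starting at one increment
on day 1), the simulation at `ramp_jump_parameters()` shows:

* a start-up phase (~3 days) while the initial film (X0 = 0.003 g kg^-1,
  L ~ 2.7e-8 m) grows into the load;
* weeks of ~100 % removal while nitrogen limitation settles the biomass
  near X ~ 5.7 g kg^-1 (L ~ 5.2e-5 m), where the net growth rate
  self-balances against decay;
* a first biofilm fold crossing at day ~30, inlet ~8.2 g m^-3 — the
  film multiplicity analysis puts the high-activity branch's fold between
  8 and 9 g m^-3 at that thickness — after which a saturation front creeps
  down the column;
* a one-day collapse of end-of-day RE from ~100 % to ~38 % when the front
  breaks through, at day 36, inlet ~9.8 g m^-3;
* hysteresis: lowering the inlet one increment after the collapse does not
  restore high removal within five days, distinguishing the steady-state
  jump from biofilm die-off (which would take weeks at these decay rates);
* the film's interface/substratum concentration ratio at a near-inlet node
  switching from > 5 to < 1.2 within about one hour of the local flip.

The collapse magnitude and the post-drop efficiencies land close to the
reported behaviour; the collapse *day* (36 vs 30) and therefore the
bracketing inlet concentrations (9.5/9.8 vs 7.9/8.2 g m^-3) do not.  The
difference is the front propagation: here, partially saturated films keep
removing ~0.12 g m^-2 h^-1 (their kinetic-limited flux, confirmed by the
finite-difference oracle), which holds downstream nodes below their fold
for several more daily increments.  A same-day whole-column cascade at the
first fold crossing could not be produced from the stated equations at any
tested node count (film 10/12/16, axial 25/27), growth mode or advection
scheme; the discrepancy most plausibly sits in unstated details of the
original integrator's handling of the daily inlet discontinuities.  The
numbers the acceptance script reports are computed, not adjusted.

## Synthetic observations

`synthesize_observations` emulates the measurement process of the
motivating experiments: daily triplicate gas-chromatography readings of the
outlet, i.i.d. Gaussian with sd 0.10 g m^-3 (the reported measurement
scatter), summarised as replicate means with standard errors
(0.10/sqrt(3) ~ 0.058 g m^-3 in expectation).  It reproduces none of the
structure of real measurement error — drift, autocorrelation, flow
fluctuations — so passing comparison-statistics tests shows the pipeline's
arithmetic, not field performance.

## Problem sizes in the shipped tests

Unit tests run on reduced grids (5-15 axial, 5-12 film nodes) and short
horizons (hours); the acceptance suite runs the full 40-day ramp once at
the default 25 x 10 resolution and shares it across checks.  The
finite-difference oracle uses 500 points (2000 in spot checks).  Film
thicknesses for the solver-vs-oracle comparison scale with each preset's
diffusion length (5e-5, 1.6e-5, 5e-6 m) so both discretizations resolve
the reaction layer.
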