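# Methods

`lungchip` simulates the transport of inhaled nanoparticles in a gas-liquid
dual-microchannel device: an air channel above a cell-culture medium channel,
the two separated by a thin perforated membrane (the microfluidic analogue of
the alveolar air-blood barrier).  The model has two one-way-coupled stages --
a steady channel-flow solve and stochastic Lagrangian particle tracing -- plus
a metrics layer that turns particle fates into the figures of merit used in
inhaled-delivery studies.

## Geometry

The device is two-dimensional: x streamwise, y vertical.  The media channel
(height `h_media`, default 100 um) sits at the bottom, the membrane band
(thickness `b` = 10 um) above it, and the air channel (`h_air` = 100 um) on
top; channels are `l` = 2 mm long.  Cylindrical membrane pores become
through-slots of width `d` spanning the membrane thickness -- the 2D analogue
of a circular perforation.  Slots tile the porous region (default the full
channel overlap `[0, l]`) left to right with period `d + p2p`, where `p2p` is
the *edge-to-edge* pore spacing; the layout convention matters because pore
spacing specifications are ambiguous, and it is fixed here so a configuration
is fully reproducible.  `d = 0` encodes an impermeable membrane, which is the
limiting case every verification in `verification_suite` uses.  Reference
porosity cases: `d`/`p2p` of 10/10, 10/5, 3/10 and 3/5 um (pore-area fractions
0.50, 0.67, 0.23 and 0.375).

## Flow model

Both phases are Newtonian and incompressible: air at 37 degC (rho = 1.123
kg/m^3, mu = 0.019 mPa s, hard-sphere collision diameter sigma = 346 pm,
specific gas constant R = 290 J/(kg K)) and a water-like medium at 37 degC
(rho = 1000 kg/m^3, mu = 0.718 mPa s).  The channel Knudsen number
Kn = kB / (sqrt(2) pi sigma^2 rho_a R 2h) evaluates to 4e-4 for the 100 um
air channel, far below the 0.01 continuum threshold, so no-slip applies.
Channel Reynolds numbers are 6e-3 (air) to 0.14 (media) at the fastest inlet
speed of 1 mm/s; the solver therefore drops the convective term and solves the
steady **Stokes** equations, which also makes the discrete problem linear (a
property the tests exploit: doubling the inlets exactly doubles the field).
The gravitational body force on the fluid is absorbed into a reduced pressure:
with constant density per phase it is hydrostatic and dynamically inert, and
retaining it across two stacked phases of very different density would
manufacture a spurious transmembrane pressure.  Gravity acts on particles
only.

Discretization is a marker-and-cell staggered grid (velocities on faces,
pressure in cells), second-order centered viscous terms, tangential no-slip
imposed through half-cell mirror ghosts.  The vertical step `dy` is chosen to
divide `h_media`, `b` and `h_air` exactly (default target 2.5 um) so the
membrane faces land on cell faces; in pore-resolving mode the streamwise step
is `d/6` or finer.  Boundary conditions: prescribed inlet velocity profile
(uniform plug by default; a fully developed parabola is available and is used
for the analytic-profile verification), zero outlet pressure through a ghost
cell (which also pins the pressure level of each connected component), and
no-slip on all solid-fluid interfaces.  An optional Hele-Shaw body force
`-12 mu u / depth^2` approximates a finite out-of-plane depth ("shallow
channel"); the verification suite confirms that enabling it with a realistic
2 mm depth leaves the deposition rate unchanged within Monte-Carlo error.
The saddle-point system is solved with a direct sparse LU factorization; MAC
staggering is inf-sup stable, so no pressure stabilization is needed.  The
mid-channel profile of the impermeable-membrane case matches the analytic
parallel-plate parabola to better than 0.1% at the default resolution, and
the discrete divergence is at round-off level.

### The membrane in the flow solve: `sealed` vs `open`

Two hydraulic treatments of the perforated membrane are provided, and the
choice is physically consequential:

* **`sealed` (default).**  The membrane, pore slots included, is closed to the
  *fluid*: each channel keeps its imposed flux, the pore interiors are
  quiescent, and particles cross the membrane driven by gravity and Brownian
  motion alone.  This emulates a device in which surface tension pins the
  air-liquid interface at the pores and blocks bulk flow through them, and it
  reproduces the reported behavior of such devices (essentially complete
  capture of 900 nm aerosols at 0.3 mm/s, see below).
* **`open`.**  The slots are resolved as fluid and the channels exchange flow.
  Because the media is ~38 times more viscous than air, the pore array then
  short-circuits the channels: within a few hundred micrometers of the inlet
  most of the media inflow crosses into the air channel, the air channel flux
  roughly doubles, and a fifth of the large particles are blown out of the air
  outlet.  This mode is kept because it is the honest solution of the fully
  connected domain; its flux bookkeeping (inlet = outlet + net pore exchange
  per channel, zero net exchange for a symmetric device with identical fluids)
  is tested.

## Particle model

Each rigid spherical particle (diameter `dp` 10-900 nm in the reference
sweeps, density `rho_p` = 1180 kg/m^3) obeys

    mp dup/dt = Fd + Fb + mp (1 - rho_i/rho_p) g,

with Stokes drag `Fd = 3 pi mu dp (u_f - up)`, a Gaussian Brownian force of
per-step amplitude `sqrt(6 pi kB mu T dp / dt)`, and the buoyant weight
directed -y (gravity perpendicular to the flow).  Fluid properties are those
of the particle's current phase: air in the air channel *and inside pores*,
medium below the membrane underside.  Two-way momentum coupling, particle
collisions, inertial lift and electrostatics are excluded by construction;
the Cunningham slip correction to the drag is deliberately omitted so that
the drag law is exactly Stokes (adding it would change nanometre-scale
results and is left to the user via an effective viscosity if needed).

Two integrators:

* **Inertial** -- the linear-drag momentum equation has an exact one-step
  exponential solution (`exponential_drag_update`), with Brownian and
  gravitational forcing treated as piecewise-constant impulses.  It is
  unconditionally stable even though the momentum relaxation time
  `tau = rho_p dp^2 / 18 mu` (3e-10 s at 10 nm, 3e-6 s at 900 nm in air) is
  many orders below the transport time step.  Retained for validation and for
  the 10 um benchmark particles.
* **Overdamped (default for submicron particles)** -- with `tau` femto-to-
  microseconds, inertia is irrelevant and the position Langevin update
  `x += (u_f + v_s) dt + sqrt(2 D dt) zeta` is used, with settling velocity
  `v_s = (rho_p - rho_i) g dp^2 / 18 mu` and Stokes-Einstein diffusivity
  `D = kB T / (3 pi mu dp)`.  This reproduces *exactly* the per-step
  displacement statistics of the Brownian force integrated through the drag
  law in the tau -> 0 limit (the algebra collapses to the same variance);
  the tests confirm the two integrators give statistically identical fate
  rates for 400 nm particles.

**Boundaries.**  The membrane top is a sticky (absorbing) substrate: a
particle whose sub-step crosses a solid membrane segment is frozen at the
crossing point and counted as deposited.  Pore mouths pass particles through;
a particle leaving a pore's lower mouth switches phase to the medium and its
transfer time is recorded.  Transfer is one-way: the membrane underside,
pore mouths included, reflects from below, consistent with a fate model in
which translocated particles do not return (and with the slow media-side
flow, re-entry would be a second-order correction at most).  The channel
outlets remove particles (exit time and height recorded at the media
outlet); every other wall -- air-channel ceiling, media floor, pore side
walls, the inlet plane -- reflects specularly.  The step-size rule makes the
per-step displacement at most a quarter pore width (advective and r.m.s.
Brownian parts separately), so boundary events are resolved one at a time.

**Release.**  Particles start uniformly distributed over the air-channel
inlet height (with a 1e-3 h margin off the walls), at the local fluid
velocity by default ("inert" zero-velocity start available).  The release
count is configurable; 1000 per case is the default, giving a binomial
standard error of at most 1.6 percentage points on any rate.

**Randomness and reproducibility.**  Every particle owns a counter-based
Philox substream keyed by (master seed, particle id) and consumes it only on
its own updates.  Results are therefore bit-reproducible for a fixed seed and
independent of scheduling order, ensemble composition, or how many steps
other particles take.  Media-phase particles advance with an integer-multiple
stride of the base time step (their rectangular-channel geometry and slower
flow tolerate a coarser step); the stride is derived once per case from the
media-side speed and diffusivity.

## Metrics

* **Deposition rate (epsilon)** -- deposited / released; **transfer rate** --
  translocated / released.  For complete runs epsilon + transfer + air-outlet
  escape = 1 exactly.
* **Deposit distribution** -- mean and population standard deviation of
  deposit positions x/l.  The ideal uniform deposition has mean 1/2 and
  standard deviation 1/sqrt(12) ~ 0.2887 (the exact uniform moments are used
  as the reference; note "1/12" sometimes quoted for this reference is the
  variance, not the standard deviation).
* **Outlet distribution** -- mean and standard deviation of media-outlet
  crossing heights y/h, floor = 0, membrane side = 1.
* **Band concentration** -- counts per equal-length band divided by the band
  measure (band length x channel height, unit depth -- the 2D reading of a
  "band volume") and by a reference areal concentration C0; the streamwise
  axis is normalized by the convection-diffusion length 3 h Pe / 16 with
  Pe = 2 u h / D.
* **Concentration-time curve** -- cumulative fraction of released particles
  that have left through the media outlet, differentiated on a 200-point
  uniform grid spanning the first to last exit (one pad bin each side so the
  rate returns to zero; the binning is a numerical-differentiation choice,
  made explicit because it is not canonical).  A Gaussian
  `A exp(-(t - tmax)^2 / 2 w^2)` is least-squares fitted to the rate,
  initialized from the raw peak; `cmax`/`tmax` are the fitted peak value and
  location, and the area under the rate curve recovers the transfer rate.
  Runs with fewer than 5 exits return the raw curve flagged unfit.

## Verification suite

Four zero-porosity limiting cases (`verification_suite`):

(a) the mid-channel velocity profile vs. the analytic parallel-plate solution
(< 1% required, < 0.1% achieved); (b) band-averaged concentration of 1 um
particles under drag + Brownian forces decaying monotonically along the
channel, with exact particle accounting -- run at a reduced Peclet number
(u = 10 um/s, h = 100 um, Pe ~ 84) so that diffusive depletion is measurable
within a 2 mm channel, whereas the original benchmark's Pe ~ 3.4e6 would
need meters of channel; (c) depth-independence of the deposition rate with
the shallow-channel drag enabled (2 mm depth vs. strictly 2D); (d) the
sedimentation regimes of water-carried benchmark particles in a single
channel (1 um / 2200 kg/m^3: washed out at 0.3 mm/s, deposited at 0.03 mm/s;
10 um / 1470 kg/m^3 in a 300 um channel: entrance-concentrated at 0.1 mm/s,
spread out at 0.3 mm/s), with the channel length scaled from 15 mm to 2 mm.
Because particles are released uniformly down to the substrate, a thin
near-floor layer deposits in the entrance region at any speed; "washed out"
is therefore scored as a small residue (< 10%, and < 1/4 of the slow-flow
deposition), not literally zero.

## What the synthetic conditions do and do not show

All inputs are generated: there is no measured data in the pipeline.  The
simulated conditions are the reference device values (100 um channels, 2 mm
length, 10 um membrane, the 10/5/3 um pore layouts, 0.3 and 1 mm/s inlets,
1180 kg/m^3 particles, both phases at 37 degC).  Passing tests show that the
implemented transport model has the documented analytic limits and
reproduces the expected qualitative physics (Brownian-dominated capture of
small particles, gravity-dominated capture of large ones, the deposition
minimum near 200 nm, porosity- and velocity-controlled translocation,
membrane-side accumulation of large transferred particles).  They do not
show that a physical device will match quantitatively: cell layers and
surface chemistry, membrane wetting, pore-scale 3D flow, slip corrections at
the smallest diameters, inlet nebulization and polydispersity are all outside
the model.

## Numerical defaults and scaling choices

* Time step: automatic, min(quarter pore width / max speed, (quarter pore
  width)^2 / 2D); for pore-free domains the length scale is h/8.
* Media-phase stride: floor(media-safe step / base step), capped at 64.
* Trend suites: 1000 particles/case; the fate-accounting case reports >= 600.
* Default `max_time` 300 s (simulated); unfinished particles are flagged, and
  rates that only need air-phase resolution are insensitive to it.
* Direct LU on the saddle-point system up to ~3e5 unknowns (the pore-resolving
  open mode at d = 10 um); the sealed mode needs only ~5e4.
* Tolerances: relative linear-system residual < 1e-8; normalized divergence
  < 1e-7; Gaussian fits bounded to positive amplitude/width.

## Known limitations

2D pores cannot represent azimuthal flow around cylindrical perforations; the
sealed/open dichotomy brackets, but does not resolve, the true pore-scale
hydraulics of a wetted membrane.  Deposition on a sticky wall from a
discrete-step random walk carries an O(sqrt(2 D dt)) boundary-layer bias,
controlled by the step-size rule and quantified against a finite-difference
oracle in the tests (within 5 percentage points).  The Gaussian fit is a
summary, not a model: strongly skewed exit-time distributions (large
particles in slow media flow) are compressed into (cmax, tmax) with the
area still matching the transfer rate.
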