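# Methods

`larvaflow` models how millimetre-scale substrate topography reshapes
wave-driven boundary-layer flow and thereby alters the settlement of coral
planula larvae.  It replaces the laboratory stages of such a study -- an
oscillatory flume, particle tracking velocimetry (PTV), and a finite-element
flow solve -- with analytic synthetic flow fields, and implements the analysis
stages (vortex identification, settling windows, an agent-based swimmer
simulation, settlement statistics) as tested library code.  Units are mm, s,
mm/s, and s^-2 (Q-criterion) throughout; x is streamwise, y vertical with
y = 0 at the substrate base; fields are periodic in x and in time.

## Synthetic flow fields

**Forcing.** A sinusoidal free stream U(t) = U0 sin(2 pi t / T), default
U0 = 45 mm/s and T = 5.5 s -- wave-dominated shallow-reef conditions.
phase0 = 0 puts a flow reversal at t = 0.  Seawater kinematic viscosity
defaults to nu = 0.85 mm^2/s (approx. 27.5 C); the oscillatory boundary-layer
thickness is delta = sqrt(2 nu / omega) ~ 1.22 mm at the defaults.

**Flat substrate.** The exact oscillatory Stokes-layer solution
u(y, t) = U0 [sin(wt) - e^(-y/delta) sin(wt - y/delta)], v = 0.  This is an
exact Navier-Stokes solution with no-slip at the wall; its near-wall phase
*leads* the free stream, which matters for both settling windows and tracer
drift.

**Ridged substrate.** Rectangular ridges of height h, width h (the ridge
cross-section is not constrained by the modelled experiments; a square
section is assumed and configurable), and edge-to-edge spacing s = 3h.
The field is composed from a streamfunction, so it is divergence-free and
vanishes on all solid surfaces:

* above the ridge-crest plane: the Stokes layer referenced to the crest
  plane, blended on with psi_blend = psi_stokes(Y) * smoothstep(Y / b_t)
  where Y = y - h.  The blend thickness b_t regularizes the gradient
  discontinuity at the crest plane and is deliberately small
  (default 0.1 mm, two default grid cells): a thick blend would create an
  artificial low-velocity cushion above the crests that the settlement speed
  gate would misinterpret as shelter.
* inside each inter-ridge cavity: a single recirculation cell
  psi_cav = A(t) sin^2(pi X / s) sin^2(pi Y / h) in local cavity coordinates.
  The cell amplitude tracks the magnitude of the free stream with a phase
  lag, A(t) = g |U(t - T/4)| by default: the sheltered in-cavity flow is
  slowest while the outer flow peaks and fastest around the reversal, when
  the decelerating outer stream washes through the gaps.  This phasing
  matches the observed behaviour of ridged-substrate boundary layers (near-
  substrate speed minimal at peak flow, slightly elevated at the turning
  point -- the opposite of a flat substrate).
* the gain g is calibrated so the peak in-cavity speed equals 6 mm/s for the
  2.5 mm ridges, the top of the observed in-cavity speed range.  For other
  ridge heights the default peak speed scales linearly with h
  (2.4 mm/s per mm): at fixed spacing-to-height ratio a shear-driven groove
  flow is geometrically self-similar, so the recirculation speed scales as
  (wall shear) x (depth).

**Gridded fields.** Grids default to 0.05 mm spacing with 64 stored time
slices per period (power-of-two, FFT-friendly); sampling interpolates
bilinearly in space and linearly in periodic time.  Gridded velocities are
obtained by *central-differencing the sampled streamfunction*, not by
sampling u and v directly: the discrete central divergence is then
identically zero at interior fluid nodes (the stated bound, 1e-6 U0/dx,
holds with machine-precision margin).  Solid nodes are masked to exactly
zero.  Known limitation: the analytic construction has zero vertical
velocity everywhere above the crest plane, so it cannot transport larvae
vertically by flow; see "What the synthetic fields do not reproduce".

## PTV

Synthetic tracer imagery is rendered at 90 frames/s and 31 um/px with
Gaussian spots and additive uniform noise.  Detection takes intensity-
weighted centroids of 8-connected components above a threshold expressed as
a fraction of the frame maximum (default 0.5; lower it for dense seeding,
where overlapping spots raise the frame maximum).  Linking is greedy nearest-
neighbour in order of ascending distance with a hard search radius; unmatched
detections start new tracks; no outlier rejection is applied (the linking
stage is kept to its documented defaults rather than layering heuristic
filters on top).  Velocities are finite differences between consecutive track
points, assigned at the link midpoint, and averaged per grid cell (default
0.5 mm) within 40-frame phase windows (0.44 s), with per-cell sample counts
retained and empty cells flagged missing rather than zero.

## Flow analysis

Velocity gradients use second-order central differences, with second-order
one-sided stencils adjacent to the solid mask and domain edges; differences
are never taken across solid nodes.  The Q-criterion is
Q = 1/2 (|Omega|^2 - |S|^2) with Frobenius norms; for 2D divergence-free
fields this equals det(grad U), which the tests use as an independent oracle.
The vortex threshold Q_thresh is the population SD of Q over all fluid nodes
and all time slices of one period of the dataset under analysis; vortex
regions are 4-connected components of Q > Q_thresh with at least 4 cells
(suppressing single-cell noise).  Band speed is the spatial mean of |U| over
fluid nodes within 1.5 mm of the *local* surface (cavity floors and crest
tops), with a cavity-restricted variant.  Settling windows are maximal
intervals with band speed below the larval threshold; the series is treated
as periodic (a window spanning the wrap counts once) and boundaries are
located by linear interpolation.  The default threshold is
u_l + 1 SD = 4 mm/s -- the settlement gate of the swimmer model; a plain
u_l cutoff is available via the `threshold` argument, since both conventions
are in use for defining settling windows.  The
turbulence diagnostic is the periodogram power fraction outside DC and the
fundamental bin +/- 1, over >= 4 periods.

## Agent-based settlement simulation

Larvae are neutrally buoyant ellipsoids (semi-axes a = 0.25, b = 0.15 mm;
shape parameter alpha = (1-(b/a)^2)/(1+(b/a)^2) = 0.47) swimming at
u_l = 3 mm/s along their major axis:

    dr/dt     = U + u_l n_hat
    dtheta/dt = omega_z / 2 + alpha g_hat . S n_hat      (Jeffery rotation)

Integration is explicit Euler at dt = 0.01 s (0.18% of the period; the
displacement per step stays below ~1.5 body lengths), with RK4 available for
convergence checks; the Jeffery tumbling period in simple shear is recovered
within 1% at this step.  The seeding lattice is deterministic: 30 x-positions
across one periodic domain at 10 mm height, 32 orientations, 20 start phases
-- 19,200 agents; there is no randomness anywhere in a run.  Boundary
conditions: periodic in x, open absorbing top, rigid bottom.  Contact is
centre-within-b of a solid surface; a larva settles on contact when its total
speed |dr/dt| is below u_l + 1 SD = 4 mm/s, otherwise the penetrating
displacement component is projected onto the surface tangent (slide;
bouncing was rejected as unphysical for ciliated larvae) and the orientation
is left unchanged by the wall.  Agents unresolved after 120 s (~22 periods)
are reported as such rather than forced to an outcome.  Settled agents do not
alter the flow (one-way coupling) and exited agents do not re-enter.

## Statistics

Settlement proportions are variance-stabilized with the arcsine-square-root
transform before testing.  One- and two-way fixed-effects ANOVA and Tukey HSD
contrasts are delegated to statsmodels behind the module interface; a
brute-force sums-of-squares F computation serves as the test oracle.  For
simulation ANOVA the replicate grouping must be supplied explicitly; the
pipeline uses the 20 seeding phases as replicate groups (each phase
contributes one settlement proportion per substrate).  Ridge-distance
summaries measure the horizontal distance from each settler to the nearest
ridge flank; the settlement-vs-Q recast classifies each settlement location
by whether any fluid node in a one-cell-wide column up to 1.5 mm above it
ever exceeds Q_thresh during a period (the column extent is a documented
package choice with no canonical definition).

## What the synthetic fields do and do not reproduce

The generator reproduces: the no-slip oscillatory boundary layer and its
phase lead; in-cavity recirculation with supra-threshold Q confined to the
cavities (flat fields have Q identically zero); the printed in-cavity speed
range and its phasing; near-substrate settling windows that are an order of
magnitude longer between ridges than over flat substrates.

It does not reproduce: vortex shedding and detachment from ridge trailing
edges, or any vertical velocity above the crest plane.  Consequently the rate
at which simulated larvae *encounter* the substrate is set by their swimming
orientation alone and is the same for every substrate, and the simulated
settlement totals come out nearly equal across substrates (~10.5% at the
defaults) instead of showing the ridged advantage that topography-induced
vertical entrainment produces in a full flow solve.  The absolute settlement
percentages nevertheless land within a few points of the reference values for
all three substrates.  Passing tests therefore validate the dynamics
(transport, rotation, settlement rule) and the flow analysis, not the claim
that this analytic field family discriminates substrates the way a resolved
flow does.

## Problem sizes and numerical choices

Analysis grids in the pipeline default to 0.1 mm spacing and 32 time slices
(refined automatically so a cavity spans >= 10 nodes); simulations in tests
use a 1,920-agent lattice (6 x 16 x 20 -- all 20 phases retained so the
replicate structure matches the full run), while the acceptance script runs
the full 19,200-agent lattice.  Tie-breaks and degenerate inputs: greedy PTV
linking resolves ties by ascending distance with stable ordering; an all-zero
frame yields no detections (not an error); empty track sets yield all-missing
fields; a constant velocity series has zero turbulence fraction; settling
windows with an always-below-threshold series return one full-period window.
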