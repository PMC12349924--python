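# Methods

## The model

`nanospin` simulates a fluid lipid bilayer perturbed by a rotating spiky
nanoparticle ("nanorobot") with a solvent-free coarse-grained model.
Each lipid is three beads — one hydrophilic head, two hydrophobic tail
beads — connected by finitely extensible (FENE) bonds and straightened
by a harmonic spring between the head and the second tail bead with a
4 sigma rest length (two bonds can never stretch that far, so the spring
is always taut and penalizes bending).  Water is not represented; the
hydrophobic effect is subsumed into a smooth attraction between tail
beads: a flat well of depth 1 eps for r < rc = 2^(1/6) sigma, tapered to
zero as cos^2 over a width wc = 1.7 sigma.  The taper width is the
model's cohesion dial; at wc = 1.7 sigma and kT = 1.1 eps the bilayer is
fluid and self-assembled.  Bead size is set by a repulsive
Weeks–Chandler–Andersen (WCA) core with length 0.95 sigma for any pair
involving a head and 1.0 sigma for tail–tail pairs.

All bonded partners also interact through their nonbonded pair
potential: the FENE bond plus the WCA core give the usual finite bond
length (the same superposition as a LAMMPS `fene` bond), and the
tail–tail cosine attraction is flat (zero force) at bond distances, so
no exclusion list is needed.

The repulsion strength deserves a note.  The printed source value for
the WCA prefactor (0.01 eps, untruncated at the cutoff) cannot hold a
bilayer together at kT = 1.1 eps; the solvent-free model this force
field descends from uses a full-strength, truncated-*and-shifted* core.
The default here is therefore `eps_rep = 1.0` with the energy shift
(`rep_shifted = True`); the literal variant remains selectable for
documentation (`eps_rep = 0.01, rep_shifted = False`) but is not used by
any shipped analysis.

Nanoparticles — free cargo beads (2 sigma, the model drug) and every
bead of the rigid robot — attract lipid beads through a truncated 12-6
potential with well depth 0.2 eps, length b_np = 2^(7/6) sigma and
cutoff 3 b_np (an adhesive-coating mimic; the printed length constant
lost its exponent in typesetting, and 2^(7/6) sigma is the natural
contact length for a 2 sigma particle against 1 sigma beads).  Both are
configurable.  Cargo–cargo pairs are purely repulsive at 2 sigma so the
cargo cannot aggregate; cargo–robot pairs are repulsive at 1.5 sigma.
A configurable fraction (default 0.1) of upper-leaflet heads are
"receptors" with a deeper attraction (default 2 eps) to robot spike
beads — a phenomenological ligand–receptor stand-in with no published
parameters, flagged as such; it makes adhered lipids co-rotate with the
spikes.

## Protocol

Langevin (BAOAB splitting) at dt = 0.005 tau, friction 1/tc with
tc = 0.5 tau, T = 1.1 eps/kB.  BAOAB is used because it samples
configurations accurately at this dt; with the thermostat off it reduces
exactly to velocity Verlet (the NVE tests rely on this).  Robot beads
are not integrated: their positions follow the prescribed angle
2 pi f t about the chosen axis (default: membrane normal) exactly, the
experimental magnetic drive being rate-controlled.  Forces exerted by
the membrane on the robot are computed and logged but do not alter its
motion.

Membrane tension is held at zero by an in-plane barostat with
tc = 5 tau: the lateral box and all non-robot x, y coordinates are
rescaled toward zero in-plane pressure.  The deterministic part is the
weak-coupling (Berendsen) relaxation with the compressibility prefactor
folded into tc; a stochastic-cell-rescaling fluctuation term is added by
default so the stationary area distribution has correct
constant-tension statistics — without it Var(A) is artificially damped
and any fluctuation-based K_A estimate would be biased high.  The
barostat is applied every step by default (a coarser cadence distorts
the area-fluctuation statistics through the Euler discretization of the
rescaling update), and a response limiter caps |d ln A| at 0.02 per
application so start-up pressure transients relax instead of
overshooting; a hard error triggers if a single rescale would leave
[0.9, 1.1].  The instantaneous tension is
-(P_xx + P_yy)/2 x L_z from the kinetic + virial pressure over the full
box volume.

Neighbor search: typed Verlet lists (WCA / tail-cosine / nanoparticle
12-6) from a linked-cell pass over membrane beads plus a direct sweep
for the few long-cutoff special beads, skin 0.5 sigma, rebuilt when any
bead has moved half the skin.  The tail-pair trigonometry uses degree
14/13 Taylor polynomials (max error ~1e-10 over the taper) — measurably
faster than libm and well inside the force-consistency tolerances.

Randomness: one PCG64 stream per run seeds thermostat noise, barostat
noise and builders; execution is single-threaded and iteration order
fixed, so runs are bit-reproducible given the seed (the manifest records
it).

## Initial systems

The builder places lipids on a square lattice (default 1.2 sigma^2 per
lipid; the barostat finds the tensionless area, so this guess only
affects equilibration), tails inward, leaflets offset by half a cell,
with Maxwell–Boltzmann velocities at the set temperature and zero net
momentum.  The robot is a spherical shell of beads (spacing <= 1 sigma)
with tapered-cone spikes: apex angles drawn from the measured 5–20
degree range, lengths configurable.  The simulated robot's size is not
stated by the source; the default (core 5 sigma, spikes 10–20 sigma) is
membrane-commensurate, and desk-scale runs use a smaller one (core
1.5 sigma, spikes 2.5–3.5 sigma) so the whole scene fits a 10x10-lipid
patch.  The robot is centered laterally with its lowest spike tip at a
configurable clearance above the mean upper head plane; because the
nanoparticle contact length is ~2.5 sigma, every assembled scene is
relaxed by displacement-capped steepest descent (cap 0.05 sigma) before
dynamics, which settles the membrane against the robot without
overstretching bonds.  Cargo is scattered on the robot side with
no two beads closer than one diameter.

## Observables

* **Density map / pore area.**  Lipid beads are binned on a 2-sigma
  lateral grid; cells below 0.25 of the mean density are pore cells,
  4-connected components are summed (total and largest reported).  An
  intact membrane projects ~5 beads/sigma^2 (~20 per cell), so Poisson
  noise sits far from the threshold.  Threshold and cell size are
  recorded in every output's metadata; the source states neither.
* **Penetrated count.**  Cargo beads whose unwrapped z is more than
  1 sigma (configurable) below the mean lower head plane; reported both
  instantaneous and as a running maximum.
* **MSD / diffusion.**  Sliding-time-origin MSD over selected beads and
  axes (z for transmembrane, x-y for lipid lateral); D from the
  least-squares slope over a window in the diffusive regime divided by
  2 x dimensionality.  The default lipid-D window is the 30–100% tail of
  the lag range, past the short-time caging regime.
* **Bending stiffness.**  The bilayer midplane is averaged onto a 16x16
  grid per frame (empty cells neighbour-interpolated and counted),
  Fourier transformed, and the inverse mode spectrum fitted to the
  tension + bending form kBT/(A S(q)) = sigma_eff q^2 + kappa q^4 over
  mode shells with 0 < q < 2 pi / 6 sigma^-1 — above that lies the
  protrusion regime.  The q^2 term matters: patches this small retain an
  effective fluctuation tension of order 1 eps/sigma^2 even when the
  barostat holds the frame tension at zero, and a pure q^-4 fit absorbs
  it into kappa (tens of percent high).  Grid binning is a box filter,
  so each mode is deconvolved by its sinc^2 pixel window before fitting;
  without the correction the edge modes of the window are attenuated by
  tens of percent.  Equal-|q| modes are shell-averaged; the weighted fit
  uses per-shell block errors, and up to two of the highest-q shells are
  trimmed when they fall more than 2.5 SE below the fit (the onset of
  the protrusion break, which otherwise drags kappa down).  Errors by
  block bootstrap; a log–log slope far from -4 flags a
  non-bending-dominated spectrum.  The estimator is validated against
  synthetic surfaces drawn from known (sigma, kappa) spectra, sampled at
  sub-cell resolution so the box filter and deconvolution are exercised
  end to end.
* **Stretching modulus.**  K_A = kBT <A> / Var(A) from the projected-area
  series of the tensionless run, with blocked standard errors.  This is
  the only route available from a tensionless trajectory, and it is why
  the barostat's stochastic term matters.  The projected area relaxes
  over ~50-100 tau (it exchanges with the undulation reservoir), so the
  sample variance of a finite window underestimates Var(A) by
  (1 - 2 tau_int/n); the estimator measures tau_int from the series
  autocorrelation and debiases accordingly (validated on synthetic
  Ornstein-Uhlenbeck series with known variance and correlation time).
  Calibration runs pool several independent replicas — far more
  effective against the slow-mode statistics than one long run — with
  per-replica windows referenced to the grand mean.  The whole
  barostat-plus-estimator chain is validated against an exact
  reference in the test suite: a dilute WCA gas held at fixed tension,
  whose K_A must equal its own two-dimensional pressure.

## Desk-scale study conditions

The published system (200 x 200 sigma, ~100k lipid beads, multi-turn
rotations) is cluster-sized.  The shipped analyses use reduced systems
chosen once:

* Calibration (elasticity, diffusion): three pooled replicas of a
  20x20-lipids-per-leaflet bilayer (2,400 beads), each with 125 tau of
  equilibration from an undulation-seeded start and 500 tau of
  production, frames every 2 tau (750 pooled).  Box height 400 sigma as
  published.  Independent replicas decorrelate the slowest height mode
  far faster than one long run; the undulation seeding (a thermal draw
  at literature-range guess moduli) removes the hundreds-of-tau
  mode-growth transient of a flat start, which otherwise biases kappa
  up and inflates Var(A).
* Robot comparison (four conditions x 3 replicas): 10x10 lipids per
  leaflet, a densely spiked desk robot (core 1.5 sigma, 12 spikes of
  2.5–3.5 sigma), 20 cargo beads, started in the post-attachment state
  (lowest tip 3.5 sigma below the upper head plane, the inserted
  configuration the experiment reaches after magnetic attachment) with
  50 tau of static settling, then 350 tau of production at the
  published frequencies f = 1/5,000 and 1/15,000 tau^-1.  The
  discriminating physics at this scale is defect healing: the insertion
  defect of a static robot seals in ~300 tau, the slowly rotating one
  somewhat later, while fast rotation re-carves it for ~700 tau —
  ordering the time-averaged pore areas by rotation frequency; longer
  productions (~600-1,000 tau) resolve the full four-way ordering more
  reliably than the shipped test-suite duration, which is sized to the
  suite's runtime.  A tip this small sweeps at most a few sigma per
  rotation period, at the edge of the lipid-refill Peclet number, which
  is why a resting (non-inserted) start shows no pores at any feasible
  desk duration — and why cargo translocation, which needs a
  robot-free opening wider than the cargo's ~2.5 sigma contact
  diameter, is not observed at this scale: the openings rotation
  maintains are tip-bound.  Transport enhancement is a large-membrane
  phenomenon; at desk scale the package demonstrates the pore-area
  half of the mechanism only.

What the reduced scale does and does not show: the elastic moduli are
intensive and transfer to the large system up to finite-size mode
truncation; the pore/transport orderings are rank properties of the
mechanism, not quantitative pore kinetics — absolute pore areas and
penetration counts at 200 sigma scale cannot be read off these runs.

## Numerical choices and edge cases

* FENE overstretch (r >= r_inf) raises an error naming the bond and
  step — the standard symptom of an oversized timestep or an unrelaxed
  contact; runs abort preserving the trajectory so far.
* dt is capped at the published 0.005 tau; the barostat requires
  tc >= 10 dt.
* Pore detection on a degenerate (empty) grid, MSD on empty selections,
  K_A on constant areas, and spectrum fits with too few frames all raise
  typed errors rather than returning numbers.
* Trajectory coordinates are stored at 6 decimals in sigma; digests are
  computed on the stored precision.  Unwrapped coordinates use per-bead
  image counters; lateral barostat rescaling applies to the current box,
  the usual convention (z, the transport axis, is never rescaled).

## Known limitations

* No hydrodynamics (solvent-free by construction): pore-refill and
  wrapping kinetics have Langevin, not Stokes, time scales.
* The robot is kinematically driven; membrane back-reaction ("step-out")
  is out of scope.
* The ligand–receptor term is phenomenological; its depth and coverage
  are package defaults, not measured quantities.
* At desk scale only a handful of long-wavelength modes exist below the
  protrusion cutoff; kappa carries a ~10% statistical error even with
  400 frames.
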