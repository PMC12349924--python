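# nanospin

Solvent-free coarse-grained molecular dynamics of a lipid bilayer
perturbed by a rotating spiky nanoparticle ("nanorobot"), with the
analysis pipeline for membrane elasticity, pore formation and
transmembrane cargo transport.

Magnetically driven particles with sharp nanospikes can be spun on a
cell membrane; the mechanical agitation increases membrane permeability
and with it the delivery of small cargo into the cell.  `nanospin` is a
self-contained simulator for the coarse-grained physics of that process:
it builds the bilayer, the rigid spiky particle and free cargo, runs
Langevin dynamics in a tensionless membrane ensemble, and measures the
quantities the mechanism is judged by — pore area, penetrated-cargo
counts, mean-square displacements, and the membrane's elastic constants.
It is a library first (plus a thin `nanospin` CLI); typical use is from
Python, as in `examples/`.

## Model

Each lipid is a three-bead chain (head + two tails, FENE bonds, a
harmonic head-to-second-tail spring of rest length 4 sigma that keeps
the chain straight).  Bead size comes from a WCA core (0.95 sigma for
head pairs, 1.0 sigma for tail pairs); the hydrophobic effect is a
smooth tail–tail attraction, flat at depth eps for r < 2^(1/6) sigma
and tapering as cos^2 over wc = 1.7 sigma.  At kT = 1.1 eps this gives
a self-assembled fluid bilayer.  Nanoparticles (cargo beads and every
bead of the rigid robot) adhere to lipids through a truncated 12-6
potential (depth 0.2 eps, length 2^(7/6) sigma, cutoff 3x).  The robot
is a bead shell with tapered spikes (apex angles 5–20 degrees) rotated
kinematically at a prescribed frequency about the membrane normal.

Dynamics: BAOAB Langevin at dt = 0.005 tau, thermostat time constant
0.5 tau, with an in-plane weak-coupling barostat (time constant 5 tau,
with a stochastic-cell-rescaling fluctuation term) holding the membrane
tension at zero.  Reduced units map to SI through the membrane itself:
sigma = 1 nm (5 sigma ~ 5 nm thickness), tau = 2 ns (lipid diffusion
1e-2 sigma^2/tau ~ 5 um^2/s), eps = 3.89e-21 J (1.1 eps/kB ~ 310 K).

The membrane calibration observables:

* bending stiffness from height fluctuations,
  `kB T / (A S(q)) = sigma_eff q^2 + kappa q^4`, fitted over the low-q
  mode shells (the q^2 term absorbs the effective fluctuation tension
  a small patch retains);
* stretching modulus from area fluctuations,
  `K_A = kB T <A> / Var(A)`;
* lipid lateral diffusion from the in-plane head-bead MSD slope.

## Worked example

```sh
python examples/membrane_elasticity.py
```

builds the 20x20-lipid-per-leaflet calibration bilayer (two pooled
replica runs), relaxes it to zero tension and prints (7-8 minutes on
one CPU; exact values vary with the seed):

```
bending stiffness kappa = 7.4 +- 2.8 eps  (spectrum slope -2.99; between -2 and -4, i.e. tension + bending)
stretching modulus K_A  = 33.1 +- 2.9 eps/sigma^2
lipid diffusion D       = 0.0067 sigma^2/tau
mean temperature        = 1.096 eps/kB
mean tension            = 0.011 eps/sigma^2
```

kappa is the Helfrich bending modulus in units of eps (7.4 eps ~ 6.7 kT
here — a soft fluid membrane), K_A the area-compressibility modulus
(33 eps/sigma^2 ~ 130 mN/m in SI), and D ~ 0.7e-2 sigma^2/tau the
lateral lipid mobility that anchors the time unit.  The fitted spectrum
slope sits between the pure-tension (-2) and pure-bending (-4) limits
because patches this small keep an effective fluctuation tension; the
two-parameter fit separates it from kappa (docs/methods.md).

`examples/spinning_robot.py` runs the mechanism itself: a densely
spiked particle inserted into a small membrane patch (the
post-attachment state), spun at f = 1/5,000 tau^-1, with the pore area
and the penetrated-cargo count printed over time — rotation keeps the
insertion defect open that a static particle lets heal;
`examples/condition_pipeline.py` runs the standard four-condition
comparison (no robot / static / slow / fast rotation) through the
`nanospin pipeline` machinery.

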