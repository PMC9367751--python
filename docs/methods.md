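# Methods

## Model

A filament is a chain of `L ∈ [2, 50]` identical rigid monomers. Every
monomer is a rigid body described by a centre position, a unit quaternion
(scalar-first, active rotations), a velocity, a body-frame angular velocity
and, if magnetic, a point dipole at its centre.

**Steric shape.** Spherical monomers are single Weeks–Chandler–Andersen
(WCA) beads: U(r) = U_LJ(r) + ε for r < 2^(1/6)σ_ij, zero beyond, with
U_LJ = 4ε[(σ/r)¹² − (σ/r)⁶]. Cubic monomers are raspberry bodies built on
the q = 2 superball |x|^2q+|y|^2q+|z|^2q = r^2q with half-extent
r = σ_central/2: eight corner sites along the ⟨111⟩ body diagonals and
twelve edge-midpoint sites along ⟨110⟩, all centred **on** the superball
surface. The printed site diameters (corners 0.41, edges 0.49) are taken as
given; the radial placement on the superball surface is this package's
reconstruction of the raspberry recipe, documented here so it can be
checked independently: a site along unit direction d̂ sits at distance
r / (Σ|d̂_k|^2q)^(1/2q) from the centre. Unlike site pairs mix by
Lorentz–Berthelot (σ_ij arithmetic, ε_ij geometric mean). WCA acts between
all steric sites of *different* monomers, including bonded neighbours — the
nearest-neighbour physics is exactly the interplay of that repulsion with
the bonds.

**Crosslinking.** Bonds are FENE springs with a shifted equilibrium length:
U = −(K_f r_f²/2) ln[1 − ((r−r0)/r_f)²], r0 = ασ, r_f = 3r0. CTC places
one centre–centre bond per junction (K_f = 90). FTF places eight bonds per
junction (K_f = 10): for spheres, two 8-site anchor crowns — the
intersection circles of the sphere with planes at body-z = ±σ/4, eight
equidistant anchor-only (non-steric) sites each — bonded index-to-index
with the facing crown, the unique pairing that gives eight parallel bonds
and a torsion-free straight chain; for cubes, the four corners plus four
edge midpoints of the facing faces, paired by matching transverse
coordinates. Anchor forces are propagated to the core as (f, d × f).

**Magnetism.** Reduced units absorb μ₀/4π; μ²_max = 3 sets the dipolar
coupling. Dipole–dipole energy U = [μ_i·μ_j − 3(μ_i·r̂)(μ_j·r̂)]/r³ with
direct O(L²) summation (a single chain in open boundary conditions — no
Ewald needed), Zeeman coupling U = −μ·H. FM moments are body-fixed along
the initial backbone direction and rotate with the quaternion; the
dipole-field torque and Zeeman torque act on the body. SPM moments are not
body-fixed: each step, before the force evaluation, every moment is set to
μ_max·L(μ_max|B_tot|/k_BT)·B̂_tot with B_tot = H + Σ_{j≠i} dipole fields
evaluated at the previous-step moments (one synchronous pass). A
fixed-point mode (tolerance 1e−10) exists for validation; at the fixed
point μ ∥ B_tot, so SPM bodies feel no magnetic torque, and none is
applied. SPM forces are those of fixed dipoles at the instantaneous values.

## Parameters (reduced units)

| quantity | value | notes |
|---|---|---|
| k_BT | 1 | sets the energy scale |
| monomer mass | 1 | equally distributed over sites for the inertia tensor |
| sphere σ, ε | 0.91, 100 | single steric site |
| cube σ, ε | 1.0, 1.0 | central site; corners 0.41, edges 0.49, same ε |
| K_f | 90 (CTC), 10 (FTF) | bond rigidity |
| r0, r_f | ασ, 3r0 | α ∈ {0.6, 0.8, 0.9, 1.0} |
| μ²_max | 3 | FM and SPM |
| H | 0…6 | uniform, along +z in field protocols |
| Γ_T = Γ_R | 1 | not printed in the source material; equilibrium averages are friction-independent, 1 gives fast decorrelation |
| dt | 5e−3 | see "Numerical choices" |

Inertia: site positions with the mass spread equally give the body-frame
tensor Σ m_s(|p|²𝟙 − ppᵀ); a bare sphere (all mass at the origin) gets the
solid-sphere tensor (1/10)mσ²𝟙 instead — any positive-definite choice
leaves equilibrium statics unchanged.

## Integration and thermostat

Velocity Verlet with one force evaluation per step. At each evaluation the
friction −Γ_T v (body-frame −Γ_R ω) and a white-noise term are added to the
conservative forces; quaternions advance by the exact exponential of the
body-frame angular velocity and are renormalized every step; Euler's
gyroscopic term ω × (Iω) is included (the FTF sphere template has an
anisotropic inertia tensor). Grafted monomers are frozen (full body frame);
the top-wall graft translates rigidly with the moving wall.

Two implementation choices deserve explicit statement:

* **Timestep.** With the sphere parameters above, the force balance between
  bond tension and the steep ε = 100 repulsion puts bonded neighbours on a
  contact of stiffness ≈ 8·10³, giving the collective longitudinal phonon
  ω·dt ≈ 1.8 at dt = 10⁻². That sits at the velocity-Verlet stability edge:
  straight chains heat resonantly and break their bonds within ~10²–10³
  steps at any friction between 1 and 10 (the integrator itself is sound —
  a bonded dimer in the microcanonical setting drifts < 1e−4 in energy over
  10⁴ steps). The package therefore integrates at **dt = 5e−3**, where long
  chains are stable over full protocol lengths and both kinetic
  temperatures sit within 1% of the thermostat. Protocol cadences are kept
  at their nominal step counts.
* **Noise distribution.** The thermostat draws *uniform bounded* noise with
  per-component variance exactly 2Γk_BT/dt (an inline splitmix64 stream,
  seeded per replica), not Gaussian draws. Only the first two moments of
  delta-correlated noise enter the sampled distribution at the order of the
  integrator; this is a classic Langevin-thermostat speed optimization. The
  equipartition and single-dipole Boltzmann tests validate the sampling.

**Initial state.** Chains start fully straight along a uniformly random
direction (isotropy is broken only by a field). The centre spacing is the
straight-chain *force balance* solved numerically per architecture: for
short bonds the FENE minimum would bury the ε = 100 cores in each other
(forces ~10⁹), so the physically stretched straight state keeps bonds under
tension against the contact repulsion. For cube FTF junctions, whose corner
and edge anchor planes sit at slightly different offsets, the residual
strain is split symmetrically between the two bond classes.

## Protocols

* **Equilibrium**: per replica, relax 2.1e6 steps, then record a snapshot
  every 7000 steps over 1.05e7 steps (1500 snapshots). Default 40 replicas.
* **Field sweep**: the same cycle per field value (default grid 0…6 in 0.5
  steps — the source material plots continuous curves without listing grid
  points, so the grid is a package choice), L = 20, default 15 replicas.
* **Compression**: an FTF filament of 20 monomers grafted fully stretched
  between two WCA planes (wall repulsion uses each steric site's own σ with
  ε = 1); the top wall steps down by 0.1 every 3e5 steps to a total of 5
  ("five length-scales" read as 5σ of wall travel, consistent with the 0.1
  increment); per plateau the first third is discarded and the mean z-force
  on the bottom-wall assembly (wall plane + grafted end) and the
  magnetization of the non-grafted monomers are recorded. Default 10
  replicas. Field, when on, points up (+z), against the compression.

A single `scale` factor multiplies relaxation, measurement and plateau
durations uniformly (cadence ratios preserved) and is recorded in every
output row; the physics constants (dt, T, σ, ε, K_f) live in a read-only
defaults layer that a run configuration cannot silently override.

**Problem sizes in the automated checks.** The test suite and the
acceptance script use scale 0.1 with 10 replicas for the quantitative
sphere-architecture checks (L ∈ {15, 20, 30, 40, 50}), and scale 0.02 with
2–4 replicas for the qualitative magnetic/compression orderings. At these
sizes the scaling exponents carry a sampling uncertainty of roughly ±0.03
and the persistence lengths ±10%; the acceptance tolerances quoted in the
tests reflect that. Cube-monomer chains are fully implemented and unit- and
property-tested (geometry, symmetry, junction topology, kernel-vs-reference
forces, rigid dynamics), but their 21-site raspberry makes full scaling
runs an order of magnitude more expensive than spheres, so their Table-type
checks are left to the example scripts rather than the automated suite.

## Estimators

d_avg is the mean nearest-neighbour centre distance of the same trajectory
set being analysed (computed separately per shape, crosslinking, L, α, H);
all starred observables are normalized by it. R*_e uses ⟨|r_L − r_1|⟩ (a
distance, so a rigid rod gives exactly L − 1 and the rod fit is a = 1,
b ≈ 1); the mean-squared variant is also computed and stored. Power-law
fits are unweighted linear least squares in log–log space over L ≥ 15.
C(n) = ⟨û_i·û_{i+n}⟩ averaged over junction index, snapshots and replicas;
L_p comes from a through-origin fit of ln C(n) = −n·d_avg/L_p restricted to
the initial decay (points with C > 0.2), reported in units of σ. A
non-decaying C(n) raises instead of returning a number. m̄ projects the
total moment on Ĥ and normalizes by L·μ_max; at H = 0 the direction-free
variant |Σμ|/(Lμ_max) is used. Compression curves get an exponential fit
A e^(−kx) + C and a zero crossing d_C by linear interpolation between the
bracketing plateaus.

## Synthetic-data generators

`magfil.synthetic` produces trajectories with known statistics for
estimator validation: rigid rods (R*_e = L−1, (R*_g)² = (L²−1)/12 exactly),
freely jointed chains (C(n≥1) = 0), and worm-like chains whose bond
directions follow the exact von Mises–Fisher transition kernel, so
C(n) = L(κ)ⁿ is exponential by construction and the persistence-length
estimator can be round-tripped against a known value. These generators
emulate conformational statistics only — no excluded volume, no dynamics,
no magnetism — so passing round-trips demonstrate estimator correctness,
not simulator correctness; the simulator is validated separately against
the force oracles, conservation laws and thermostat calibration tests.

## Numerical choices

Finite-extensibility violations (|r − r0| ≥ r_f) raise immediately with the
step index; protocol drivers catch the error, flag and drop that replica,
and continue — aggregated tables always carry the flag. The SPM update at
zero total field sets μ = 0 (no direction defined). The Langevin function
uses its Taylor series below |α| = 1e−4. Steric pair search uses a Verlet
neighbour list (skin 0.4) rebuilt when any monomer has moved more than half
a skin. Fits use scipy/numpy least squares throughout. All randomness —
initial backbone directions and thermostat streams — derives from integer
seeds; one stream per replica, recorded in the output tables.

## Known limitations

The face-to-face junction is built from the eight index-paired parallel
bonds described above — the minimal bond graph consistent with the crown
construction. Its bending stiffness is dominated by bond stretching
(lever ∝ crown radius), while the junction *shear* mode is only
second-order stiff when the bonds carry little tension; richer bond graphs
(e.g. additional diagonal cross-links between non-facing anchors) would
stiffen shear substantially, so measured FTF persistence lengths are
sensitive to this topology choice. The Langevin sampler has been verified
against an independent Metropolis Monte-Carlo oracle on the FTF trimer, so
the reported stiffness is a property of the bond graph, not of the
integrator.

No hydrodynamic coupling (implicit solvent only, θ-solvent assumed); no
periodic boundaries (single chains); dipolar sums are direct (adequate for
L ≤ 50, not for dense many-chain systems); SPM moments use the one-pass
local-field update rather than per-step self-consistency (the fixed-point
mode exists for validation; differences are far below sampling noise at the
protocol cadences); dynamic observables (MSD, relaxation spectra, rheology)
are out of scope. The reduced↔SI field conversion is convention-dependent;
`map_to_physical_units` states its Zeeman-energy-equivalence assumption
explicitly rather than asserting a unique mapping.
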