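# Methods

## Model

The lipid is dipalmitoylphosphatidylcholine (DPPC) in a united-atom
representation: hydrogens are folded into their heavy atoms, reducing the
molecule from 120 atoms to 50 interaction sites.  The shipped parameter file
`src/lipidmc/data/dppc.ff` is the single source of truth for the model:
atom records (united masses, electron counts, van der Waals radii, partial
charges, Lennard-Jones types), the 49 fixed bond lengths, harmonic
bond-angle terms, AMBER-style Fourier torsions, Ryckaert-Bellemans (RB)
cosine polynomials for the acyl-chain torsions (standard butane
coefficients), 1-4 scaling factors (0.8333 electrostatic, 0.5 LJ), and the
equilibrium internal coordinates used to construct start structures.  The
numerical values are this package's own parametrization in the AMBER
united-atom style; exchanging the file exchanges the model, and no constant
is hard-coded.

Atom numbering follows the molecule: N(1)-C(2)-C(3)-O(4)-P(5)-O(6)-C(7)-
C(8) for the choline/phosphate/glycerol backbone, the sn-2 ester and chain
on atoms 9-25, the sn-1 branch on atoms 26-43, and seven *external* atoms —
three N-methyls (44-46), two phosphate oxygens (47-48), two carbonyl
oxygens (49-50) — that are never moved directly in Cartesian space.

## Degrees of freedom and the move plan

Under the constant bond length approximation (CBLA) the 150 Cartesian
degrees of freedom are reduced to 88 sampled ones.  The text total (88) is
fixed; the per-atom role assignment shipped in `dppc.moves` is this
package's own, constructed to satisfy every structural constraint:

* 14 breakage atoms x 3 Cartesian DOF = 42.  Breakage atoms are interior
  chain atoms whose bonded neighbors each have exactly one further fixed
  anchor; atoms adjacent to the glycerol branch point C8 are excluded
  because a branch-point neighbor cannot be repositioned by a two-anchor
  closure.
* 26 crankshaft atoms x 1 DOF = 26 (the remaining interior atoms; the
  branch atom C8 drags the entire sn-1 subtree rigidly with its rotation).
* 10 terminal/external moieties x (1 torsion + 1 bond angle) = 20: the
  choline nitrogen with its riding methyls, the two chain-end methyls, and
  the seven external atoms.

Step sizes (breakage 0.10 Å, crankshaft/torsion 30°, bond angle 10°) were
set so each move class accepts at roughly 40-50 % on the equilibrated
monomer, a standard efficiency target for local Metropolis moves.

## Closure and reversibility

For a single-atom breakage fragment the closure solutions form the
intersection circle of two spheres.  A selection rule must pick one point,
and detailed balance demands that the rule be *involutive*: applying the
reverse displacement must recover the original positions exactly.  The
natural nearest-point ("proximity") rule is not involutive — the projection
from old circle to new circle and back misses the original position at
second order in the step, which is around 1e-2 Å at practical step sizes,
so a reversibility check at any sensible tolerance would veto essentially
every move.  The move set therefore uses an azimuth-transport rule: the
closure atom's azimuth about the anchor axis, measured from the common
plane of the old and new axes, is transported unchanged.  This rule

* restores both bond lengths exactly,
* is exactly involutive (the reverse-transport check in the proposal is a
  safety net and never fires in practice),
* reduces to the identity for vanishing displacement, and
* deviates from the nearest point only in proportion to the anchor
  displacement.

`solve_closure` (the nearest-point rule) is retained for geometry
utilities; the sampler uses `transport_closure`.

## Jacobians

Sampling mixed Cartesian/internal coordinates under constraints changes the
configuration-space volume element, dGamma = J prod dq prod dc, with J the
inverse determinant of the derivative matrix of the local coordinates with
respect to the fragment's Cartesian coordinates.  Reducing the bond-length
delta functions for one closure atom gives the circle measure
(l_a l_b / d) dpsi with d the anchor-anchor distance, hence the analytic
ratios used in acceptance:

* breakage: J(n)/J(m) = prod_k d_k(m)/d_k(n) over closure atoms,
* crankshaft and torsion rotations about a fixed axis: 1,
* driven bond angle theta: sin(theta_n)/sin(theta_m),
* rigid translations of riding atoms (leaf neighbors, external atoms): 1.

The analytic breakage factor was validated two independent ways: against a
central finite-difference evaluation of the defining determinant (agreement
to 1e-6 relative; `closure_jacobian_fd`), and against a full 6-D
finite-difference volume distortion of the composite move map during
development.  The decisive end-to-end check is the quadrature
detailed-balance test below.

## Acceptance rule and ensembles

Structural moves use Metropolis acceptance with dH = dE.  NPT volume moves
propose a uniform increment in ln V, rescale molecular centers of mass
affinely (molecules rigid), and accept with
dH = dE + P dV - n_molecules k_B T ln(V'/V).  With the uniform-in-ln V
proposal this samples p(V) ∝ V^(n-1) e^(-beta P V), whose mean is exactly
n k_B T / P — the property verified by the ideal-gas test.  The ln-volume
term counts molecules, not atoms, because only centers of mass are scaled.

Moves are applied sequentially in plan-file order with sequential energy
updating; sequential sweeps satisfy the balance condition for the
stationary distribution.  A monomer runs as NVT without a box; a bilayer as
NPT in a cubic cell periodic in x and y only (the bilayer normal is +z).

## Detailed-balance oracle

The core correctness test uses a 4-atom chain with fixed 1.53 Å bonds and a
single harmonic bond-angle potential E = k (theta - theta0)^2, k = 1.0
kcal/mol/rad^2, theta0 = 109.5°, at 323 K — a soft, realistic C-C-C-like
angle.  The exact marginal under the Cartesian Boltzmann measure is
p(theta) ∝ sin(theta) e^(-beta E), computable by 1-D quadrature.  Sampling
with breakage + crankshaft moves and the Jacobian reproduces this marginal
to a Kolmogorov-Smirnov distance below 0.01 at 1e6 attempted moves;
deliberately omitting the Jacobian (a supported switch used only for this
demonstration) biases the marginal to a KS distance above 0.05.  The sin
weight itself is what the Jacobian factors generate — a flat-measure
sampler cannot produce it.

## Energy evaluation

Nonbonded terms are 6-12 LJ (Lorentz-Berthelot combination) plus Coulomb
screened by the sigmoidal dielectric, truncated sharply at the cutoff (10 Å
for bilayers; no switching function), with 1-2/1-3 exclusions and scaled
1-4 pairs.  The dielectric argument is the *pair distance* by default — the
standard screened-Coulomb usage; a mode screening by the pair midpoint's
distance from the bilayer midplane is provided for comparison, as is a
constant-epsilon override.  The printed form of the screening function is
implemented with the argument s*r, the only reading that reproduces both
published checkpoints (74.69 and 15.72 at r = 10 Å).

Pairs between 10 and 20 Å are kept in a Verlet shell refreshed every 10
cycles (and after every accepted volume move), guaranteeing that local
energy deltas equal a full recompute: the delta of each move evaluates
exactly the pair and bonded terms involving moved atoms, and the shell
ensures no interacting pair is missed in either state.  Monomer runs
evaluate all intramolecular pairs without cutoff.  The energy bookkeeping
resynchronizes against a full recomputation at every pair-list refresh and
before every saved frame, so recorded scalars equal an independent
recomputation on the saved configuration.

A hard-core guard rejects any state putting two *interacting* atoms closer
than 0.1 Å; trial states violating it are certain rejections, while a
violation in the accepted state aborts the run with a diagnostic frame, as
does any bond-length drift beyond 1e-6 relative (none is ever observed;
closure restores lengths analytically, and drift stays below 1e-9 over 1e5
accepted moves).

## Start structures

Structures are built by forward kinematics from the parameter file's
equilibrium values: fixed bond lengths, equilibrium angles, and stated
build torsions (180° along the acyl chains, giving straight all-trans
tails; glycerol/ester torsions chosen once so the two tails run parallel
about 3.7 Å apart).  The bilayer builder places two opposed leaflets of
all-trans lipids on a lattice inside a cubic cell — 32 per leaflet on an
8x4 rectangular grid by default, cubic edge sqrt(32) x spacing, so the
default 10.1 Å spacing gives an initial area per lipid of 1.02 nm^2 — with
tails inward and each lipid rotated about its long axis by a seeded random
angle.  Because an 8x4 grid in a cubic cell spaces columns more tightly
than rows, the builder redraws a lipid's rotation angle (from the same
seeded stream) when a placement would put two lipids' atoms within 1.8 Å;
the construction remains bit-reproducible under the seed.  Reading a
structure back from PDB (1e-3 Å precision) is followed by a tree-walk
projection that restores every bond length exactly.

## Observables

* **Energy histogram**: Gaussian fit by nonlinear least squares; heat
  capacity from the fluctuation formula c = sigma^2/(k_B T^2).  (The
  alternative reading "multiply sigma^2 by beta" is dimensionally a free
  energy, not a heat capacity, and is not used.)
* **Schlitter entropy**: S = (k_B/2) ln det(1 + (k_B T e^2/hbar^2)
  M^(1/2) C M^(1/2)) with e Euler's number, C the Cartesian covariance over
  a frame window, M the diagonal mass matrix.  This is an upper bound that
  assumes Gaussian fluctuations.  No roto-translational superposition is
  applied by default (fluctuations are measured in the laboratory frame);
  a Kabsch-superposition mode exists behind a flag and yields smaller
  values because rigid-body diffusion is removed.  F = E - TS.
* **Electron density**: each atom contributes a z-Gaussian integrating to
  its electron count with width equal to its van der Waals radius;
  profiles are per-frame normalized (integral x lateral area = total
  electrons, exact to the grid's Gaussian tails, padded to 14 Å) and
  frame-averaged after centering on the electron-weighted mean.  D_HH is
  the distance between the smoothed maxima in symmetric head-group bands
  (default 10-30 Å from the midplane, configurable).
* **Torsion distributions**: named head-group torsions (alpha1-alpha6
  along the choline-phosphate backbone, beta1/beta4 down the sn-2 chain)
  as percentage occupancy in 5° bins, cumulative over the analyzed frames
  (a window option restricts the range), averaged over molecules.
* **P-N vector**: angle to +z per molecule per frame; an isotropic
  orientation gives the sin(theta)-weighted null distribution.
* **Area per lipid / K_A**: lateral box area over lipids per leaflet;
  K_A = k_B T <A>/Var(A) in mN/m, capped at 1e6 with a warning when the
  variance vanishes.
* **MSD**: all-lag-origin average of squared in-plane center-of-mass
  displacements, computed by the FFT identity (exactly the double loop,
  verified against it) on the *unwrapped* per-cycle COM series; the
  apparent D is the Einstein-relation slope/4 over a fit window.  MC
  cycles carry no physical time, so D only measures lateral scrambling
  efficiency.

## Problem sizes used in the shipped checks

The automated checks run at sizes chosen to make their statistics decisive:
1e6 attempted moves for the detailed-balance oracle (KS noise floor
~4e-3), 1e5 accepted monomer moves for constraint conservation, 1e5 volume
moves for the NPT closed form (mean-volume standard error ~0.5 %), 1e5
samples for the 1-D entropy closed form, 64 walkers x 1e4 steps for
diffusion recovery, and an 8-lipid bilayer for density normalization.
Equilibrium bilayer observables (D_HH, area per lipid, K_A, apparent D)
need 64-lipid runs of many days and are produced by the CLI workflow
rather than asserted by tests.

## What the toy generators do and do not show

The fixture systems (linear/branched chains with a single harmonic angle or
RB torsion, an ideal gas of point molecules) make reference distributions
computable by quadrature or closed form; passing their tests establishes
the correctness of the sampling machinery — measure, Jacobians,
reversibility, ensemble weights — not the realism of the force field.
Realism of the shipped DPPC parametrization is limited: the values are
plausible but authored here, the implicit solvent is a radial screening
function with no hydrogen-bonding or interfacial anisotropy, truncation at
10 Å neglects long-range electrostatics, and quantitative agreement with
experimental bilayer structure should not be expected from it.

## Known limitations

Single-atom breakage fragments only (no multi-atom rebridging or
configurational-bias regrowth); no Ewald or reaction-field electrostatics;
no Generalized-Born-class solvent; sequential sweeps are inherently serial;
pressure is imposed only through volume-move acceptance (no virial); the
88-DOF role assignment is one consistent realization of the stated totals,
not a unique one.
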