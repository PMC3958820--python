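# lipidmc

Atomistic Metropolis Monte Carlo simulation of united-atom phospholipids,
built around a **chain-breakage/closure (CBC) local move set** operating in
bond-/torsion-angle space under the **constant bond length approximation
(CBLA)**.  The package is for researchers who want rapid conformational
equilibration of single lipids and small bilayer patches — for example as a
pre-equilibration stage before molecular dynamics — together with the
observables used to judge that equilibration.

## What it does

Covalent bond lengths are treated as hard constraints, so sampling happens
on the constraint manifold with 88 degrees of freedom per DPPC molecule
instead of 150 Cartesian ones.  One MC cycle updates every degree of freedom
once, sequentially:

* **Breakage moves** — a single chain atom is displaced uniformly in a
  Cartesian cube; its bonded neighbors are repositioned analytically on the
  two-sphere intersection circle so that every bond length is restored
  exactly, using an involutive azimuth-transport selection that makes each
  move exactly reversible.
* **Crankshaft moves** — rotation of an atom about the axis through its two
  bonded neighbors.
* **Internal-coordinate moves** — torsion and bond-angle updates of terminal
  moieties (choline methyls, phosphate and carbonyl oxygens, chain ends).
* **Volume moves** (bilayer, NPT) — isotropic box rescaling with rigid
  molecules, one attempt per cycle at 1 atm.

Because the sampled coordinates are a mixture of Cartesian and internal
coordinates under constraints, the Boltzmann volume element changes with the
configuration.  The acceptance rule therefore carries the Jacobian ratio of
the coordinate transformation,

    p_acc(m -> n) = min{ 1, (p_sel(n->m)/p_sel(m->n)) e^(-beta dH) J(n)/J(m) },

with `J(n)/J(m) = prod_k d_k(m)/d_k(n)` over the closure atoms (d = distance
between a closure atom's two anchors) for breakage moves, 1 for crankshaft
and torsion rotations, and `sin(theta_n)/sin(theta_m)` for driven bond
angles.  Omitting these factors demonstrably skews the sampled bond-angle
distributions (see the detailed-balance test).

Solvent is implicit: electrostatics uses a sigmoidal distance-dependent
dielectric

    eps(r) = d - (d-1)/2 ((s r)^2 + 2 s r + 2) e^(-s r)

with plateau d = 78 (water) and slope s (1/Å); eps(10 Å) = 74.69 at s = 0.65
and 15.72 at s = 0.15.  Nonbonded interactions are 6-12 Lennard-Jones plus
screened Coulomb with a 10 Å cutoff, a 10 Å pair-list shell refreshed every
10 cycles, and minimum-image convention in the bilayer's two periodic
dimensions.

Observables: Gaussian fits of energy/enthalpy histograms and the fluctuation
heat capacity `c = sigma^2/(k_B T^2)`; Schlitter configurational entropy
`S = (k_B/2) ln det(1 + (k_B T e^2/hbar^2) M^(1/2) C M^(1/2))` from the
coordinate covariance; head-group torsion distributions; the transbilayer
electron density profile and head-head thickness D_HH; the P-N vector
orientation; area per lipid and the compressibility modulus
`K_A = k_B T <A>/Var(A)`; and in-plane mean-square displacement with an
apparent diffusion coefficient per MC cycle via MSD = 4 D s.

## Worked example

```bash
lipidmc build --system dppc-monomer --out demo/
cp src/lipidmc/data/monomer.yaml demo/run.yaml
lipidmc run --config demo/run.yaml --start demo/start.pdb --out demo/out
lipidmc analyze --traj demo/out --obs energy,entropy --out demo/tables
lipidmc validate --traj demo/out
```

The run command prints per-class acceptance counts:

```
finished 2000 cycles; acceptance {'crankshaft': '22221/52000',
'breakage': '12273/28000', 'torsion': '7807/20000', 'bond_angle': '9993/20000'}
```

i.e. roughly 40-50 % acceptance for every move class.  The analysis tables
from that run read:

```
mean_kcal_mol,sd_kcal_mol,heat_capacity_kcal_mol_K
43.11,5.35,0.138
entropy_kcal_mol_K,free_energy_kcal_mol,n_frames
0.1224,3.81,21
```

The mean is the equilibrium conformational energy of the single lipid under
the shipped parameter set, the standard deviation its thermal fluctuation
(the histogram passes a normality check, as expected at equilibrium), the
heat capacity follows from the fluctuation formula at 323 K, and the entropy
is the Schlitter upper bound from the 150x150 coordinate covariance of the
saved frames, giving F = E - TS.  `validate` confirms that every saved frame
satisfies the bond constraints to PDB precision.

A bilayer workflow is identical with `--system dppc-bilayer` and
`data/bilayer.yaml` (64 lipids, 2-D periodic cubic cell, NPT at 1 atm,
volume move each cycle); `lipidmc analyze --obs density,pn,area,msd` then
yields the electron-density profile with D_HH, head-group orientations, the
area-per-lipid series with K_A, and lateral center-of-mass MSD.  Absolute
equilibrium values for those observables require runs of many days; the
shipped configurations are sized for demonstration and testing.

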