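"""Programmatic generation of small test systems.

Fixture systems satisfy the same topology/configuration invariants as the
real model and use toy potentials whose reference distributions are
computable by quadrature or closed form: a single harmonic bond angle, a
single Ryckaert-Bellemans torsion, or no interactions at all (ideal gas).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..errors import LipidMCError
from ..model.builders import (
    build_bilayer_start,
    build_monomer_start,
    build_template_coords,
)
from ..model.moveplan import MovePlan, parse_move_plan
from ..model.parameters import (
    AngleTerm,
    Atom,
    BuildEntry,
    ForceField,
    RBTorsion,
    load_forcefield,
    shipped_parameter_path,
    topology_from_forcefield,
)
from ..model.moveplan import shipped_plan_path
from ..model.topology import Configuration, Topology

KINDS = (
    "linear_chain",
    "branched_chain",
    "ideal_gas",
    "dppc_monomer",
    "dppc_bilayer",
)

# study conditions of the 4-atom detailed-balance chain (fixed once):
# C-C-like bond length, soft harmonic angle at the tetrahedral value
CHAIN_BOND_LENGTH = 1.53        # Å
CHAIN_ANGLE_K = 1.0             # kcal/mol/rad^2
CHAIN_ANGLE_THETA0 = 109.5      # degrees
CHAIN_BREAKAGE_STEP = 0.35      # Å
CHAIN_CRANK_STEP = 60.0         # degrees


@dataclass
class FixtureSpec:
    kind: str
    n_atoms: int = 4                 # chain kinds
    n_molecules: int = 20            # ideal gas / bilayer leaflet count
    bond_length: float = CHAIN_BOND_LENGTH
    angle_k: float = CHAIN_ANGLE_K
    angle_theta0: float = CHAIN_ANGLE_THETA0
    potential: str = "harmonic_angle"    # or "rb_torsion", "none"
    box: float = 40.0                # Å, ideal gas
    lattice_spacing: float = 10.1    # Å, bilayer
    layout: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise LipidMCError(f"unknown fixture kind {self.kind!r}")


@dataclass
class Fixture:
    topology: Topology
    configuration: Configuration
    plan: MovePlan
    forcefield: ForceField
    plan_text: str = ""


_RB_BUTANE = (2.2180, 2.9065, -3.1356, -0.7313, 6.2714, -7.5278)


def _chain_forcefield(spec: FixtureSpec, bonds_extra=()) -> ForceField:
    n = spec.n_atoms
    atoms = [
        Atom(
            name=f"C{i + 1}", united_mass=14.027, electron_count=8,
            vdw_radius=1.9, charge=0.0, element="C", type_="X",
        )
        for i in range(n)
    ]
    bonds = [(i, i + 1, spec.bond_length) for i in range(n - 1)]
    bonds += list(bonds_extra)
    nbrs = [[] for _ in range(n)]
    for i, j, _ in bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    angles = []
    for j in range(n):
        nb = sorted(nbrs[j])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                k = (
                    spec.angle_k
                    if spec.potential == "harmonic_angle"
                    and (nb[x], j, nb[y]) == (0, 1, 2)
                    else 0.0
                )
                angles.append(
                    AngleTerm(nb[x], j, nb[y], k, np.deg2rad(spec.angle_theta0))
                )
    rbs = []
    if spec.potential == "rb_torsion" and n >= 4:
        rbs.append(RBTorsion(0, 1, 2, 3, _RB_BUTANE))
    build = []
    for i in range(n):
        # torsion 60 keeps the start away from the collinear degenerate
        # geometry where the closure circle has zero radius
        build.append(BuildEntry(i, i - 1, i - 2, i - 3, np.deg2rad(60.0)))
    return ForceField(
        molecule_name="CHAIN",
        atoms=atoms,
        bonds=bonds,
        angles=angles,
        torsions=[],
        rb_torsions=rbs,
        lj={"X": (1.0, 0.0)},
        external=set(),
        main_chain=list(range(n)),
        build=build,
    )


def _chain_plan_text(n: int) -> str:
    lines = []
    for a in range(2, n):             # interior atoms, 1-based serials
        lines.append(f"breakage {a} {CHAIN_BREAKAGE_STEP}")
        lines.append(f"crankshaft {a} {CHAIN_CRANK_STEP}")
    lines.append(f"torsion {n} {n - 1} {n - 2} {CHAIN_CRANK_STEP}")
    lines.append(f"bond_angle {n} {n - 1} {n - 2} 20")
    return "\n".join(lines) + "\n"


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Deterministic (seeded) toy system of the requested kind."""
    if spec.kind == "linear_chain":
        ff = _chain_forcefield(spec)
        top = topology_from_forcefield(ff, 1)
        conf = Configuration(build_template_coords(ff))
        text = _chain_plan_text(spec.n_atoms)
        plan = parse_move_plan(text, top)
        return Fixture(top, conf, plan, ff, text)

    if spec.kind == "branched_chain":
        # linear n-chain with one extra leaf on atom 2 (0-based index 1)
        spec2 = FixtureSpec(**{**spec.__dict__, "kind": "linear_chain"})
        spec2.n_atoms = spec.n_atoms
        ff = _chain_forcefield(spec2)
        n = spec.n_atoms
        leaf = Atom(
            name=f"C{n + 1}", united_mass=15.035, electron_count=9,
            vdw_radius=2.0, charge=0.0, element="C", type_="X",
        )
        ff.atoms.append(leaf)
        ff.bonds.append((1, n, spec.bond_length))
        ff.angles.append(AngleTerm(0, 1, n, 0.0, np.deg2rad(spec.angle_theta0)))
        ff.angles.append(AngleTerm(2, 1, n, 0.0, np.deg2rad(spec.angle_theta0)))
        ff.build.append(BuildEntry(n, 1, 0, 2, np.deg2rad(120.0)))
        top = topology_from_forcefield(ff, 1)
        conf = Configuration(build_template_coords(ff))
        # atom 2 carries the branch: its crankshaft drags the leaf; atoms
        # adjacent to the branch point cannot be breakage atoms
        lines = [f"breakage 2 {CHAIN_BREAKAGE_STEP}"]
        for a in range(2, spec.n_atoms):
            lines.append(f"crankshaft {a} {CHAIN_CRANK_STEP}")
        lines.append(
            f"torsion {spec.n_atoms} {spec.n_atoms - 1} {spec.n_atoms - 2} "
            f"{CHAIN_CRANK_STEP}"
        )
        text = "\n".join(lines) + "\n"
        plan = parse_move_plan(text, top)
        return Fixture(top, conf, plan, ff, text)

    if spec.kind == "ideal_gas":
        atom = Atom(
            name="AR", united_mass=39.95, electron_count=18,
            vdw_radius=1.9, charge=0.0, element="Ar", type_="X",
        )
        ff = ForceField(
            molecule_name="IGAS",
            atoms=[atom],
            bonds=[],
            angles=[],
            torsions=[],
            rb_torsions=[],
            lj={"X": (1.0, 0.0)},
            build=[BuildEntry(0, -1, -1, -1, 0.0)],
        )
        top = topology_from_forcefield(ff, spec.n_molecules)
        rng = np.random.default_rng(spec.seed)
        coords = rng.uniform(0.0, spec.box, (spec.n_molecules, 3))
        conf = Configuration(coords, box=spec.box, periodic_dims=(0, 1))
        plan = MovePlan([])
        return Fixture(top, conf, plan, ff, "")

    ff = load_forcefield()
    if spec.kind == "dppc_monomer":
        top = topology_from_forcefield(ff, 1)
        conf = build_monomer_start(top, ff)
        plan_text = shipped_plan_path().read_text()
        plan = parse_move_plan(plan_text, top)
        return Fixture(top, conf, plan, ff, plan_text)

    # dppc_bilayer
    n = spec.n_molecules
    top = topology_from_forcefield(ff, 2 * n)
    conf = build_bilayer_start(
        top, ff, n, spec.lattice_spacing, seed=spec.seed, layout=spec.layout
    )
    plan_text = shipped_plan_path().read_text()
    plan = parse_move_plan(plan_text, top, template_n_atoms=ff.n_atoms)
    return Fixture(top, conf, plan, ff, plan_text)


def write_fixture(fix: Fixture, out_dir: str | Path, name: str = "fixture"):
    """Write the fixture's structure, plan and (for DPPC) parameter files."""
    from .pdbio import write_pdb

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pdb(fix.configuration, fix.topology, out / f"{name}.pdb")
    (out / f"{name}.moves").write_text(fix.plan_text)
    if fix.forcefield.molecule_name == "DPPC":
        (out / f"{name}.ff").write_text(shipped_parameter_path().read_text())
    return out
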