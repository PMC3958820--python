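"""Plain-text force-field parameter files.

The parameter file is the source of truth for one molecule *template*: atom
records, the fixed bond lengths (constant bond length approximation), harmonic
bond-angle terms, Fourier and Ryckaert-Bellemans torsion terms, Lennard-Jones
parameters per atom type, 1-4 scaling factors, and the equilibrium internal
coordinates used to construct start structures.

Sections are introduced by ``[name]`` headers; ``#`` starts a comment; atom
serials are 1-based in the file and converted to 0-based indices on parsing.

Sections::

    [meta]        molecule NAME / external s1 s2 ... / main_chain s1 s2 ...
    [atoms]       serial name type mass electrons vdw_radius charge element
    [bonds]       i j length
    [angles]      i j k k_theta theta0_deg
    [torsions]    i j k l v_n gamma_deg n          (AMBER-style Fourier term)
    [rb_torsions] i j k l c0 c1 c2 c3 c4 c5        (Ryckaert-Bellemans)
    [lj]          type sigma epsilon
    [scaling]     coulomb14 X / lj14 X
    [build]       atom parent grandparent greatgrand torsion_deg  (0 if absent)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from ..errors import ParameterFileError, TopologyError
from .topology import Atom, Topology


@dataclass
class AngleTerm:
    i: int
    j: int
    k: int
    k_theta: float      # kcal/mol/rad^2;  E = k_theta (theta - theta0)^2
    theta0: float       # radians


@dataclass
class FourierTorsion:
    i: int
    j: int
    k: int
    l: int
    v_n: float          # kcal/mol;  E = v_n/2 (1 + cos(n phi - gamma))
    gamma: float        # radians
    n: int


@dataclass
class RBTorsion:
    i: int
    j: int
    k: int
    l: int
    c: tuple[float, ...]   # kcal/mol;  E = sum c_m cos^m(psi), psi = phi - pi


@dataclass
class BuildEntry:
    atom: int
    parent: int          # -1 when absent
    grandparent: int
    greatgrand: int
    torsion: float       # radians


@dataclass
class ForceField:
    """Parsed single-molecule template."""

    molecule_name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    angles: list[AngleTerm]
    torsions: list[FourierTorsion]
    rb_torsions: list[RBTorsion]
    lj: dict[str, tuple[float, float]]          # type -> (sigma Å, eps kcal/mol)
    scale14_coulomb: float = 1.0
    scale14_lj: float = 1.0
    external: set[int] = field(default_factory=set)
    main_chain: list[int] = field(default_factory=list)
    build: list[BuildEntry] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def angle_theta0(self, i: int, j: int, k: int) -> float:
        """Equilibrium value of the angle i-j-k, radians."""
        for t in self.angles:
            if t.j == j and {t.i, t.k} == {i, k}:
                return t.theta0
        raise ParameterFileError(
            f"no angle term for atoms {i + 1}-{j + 1}-{k + 1}"
        )

    def lj_params(self, type_: str) -> tuple[float, float]:
        try:
            return self.lj[type_]
        except KeyError:
            raise ParameterFileError(f"no LJ parameters for type {type_!r}") from None


def shipped_parameter_path(name: str = "dppc.ff") -> Path:
    """Path of a parameter file shipped with the package."""
    return Path(resources.files("lipidmc").joinpath("data").joinpath(name))


def _tokens(path: Path):
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield lineno, line


def load_forcefield(path: str | Path | None = None) -> ForceField:
    """Parse a parameter file (default: the shipped united-atom DPPC set)."""
    path = shipped_parameter_path() if path is None else Path(path)
    section = None
    meta: dict[str, list[str]] = {}
    atoms: list[Atom] = []
    bonds, angles, torsions, rbs, build = [], [], [], [], []
    lj: dict[str, tuple[float, float]] = {}
    scaling = {"coulomb14": 1.0, "lj14": 1.0}

    def fail(lineno, msg):
        raise ParameterFileError(f"{path.name}:{lineno}: {msg}")

    for lineno, line in _tokens(path):
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            continue
        parts = line.split()
        try:
            if section == "meta":
                meta[parts[0]] = parts[1:]
            elif section == "atoms":
                serial = int(parts[0])
                if serial != len(atoms) + 1:
                    fail(lineno, f"atom serial {serial} out of order")
                atoms.append(
                    Atom(
                        name=parts[1],
                        type_=parts[2],
                        united_mass=float(parts[3]),
                        electron_count=int(parts[4]),
                        vdw_radius=float(parts[5]),
                        charge=float(parts[6]),
                        element=parts[7],
                    )
                )
            elif section == "bonds":
                i, j = int(parts[0]) - 1, int(parts[1]) - 1
                bonds.append((min(i, j), max(i, j), float(parts[2])))
            elif section == "angles":
                angles.append(
                    AngleTerm(
                        int(parts[0]) - 1, int(parts[1]) - 1, int(parts[2]) - 1,
                        float(parts[3]), np.deg2rad(float(parts[4])),
                    )
                )
            elif section == "torsions":
                torsions.append(
                    FourierTorsion(
                        int(parts[0]) - 1, int(parts[1]) - 1,
                        int(parts[2]) - 1, int(parts[3]) - 1,
                        float(parts[4]), np.deg2rad(float(parts[5])), int(parts[6]),
                    )
                )
            elif section == "rb_torsions":
                rbs.append(
                    RBTorsion(
                        int(parts[0]) - 1, int(parts[1]) - 1,
                        int(parts[2]) - 1, int(parts[3]) - 1,
                        tuple(float(x) for x in parts[4:10]),
                    )
                )
            elif section == "lj":
                lj[parts[0]] = (float(parts[1]), float(parts[2]))
            elif section == "scaling":
                scaling[parts[0]] = float(parts[1])
            elif section == "build":
                build.append(
                    BuildEntry(
                        int(parts[0]) - 1, int(parts[1]) - 1,
                        int(parts[2]) - 1, int(parts[3]) - 1,
                        np.deg2rad(float(parts[4])),
                    )
                )
            elif section is None:
                fail(lineno, "content before first [section] header")
            else:
                fail(lineno, f"unknown section {section!r}")
        except ParameterFileError:
            raise
        except (ValueError, IndexError) as exc:
            fail(lineno, f"cannot parse {line!r} ({exc})")

    if not atoms:
        raise ParameterFileError(f"{path.name}: no [atoms] section")
    n = len(atoms)
    for i, j, _ in bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise ParameterFileError(
                f"{path.name}: bond ({i + 1}, {j + 1}) references missing atom"
            )
    external = {int(s) - 1 for s in meta.get("external", [])}
    main_chain = [int(s) - 1 for s in meta.get("main_chain", [])]
    return ForceField(
        molecule_name=meta.get("molecule", ["MOL"])[0],
        atoms=atoms,
        bonds=bonds,
        angles=angles,
        torsions=torsions,
        rb_torsions=rbs,
        lj=lj,
        scale14_coulomb=scaling["coulomb14"],
        scale14_lj=scaling["lj14"],
        external=external,
        main_chain=main_chain,
        build=build,
    )


def topology_from_forcefield(ff: ForceField, n_molecules: int = 1) -> Topology:
    """Replicate the template molecule into an ``n_molecules``-copy topology."""
    n = ff.n_atoms
    atoms: list[Atom] = []
    bonds: list[tuple[int, int, float]] = []
    molecules = []
    external: set[int] = set()
    for m in range(n_molecules):
        off = m * n
        atoms.extend(ff.atoms)
        bonds.extend((i + off, j + off, ell) for i, j, ell in ff.bonds)
        molecules.append(np.arange(off, off + n, dtype=np.intp))
        external.update(e + off for e in ff.external)
    return Topology(
        atoms=atoms,
        bonds=bonds,
        molecules=molecules,
        external_atoms=external,
        main_chain=list(ff.main_chain),
    )


def build_dppc_topology(parameter_file: str | Path | None = None) -> Topology:
    """The 50-atom united-atom DPPC topology from its parameter file."""
    ff = load_forcefield(parameter_file)
    top = topology_from_forcefield(ff, 1)
    if ff.molecule_name == "DPPC" and top.n_atoms != 50:
        raise TopologyError(
            f"DPPC parameter file defines {top.n_atoms} atoms, expected 50"
        )
    return top
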