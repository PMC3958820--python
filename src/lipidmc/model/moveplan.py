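"""Move plans: the assignment of every sampled degree of freedom to a move
class.

Four move classes exist:

``breakage``
    A single chain atom is displaced in Cartesian space (3 DOF).  Its bonded
    non-external neighbors are repositioned by the chain-closure rule so that
    all bond lengths are conserved; each closure neighbor needs exactly one
    further bonded anchor that stays fixed during the move.  Leaf neighbors
    and external atoms ride rigidly.
``crankshaft``
    Rotation of an atom about the axis through its two flanking bonded
    neighbors (1 DOF).  Any additional branches hanging off the atom ride
    rigidly with the rotation.
``torsion`` / ``bond_angle``
    Classical internal-coordinate moves of a *terminal* subtree (1 DOF each):
    the subtree hanging off atom ``a`` across the bond a-p is rotated about
    the bond axis p-g (torsion) or about the normal of the a-p-g plane
    through p (bond angle).

The plan file has one entry per line (1-based atom serials)::

    breakage a max_step_A
    crankshaft a max_deg
    torsion a p g max_deg
    bond_angle a p g max_deg

Plans for multi-molecule systems are replicated per molecule by the loader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from ..errors import PlanError
from .topology import Topology

MOVE_CLASSES = ("breakage", "crankshaft", "torsion", "bond_angle")


@dataclass
class PlanEntry:
    """One degree-of-freedom entry, resolved against a topology."""

    dof_id: int
    move_class: str
    atom: int
    max_step: float                 # Å for breakage, radians for the rest
    # breakage: list of (closure_atom, outer_anchor); leaf/external riders
    closures: list[tuple[int, int]] = field(default_factory=list)
    riders: list[int] = field(default_factory=list)
    # crankshaft: flanking axis atoms
    axis: tuple[int, int] | None = None
    # internal moves: parent / grandparent and the rotated subtree
    parent: int = -1
    grandparent: int = -1
    subtree: list[int] = field(default_factory=list)

    @property
    def n_dof(self) -> int:
        return 3 if self.move_class == "breakage" else 1

    @property
    def moved_atoms(self) -> list[int]:
        if self.move_class == "breakage":
            return [self.atom] + [c for c, _ in self.closures] + self.riders
        if self.move_class == "crankshaft":
            return [self.atom] + self.riders
        return list(self.subtree)


@dataclass
class MovePlan:
    entries: list[PlanEntry]

    @property
    def total_dof(self) -> int:
        return sum(e.n_dof for e in self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def shipped_plan_path(name: str = "dppc.moves") -> Path:
    return Path(resources.files("lipidmc").joinpath("data").joinpath(name))


def _resolve_breakage(atom: int, topology: Topology) -> tuple[list, list]:
    if atom in topology.external_atoms:
        raise PlanError(
            f"atom {atom + 1} is external and cannot be a breakage atom "
            "(external atoms move only by internal coordinates)"
        )
    closures: list[tuple[int, int]] = []
    riders: list[int] = []
    for nb in topology.neighbors(atom):
        if nb in topology.external_atoms:
            riders.append(nb)
            continue
        outer = [
            x for x in topology.neighbors(nb)
            if x != atom and x not in topology.external_atoms
        ]
        if len(outer) == 0:
            # leaf neighbor: rides rigidly with the breakage atom
            riders.append(nb)
            riders.extend(topology.external_dependents(nb))
        elif len(outer) == 1:
            closures.append((nb, outer[0]))
            riders.extend(topology.external_dependents(nb))
        else:
            raise PlanError(
                f"breakage atom {atom + 1}: neighbor {nb + 1} is a branch "
                "point and cannot be repositioned by two-anchor closure"
            )
    return closures, riders


def _resolve_crankshaft(atom: int, topology: Topology) -> tuple[tuple, list]:
    flank = [x for x in topology.neighbors(atom) if x not in topology.external_atoms]
    if len(flank) < 2:
        raise PlanError(
            f"crankshaft atom {atom + 1} needs two non-external bonded neighbors"
        )
    # branch points: the first two main-chain neighbors form the axis and any
    # further branches ride rigidly with the rotation
    axis = (flank[0], flank[1])
    riders = list(topology.external_dependents(atom))
    for extra in flank[2:]:
        riders.extend(topology.subtree(extra, atom))
    return axis, riders


def load_move_plan(
    plan_file: str | Path | None,
    topology: Topology,
    template_n_atoms: int | None = None,
) -> MovePlan:
    """Parse and validate a move-plan file against ``topology``.

    For multi-molecule systems the file describes one molecule (serials
    within ``template_n_atoms``) and is replicated across molecules.
    """
    path = shipped_plan_path() if plan_file is None else Path(plan_file)
    return parse_move_plan(
        path.read_text(), topology, template_n_atoms, source=path.name
    )


def parse_move_plan(
    text: str,
    topology: Topology,
    template_n_atoms: int | None = None,
    source: str = "<plan>",
) -> MovePlan:
    """Parse move-plan text (see module docstring) against ``topology``."""
    n_t = template_n_atoms or topology.n_atoms
    n_rep = topology.n_atoms // n_t
    if n_rep * n_t != topology.n_atoms:
        raise PlanError("topology size is not a multiple of the template size")

    raw: list[tuple[str, list[int], float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        cls = parts[0]
        if cls not in MOVE_CLASSES:
            raise PlanError(f"{source}:{lineno}: unknown move class {cls!r}")
        try:
            if cls in ("breakage", "crankshaft"):
                atoms = [int(parts[1]) - 1]
                step = float(parts[2])
            else:
                atoms = [int(p) - 1 for p in parts[1:4]]
                step = float(parts[4])
        except (ValueError, IndexError):
            raise PlanError(f"{source}:{lineno}: cannot parse {line!r}") from None
        for a in atoms:
            if not (0 <= a < n_t):
                raise PlanError(
                    f"{source}:{lineno}: atom {a + 1} outside template "
                    f"(1..{n_t})"
                )
        raw.append((cls, atoms, step))

    entries: list[PlanEntry] = []
    dof_id = 0
    for rep in range(n_rep):
        off = rep * n_t
        for cls, atoms, step in raw:
            a = atoms[0] + off
            if cls == "breakage":
                closures, riders = _resolve_breakage(a, topology)
                e = PlanEntry(dof_id, cls, a, step, closures=closures, riders=riders)
            elif cls == "crankshaft":
                axis, riders = _resolve_crankshaft(a, topology)
                e = PlanEntry(
                    dof_id, cls, a, np.deg2rad(step), axis=axis, riders=riders
                )
            else:
                p, g = atoms[1] + off, atoms[2] + off
                if p not in topology.neighbors(a):
                    raise PlanError(
                        f"{cls} entry: atoms {a + 1} and {p + 1} are not bonded"
                    )
                if g not in topology.neighbors(p):
                    raise PlanError(
                        f"{cls} entry: atoms {p + 1} and {g + 1} are not bonded"
                    )
                subtree = topology.subtree(a, p)
                e = PlanEntry(
                    dof_id, cls, a, np.deg2rad(step),
                    parent=p, grandparent=g, subtree=subtree,
                )
            entries.append(e)
            dof_id += e.n_dof
    return MovePlan(entries)
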