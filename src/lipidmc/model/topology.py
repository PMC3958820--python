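"""Molecular topology and configuration containers.

A :class:`Topology` holds the united-atom composition of a system: per-atom
properties, the fixed-length bond tree of each molecule (constant bond length
approximation: bond lengths are hard constraints, never potential terms), the
partition of atoms into molecules, and the set of *external* atoms (terminal
moieties such as N-methyls or carbonyl/phosphate oxygens that are never moved
directly in Cartesian space).

Atom indices are 0-based everywhere in memory; file formats are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import TopologyError


@dataclass(frozen=True)
class Atom:
    """One united interaction site."""

    name: str
    united_mass: float        # amu, hydrogens folded in
    electron_count: int
    vdw_radius: float         # Å
    charge: float             # e
    element: str
    type_: str = ""

    def __post_init__(self):
        if self.united_mass <= 0:
            raise TopologyError(f"atom {self.name}: united_mass must be > 0")
        if self.electron_count < 0:
            raise TopologyError(f"atom {self.name}: electron_count must be >= 0")
        if self.vdw_radius <= 0:
            raise TopologyError(f"atom {self.name}: vdw_radius must be > 0")


@dataclass
class Topology:
    """Atoms, fixed-length bond tree, molecule partition.

    Parameters
    ----------
    atoms : list of Atom
    bonds : list of (i, j, length) with i < j, length in Å
    molecules : list of arrays of atom indices (a partition)
    external_atoms : set of atom indices moved only through internal
        coordinates (and carried as rigid riders by their parent atom).
    main_chain : ordered atom indices of the branched main chain (optional,
        informational).
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    molecules: list[np.ndarray]
    external_atoms: set[int] = field(default_factory=set)
    main_chain: list[int] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.atoms)
        self._neighbors: list[list[int]] = [[] for _ in range(n)]
        self._length: dict[tuple[int, int], float] = {}
        for i, j, ell in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise TopologyError(f"bond ({i}, {j}) references invalid atoms")
            if ell <= 0:
                raise TopologyError(f"bond ({i}, {j}) has non-positive length")
            key = (min(i, j), max(i, j))
            if key in self._length:
                raise TopologyError(f"duplicate bond {key}")
            self._length[key] = ell
            self._neighbors[i].append(j)
            self._neighbors[j].append(i)
        self.molecule_of = np.empty(n, dtype=np.intp)
        self.molecule_of.fill(-1)
        for m, idx in enumerate(self.molecules):
            self.molecule_of[np.asarray(idx, dtype=np.intp)] = m
        if np.any(self.molecule_of < 0):
            raise TopologyError("molecule partition does not cover all atoms")
        self._check_trees()

    # -- basic queries -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def neighbors(self, i: int) -> list[int]:
        return self._neighbors[i]

    def degree(self, i: int) -> int:
        return len(self._neighbors[i])

    def bond_length(self, i: int, j: int) -> float:
        try:
            return self._length[(min(i, j), max(i, j))]
        except KeyError:
            raise TopologyError(f"atoms {i} and {j} are not bonded") from None

    def masses(self) -> np.ndarray:
        return np.array([a.united_mass for a in self.atoms])

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def electron_counts(self) -> np.ndarray:
        return np.array([a.electron_count for a in self.atoms], dtype=float)

    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def bond_index_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = np.array([b[0] for b in self.bonds], dtype=np.intp)
        j = np.array([b[1] for b in self.bonds], dtype=np.intp)
        ell = np.array([b[2] for b in self.bonds])
        return i, j, ell

    def subtree(self, root: int, cut_neighbor: int) -> list[int]:
        """Atoms on the ``root`` side when the bond root--cut_neighbor is cut."""
        if cut_neighbor not in self._neighbors[root]:
            raise TopologyError(f"atoms {root} and {cut_neighbor} are not bonded")
        seen = {cut_neighbor, root}
        stack = [root]
        out = [root]
        while stack:
            a = stack.pop()
            for b in self._neighbors[a]:
                if b not in seen:
                    seen.add(b)
                    out.append(b)
                    stack.append(b)
        return out

    def external_dependents(self, i: int) -> list[int]:
        """External atoms bonded to atom ``i`` (rigid riders of ``i``)."""
        return [j for j in self._neighbors[i] if j in self.external_atoms]

    # -- invariants ----------------------------------------------------

    def _check_trees(self):
        for m, idx in enumerate(self.molecules):
            idx = np.asarray(idx, dtype=np.intp)
            atoms = set(int(a) for a in idx)
            n_bonds = sum(
                1 for (i, j) in self._length if i in atoms and j in atoms
            )
            for (i, j) in self._length:
                if (i in atoms) != (j in atoms):
                    raise TopologyError(f"bond ({i}, {j}) crosses molecules")
            if len(atoms) == 1:
                continue
            if n_bonds != len(atoms) - 1:
                raise TopologyError(
                    f"molecule {m}: {n_bonds} bonds for {len(atoms)} atoms "
                    "(bond graph is not a tree)"
                )
            # connectivity
            start = int(idx[0])
            seen = {start}
            stack = [start]
            while stack:
                a = stack.pop()
                for b in self._neighbors[a]:
                    if b not in seen:
                        seen.add(b)
                        stack.append(b)
            if seen != atoms:
                raise TopologyError(f"molecule {m}: bond graph is disconnected")

    def max_bond_deviation(self, coords: np.ndarray) -> float:
        """Maximum relative deviation of any bond length from its fixed value."""
        i, j, ell = self.bond_index_arrays()
        if len(ell) == 0:
            return 0.0
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        return float(np.max(np.abs(d - ell) / ell))


@dataclass
class Configuration:
    """Cartesian coordinates plus (optional) periodic box.

    ``box`` is the cubic edge length in Å; ``periodic_dims`` names the wrapped
    axes — ``(0, 1)`` for a bilayer that is periodic in x and y only.
    Coordinates are stored *unwrapped*; minimum-image convention is applied in
    energy evaluation, wrapping only at I/O boundaries.
    """

    coords: np.ndarray
    box: float | None = None
    periodic_dims: tuple[int, ...] = ()

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TopologyError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise TopologyError("coordinates must be finite")
        if self.box is not None and self.box <= 0:
            raise TopologyError("box edge must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Configuration":
        return Configuration(self.coords.copy(), self.box, self.periodic_dims)

    def wrapped_coords(self) -> np.ndarray:
        """Coordinates wrapped into [0, box) along the periodic dims."""
        out = self.coords.copy()
        if self.box is not None:
            for d in self.periodic_dims:
                out[:, d] = np.mod(out[:, d], self.box)
        return out

    def volume(self) -> float:
        if self.box is None:
            raise TopologyError("configuration has no box")
        return self.box ** 3

    def area(self) -> float:
        if self.box is None:
            raise TopologyError("configuration has no box")
        return self.box ** 2


def molecule_centers_of_mass(
    coords: np.ndarray, topology: Topology
) -> np.ndarray:
    """Per-molecule center of mass, shape (n_molecules, 3)."""
    masses = topology.masses()
    out = np.empty((topology.n_molecules, 3))
    for m, idx in enumerate(topology.molecules):
        idx = np.asarray(idx, dtype=np.intp)
        w = masses[idx]
        out[m] = (coords[idx] * w[:, None]).sum(axis=0) / w.sum()
    return out
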