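"""Structure and trajectory I/O.

PDB is the interchange format: united atoms are written as single HETATM
records (one molecule per residue) with CONECT records for every bond, and
multi-model files hold trajectories.  An extended-XYZ writer is provided as
a plain-text alternative for frame stacks.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from ..errors import MappingError
from ..model.topology import Configuration, Topology


def _atom_array(conf_coords, topology: Topology, box: float | None):
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(conf_coords, dtype=np.float32)
    arr.atom_name = np.array([a.name for a in topology.atoms])
    arr.element = np.array([a.element for a in topology.atoms])
    arr.res_id = topology.molecule_of.astype(int) + 1
    arr.res_name = np.array(["LIP"] * n)
    arr.chain_id = np.array(["A"] * n)
    arr.hetero = np.ones(n, dtype=bool)     # hetero residues get CONECT records
    bonds = np.array([[i, j] for i, j, _ in topology.bonds], dtype=np.uint32)
    if len(bonds):
        arr.bonds = struc.BondList(n, bonds)
    if box is not None:
        arr.box = np.eye(3) * box
    return arr


def write_pdb(
    conf: Configuration, topology: Topology, path: str | Path, wrap: bool = False
):
    """Write one configuration; coordinates to PDB precision (1e-3 Å)."""
    coords = conf.wrapped_coords() if wrap else conf.coords
    arr = _atom_array(coords, topology, conf.box)
    f = PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def write_pdb_trajectory(
    frames, topology: Topology, path: str | Path, box=None
):
    """Write a frame stack as a multi-model PDB."""
    frames = np.asarray(frames, dtype=np.float32)
    stack = struc.AtomArrayStack(frames.shape[0], frames.shape[1])
    template = _atom_array(frames[0], topology, None)
    for cat in ("atom_name", "element", "res_id", "res_name", "chain_id", "hetero"):
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.bonds = template.bonds
    stack.coord = frames
    if box is not None:
        b = np.asarray(box, float)
        if b.ndim == 0:
            stack.box = np.broadcast_to(np.eye(3) * b, (len(frames), 3, 3)).copy()
        else:
            stack.box = np.array([np.eye(3) * e for e in b])
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_pdb(
    path: str | Path, topology: Topology | None = None
) -> tuple[Configuration, dict[str, int]]:
    """Read a configuration (first model) and the name -> index mapping.

    With a topology given, the atom count must match and the box/periodicity
    conventions of the topology's system are applied.
    """
    f = PDBFile.read(str(path))
    arr = f.get_structure(model=1)
    if topology is not None and arr.array_length() != topology.n_atoms:
        raise MappingError(
            f"{path}: {arr.array_length()} atoms vs topology's "
            f"{topology.n_atoms}"
        )
    box = None
    periodic = ()
    if arr.box is not None:
        edge = float(arr.box[0, 0])
        if edge > 1.0:
            box = edge
            periodic = (0, 1)
    conf = Configuration(arr.coord.astype(float), box, periodic)
    mapping = {name: k for k, name in enumerate(arr.atom_name)}
    return conf, mapping


def read_pdb_trajectory(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """All models of a multi-model PDB: (frames, per-frame box edges)."""
    f = PDBFile.read(str(path))
    stack = f.get_structure()
    boxes = None
    if stack.box is not None:
        boxes = np.array([b[0, 0] for b in stack.box])
    return stack.coord.astype(float), boxes


def write_extxyz(frames, topology: Topology, path: str | Path, box=None):
    """Extended-XYZ frame stack (plain-text alternative to PDB models)."""
    frames = np.asarray(frames, float)
    names = [a.element for a in topology.atoms]
    with open(path, "w") as fh:
        for k, fcoords in enumerate(frames):
            fh.write(f"{len(fcoords)}\n")
            comment = f'Properties=species:S:1:pos:R:3 frame={k}'
            if box is not None:
                e = float(np.asarray(box).ravel()[k] if np.ndim(box) else box)
                comment += (
                    f' Lattice="{e} 0 0 0 {e} 0 0 0 {e}"'
                )
            fh.write(comment + "\n")
            for name, (x, y, z) in zip(names, fcoords):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")
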