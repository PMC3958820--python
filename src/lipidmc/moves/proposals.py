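"""Trial-move generation for the local move set.

Every proposal carries its sparse trial coordinates, the Jacobian ratio
J(n)/J(m) of the coordinate-transformation volume elements, the proposal
selection ratio, and (for volume moves) the volume change.  The energy delta
is filled in by the caller, which owns the energy model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import GeometryError
from ..model.moveplan import PlanEntry
from ..model.topology import Configuration, Topology, molecule_centers_of_mass
from .closure import rotate_about_axis, transport_closure

REVERSE_TOL = 1e-9  # Å; reverse-proximity recovery tolerance


@dataclass
class MoveProposal:
    """A trial move: sparse new coordinates plus acceptance bookkeeping."""

    move_class: str
    trial_coords: dict[int, np.ndarray] = field(default_factory=dict)
    delta_E: float = 0.0
    jacobian_ratio: float = 1.0
    selection_ratio: float = 1.0
    delta_V: float = 0.0
    feasible: bool = True
    new_box: float | None = None
    log_volume_ratio: float = 0.0

    @classmethod
    def infeasible(cls, move_class: str) -> "MoveProposal":
        return cls(move_class=move_class, feasible=False, jacobian_ratio=0.0)


def propose_breakage_move(
    conf: Configuration,
    entry: PlanEntry,
    topology: Topology,
    rng: np.random.Generator,
    max_step: float | None = None,
) -> MoveProposal:
    """Cartesian displacement of a single breakage atom with chain closure.

    The displacement is uniform in a cube of half-width ``max_step``.  Each
    closure neighbor is repositioned by the reversible transport rule; leaf
    neighbors and external atoms ride rigidly.  The Jacobian ratio is the
    product over closure atoms of d(m)/d(n), where d is the distance between
    the closure atom's two anchors.  A reverse-transport check enforces
    microscopic reversibility.
    """
    step = entry.max_step if max_step is None else max_step
    b = entry.atom
    pts = conf.coords
    u = rng.uniform(-step, step, 3)
    new_b = pts[b] + u
    trial: dict[int, np.ndarray] = {b: new_b}
    for r in entry.riders:
        trial[r] = pts[r] + u
    jac = 1.0
    for cl_atom, anchor in entry.closures:
        len_cb = topology.bond_length(cl_atom, b)
        len_ca = topology.bond_length(cl_atom, anchor)
        new_cl = transport_closure(
            pts[b], new_b, pts[anchor], len_cb, len_ca, pts[cl_atom]
        )
        if new_cl is None:
            return MoveProposal.infeasible("breakage")
        back = transport_closure(
            new_b, pts[b], pts[anchor], len_cb, len_ca, new_cl
        )
        if back is None or np.linalg.norm(back - pts[cl_atom]) > REVERSE_TOL:
            return MoveProposal.infeasible("breakage")
        disp = new_cl - pts[cl_atom]
        trial[cl_atom] = new_cl
        for dep in topology.external_dependents(cl_atom):
            trial[dep] = pts[dep] + disp
        d_m = np.linalg.norm(pts[anchor] - pts[b])
        d_n = np.linalg.norm(pts[anchor] - new_b)
        if d_n < 1e-12:
            return MoveProposal.infeasible("breakage")
        jac *= d_m / d_n
    return MoveProposal("breakage", trial, jacobian_ratio=jac)


def propose_crankshaft(
    conf: Configuration,
    entry: PlanEntry,
    rng: np.random.Generator,
    max_angle: float | None = None,
) -> MoveProposal:
    """Rotation of an atom (plus riders) about its flanking-atom axis.

    The rotation preserves both adjacent bond lengths by construction and is
    volume-preserving: jacobian_ratio = 1, selection_ratio = 1.
    """
    step = entry.max_step if max_angle is None else max_angle
    pts = conf.coords
    p, q = entry.axis
    axis = pts[q] - pts[p]
    if np.linalg.norm(axis) < 1e-9:
        raise GeometryError(
            f"crankshaft atom {entry.atom}: flanking atoms {p} and {q} coincide"
        )
    ang = rng.uniform(-step, step)
    atoms = [entry.atom] + entry.riders
    rotated = rotate_about_axis(pts[np.array(atoms)], pts[p], axis, ang)
    trial = {a: rotated[k] for k, a in enumerate(atoms)}
    return MoveProposal("crankshaft", trial)


def propose_internal(
    conf: Configuration,
    entry: PlanEntry,
    rng: np.random.Generator,
    max_step: float | None = None,
) -> MoveProposal:
    """Classical internal-coordinate move of a terminal subtree.

    Torsions rotate the subtree about the parent-grandparent bond axis
    (volume-preserving).  Bond-angle moves drive the angle atom-parent-
    grandparent and carry the volume-element factor sin(theta_new) /
    sin(theta_old); proposals that would reach 0 or 180 degrees are
    infeasible because the volume element vanishes there.
    """
    step = entry.max_step if max_step is None else max_step
    pts = conf.coords
    a, p, g = entry.atom, entry.parent, entry.grandparent
    sub = np.array(entry.subtree, dtype=np.intp)
    delta = rng.uniform(-step, step)
    if entry.move_class == "torsion":
        axis = pts[p] - pts[g]
        if np.linalg.norm(axis) < 1e-9:
            raise GeometryError("torsion axis atoms coincide")
        rotated = rotate_about_axis(pts[sub], pts[p], axis, delta)
        trial = {int(s): rotated[k] for k, s in enumerate(sub)}
        return MoveProposal("torsion", trial)
    # bond angle
    u = pts[a] - pts[p]
    v = pts[g] - pts[p]
    n = np.cross(u, v)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        return MoveProposal.infeasible("bond_angle")
    theta_old = float(
        np.arccos(
            np.clip(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1
            )
        )
    )
    theta_new = theta_old + delta
    if not (1e-6 < theta_new < np.pi - 1e-6):
        return MoveProposal.infeasible("bond_angle")
    # rotation by -delta about n increases theta by +delta (see geometry of
    # u x v); verify numerically and flip if needed
    rotated = rotate_about_axis(pts[sub], pts[p], n / nn, -delta)
    # confirm direction using the moved atom itself
    idx_a = int(np.where(sub == a)[0][0])
    u_new = rotated[idx_a] - pts[p]
    check = float(
        np.arccos(
            np.clip(
                np.dot(u_new, v) / (np.linalg.norm(u_new) * np.linalg.norm(v)),
                -1,
                1,
            )
        )
    )
    if abs(check - theta_new) > 1e-9:
        rotated = rotate_about_axis(pts[sub], pts[p], n / nn, delta)
    trial = {int(s): rotated[k] for k, s in enumerate(sub)}
    jac = np.sin(theta_new) / np.sin(theta_old)
    return MoveProposal("bond_angle", trial, jacobian_ratio=jac)


def propose_molecule_rigid_move(
    conf: Configuration,
    topology: Topology,
    molecule: int,
    rng: np.random.Generator,
    max_translation: float = 0.5,
    max_rotation: float = np.deg2rad(10.0),
) -> MoveProposal:
    """Rigid-body translation + rotation of one whole molecule.

    Not part of the default move plan (the local move set suffices); offered
    for experiments on bilayer mixing.  Rigid motions preserve the internal
    measure exactly: jacobian_ratio = selection_ratio = 1.
    """
    idx = np.asarray(topology.molecules[molecule], dtype=np.intp)
    pts = conf.coords[idx]
    shift = rng.uniform(-max_translation, max_translation, 3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_rotation, max_rotation)
    center = pts.mean(axis=0)
    rotated = rotate_about_axis(pts, center, axis, angle) + shift
    trial = {int(a): rotated[k] for k, a in enumerate(idx)}
    return MoveProposal("rigid_molecule", trial)


def propose_volume_move(
    conf: Configuration,
    topology: Topology,
    max_dlnv: float,
    rng: np.random.Generator,
    min_box: float | None = None,
) -> MoveProposal:
    """Isotropic box rescaling with rigid molecules.

    ln V is perturbed uniformly in ±max_dlnv; molecular centers of mass are
    scaled affinely while intramolecular geometry stays rigid.  With this
    uniform-in-ln V proposal the acceptance weight
    exp(-beta (dE + P dV) + n_molecules ln(V'/V)) makes the sampled volume
    density proportional to V^(n-1) exp(-beta P V).
    """
    if conf.box is None:
        raise GeometryError("volume move requires a periodic box")
    dlnv = rng.uniform(-max_dlnv, max_dlnv)
    v_old = conf.volume()
    v_new = v_old * np.exp(dlnv)
    scale = (v_new / v_old) ** (1.0 / 3.0)
    new_box = conf.box * scale
    if min_box is not None and new_box < min_box:
        import warnings

        warnings.warn(
            f"volume move proposes box {new_box:.1f} Å below minimum "
            f"{min_box:.1f} Å; rejected"
        )
        return MoveProposal.infeasible("volume")
    coms = molecule_centers_of_mass(conf.coords, topology)
    shifts = coms * (scale - 1.0)
    new_coords = conf.coords.copy()
    for m, idx in enumerate(topology.molecules):
        new_coords[np.asarray(idx, dtype=np.intp)] += shifts[m]
    prop = MoveProposal(
        "volume",
        trial_coords={},       # full-array move; see .full_coords
        delta_V=v_new - v_old,
        new_box=new_box,
        log_volume_ratio=dlnv,
    )
    prop.full_coords = new_coords
    return prop
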