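"""Start-structure construction from equilibrium internal coordinates.

Structures are built by forward kinematics (the NeRF chain-extension rule)
from the parameter file's ``[build]`` section: every atom is placed at its
fixed bond length, the equilibrium bond angle from the ``[angles]`` section,
and a stated build torsion.  Under the constant bond length approximation the
resulting configuration satisfies every bond constraint *exactly* by
construction; acyl-chain build torsions of 180° give straight (all-trans)
fatty acid tails.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError, ParameterFileError
from .parameters import ForceField, topology_from_forcefield
from .topology import Configuration, Topology


def place_atom(
    c: np.ndarray, b: np.ndarray, a: np.ndarray,
    length: float, theta: float, phi: float,
) -> np.ndarray:
    """Position of atom d with |d-a| = length, angle(d,a,b) = theta and
    dihedral(d,a,b,c) = phi (NeRF construction)."""
    ab = a - b
    nab = np.linalg.norm(ab)
    if nab < 1e-12:
        raise ConfigurationError("coincident parent/grandparent in build")
    e1 = ab / nab
    cb = b - c
    n = np.cross(cb, ab)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # collinear reference frame; any perpendicular works (phi degenerate)
        t = np.array([1.0, 0.0, 0.0]) if abs(e1[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        n = np.cross(e1, t)
        nn = np.linalg.norm(n)
    e3 = n / nn
    e2 = np.cross(e3, e1)
    d_local = np.array(
        [
            -np.cos(theta),
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
        ]
    )
    return a + length * (d_local[0] * e1 + d_local[1] * e2 + d_local[2] * e3)


def build_template_coords(ff: ForceField) -> np.ndarray:
    """One molecule's coordinates from its ``[build]`` recipe."""
    if len(ff.build) != ff.n_atoms:
        raise ConfigurationError(
            f"[build] lists {len(ff.build)} entries for {ff.n_atoms} atoms"
        )
    lengths = {(min(i, j), max(i, j)): ell for i, j, ell in ff.bonds}
    coords = np.full((ff.n_atoms, 3), np.nan)
    placed = set()
    for entry in ff.build:
        a, p, g, gg = entry.atom, entry.parent, entry.grandparent, entry.greatgrand
        if p < 0:
            coords[a] = 0.0
        elif g < 0:
            coords[a] = coords[p] + [lengths[(min(a, p), max(a, p))], 0.0, 0.0]
        else:
            if p not in placed or g not in placed:
                raise ConfigurationError(
                    f"build entry for atom {a + 1} references unplaced atoms"
                )
            try:
                ell = lengths[(min(a, p), max(a, p))]
            except KeyError:
                raise ConfigurationError(
                    f"no bond length for build pair {a + 1}-{p + 1}"
                ) from None
            try:
                theta = ff.angle_theta0(a, p, g)
            except ParameterFileError as exc:
                raise ConfigurationError(
                    f"missing equilibrium angle for atom {a + 1}: {exc}"
                ) from exc
            if gg >= 0 and gg not in placed:
                raise ConfigurationError(
                    f"build entry for atom {a + 1} references unplaced atoms"
                )
            cref = coords[gg] if gg >= 0 else coords[g] + np.array([0.0, 1.0, 0.0])
            coords[a] = place_atom(cref, coords[g], coords[p], ell, theta, entry.torsion)
        placed.add(a)
    if np.any(np.isnan(coords)):
        raise ConfigurationError("build recipe left atoms unplaced")
    return coords


def _oriented_template(ff: ForceField) -> np.ndarray:
    """Template coordinates rotated so the head->tail axis points along -z
    and centered on the molecular center of geometry in x, y."""
    coords = build_template_coords(ff)
    center = coords.mean(axis=0)
    rel = coords - center
    # long axis = largest principal axis of the (unweighted) gyration tensor
    _, vecs = np.linalg.eigh(rel.T @ rel)
    axis = vecs[:, -1]
    target = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, target)
    s = np.linalg.norm(v)
    c = float(np.dot(axis, target))
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    out = rel @ rot.T
    if ff.main_chain:
        head, tail = ff.main_chain[0], ff.main_chain[-1]
        if out[head, 2] < out[tail, 2]:      # head points up (+z)
            out = out * np.array([1.0, -1.0, -1.0])
    out[:, :2] -= out[:, :2].mean(axis=0)
    return out


def build_monomer_start(topology: Topology, ff: ForceField) -> Configuration:
    """All-trans single-molecule start structure (no box)."""
    if topology.n_molecules != 1 or topology.n_atoms != ff.n_atoms:
        raise ConfigurationError("monomer build requires a single-molecule topology")
    conf = Configuration(build_template_coords(ff))
    dev = topology.max_bond_deviation(conf.coords)
    if dev > 1e-9:
        raise ConfigurationError(f"built structure violates bond lengths ({dev:.2e})")
    return conf


def build_bilayer_start(
    topology: Topology,
    ff: ForceField,
    n_per_leaflet: int,
    lattice_spacing: float,
    seed: int,
    layout: tuple[int, int] | None = None,
    gap: float = 2.0,
) -> Configuration:
    """Crystalline bilayer: two opposed leaflets of all-trans lipids on a
    lattice, tails inward, each lipid rotated by a random angle about its
    long (z) axis.

    ``n_per_leaflet`` must be a perfect square unless an explicit rectangular
    ``layout`` (nx, ny) with nx * ny == n_per_leaflet is given.  The cubic box
    edge is sqrt(n_per_leaflet) * lattice_spacing, i.e. the initial area per
    lipid is lattice_spacing**2.  ``gap`` is the tail-tail spacing across the
    midplane in Å.
    """
    if topology.n_molecules != 2 * n_per_leaflet:
        raise ConfigurationError(
            f"topology holds {topology.n_molecules} molecules; "
            f"bilayer needs {2 * n_per_leaflet}"
        )
    if layout is None:
        nx = int(round(np.sqrt(n_per_leaflet)))
        if nx * nx != n_per_leaflet:
            raise ConfigurationError(
                f"n_per_leaflet={n_per_leaflet} is not a perfect square; "
                "pass an explicit rectangular layout=(nx, ny)"
            )
        layout = (nx, nx)
    nx, ny = layout
    if nx * ny != n_per_leaflet:
        raise ConfigurationError(f"layout {layout} does not give {n_per_leaflet} sites")
    box = float(np.sqrt(n_per_leaflet) * lattice_spacing)

    template = _oriented_template(ff)
    z_top = template[:, 2].max()      # head end (z=0 at head atom before shift)
    z_bot = template[:, 2].min()
    # shift template so the lowest atom (tail tip) sits at +gap/2
    upper = template.copy()
    upper[:, 2] += gap / 2.0 - z_bot
    rng = np.random.default_rng(seed)

    n_t = ff.n_atoms
    coords = np.empty((topology.n_atoms, 3))
    placed: list[np.ndarray] = []
    mol = 0
    for leaflet in (0, 1):
        for iy in range(ny):
            for ix in range(nx):
                offset = np.array(
                    [(ix + 0.5) * box / nx, (iy + 0.5) * box / ny, 0.0]
                )
                pos = _place_lipid(
                    upper, leaflet, offset, box, rng, placed
                )
                placed.append(pos)
                coords[mol * n_t:(mol + 1) * n_t] = pos
                mol += 1
    conf = Configuration(coords, box=box, periodic_dims=(0, 1))
    _check_overlaps(conf, topology)
    return conf


_CLASH_LIMIT = 1.8  # Å, between atoms of different lipids at build time


def _place_lipid(template, leaflet, offset, box, rng, placed, tries=60):
    """Rotate one lipid by a random angle about its long (z) axis, resampling
    the seeded stream until the placement has no hard clash with lipids
    already on the lattice (minimum-image in x, y)."""
    from scipy.spatial import cKDTree

    others = np.concatenate(placed) if placed else None
    tree = cKDTree(
        np.mod(others[:, :2], box), boxsize=(box, box)
    ) if others is not None else None
    best_pos, best_d = None, -np.inf
    for _ in range(tries):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        ca, sa = np.cos(ang), np.sin(ang)
        rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
        pos = template @ rot.T
        if leaflet == 1:
            pos = pos * np.array([1.0, -1.0, -1.0])   # proper rotation: z-flip
        pos = pos + offset
        if tree is None:
            return pos
        # candidate clash pairs by xy proximity, then full 3-D distance
        d = _min_dist(pos, others, tree, box)
        if d >= _CLASH_LIMIT:
            return pos
        if d > best_d:
            best_pos, best_d = pos, d
    return best_pos


def _min_dist(pos, others, tree, box):
    nbr = tree.query_ball_point(np.mod(pos[:, :2], box), r=3.0)
    dmin = np.inf
    for a, idxs in enumerate(nbr):
        if not idxs:
            continue
        dv = others[idxs] - pos[a]
        dv[:, :2] -= box * np.round(dv[:, :2] / box)
        dmin = min(dmin, float(np.min(np.linalg.norm(dv, axis=1))))
    return dmin


def restore_bond_constraints(
    conf: Configuration, topology: Topology
) -> Configuration:
    """Project a configuration back onto the fixed-bond-length manifold.

    Needed after lossy round trips (PDB stores 1e-3 Å).  Walks each
    molecule's bond tree from its first atom and rescales every bond vector
    to its exact constrained length, keeping all bond directions; the
    perturbation is of the order of the coordinate noise.
    """
    out = conf.copy()
    coords = out.coords
    for idx in topology.molecules:
        root = int(np.asarray(idx)[0])
        seen = {root}
        stack = [root]
        while stack:
            a = stack.pop()
            for b in topology.neighbors(a):
                if b in seen:
                    continue
                seen.add(b)
                v = coords[b] - coords[a]
                nv = np.linalg.norm(v)
                if nv < 1e-9:
                    raise ConfigurationError(
                        f"coincident bonded atoms {a} and {b}"
                    )
                coords[b] = coords[a] + v * (
                    topology.bond_length(a, b) / nv
                )
                stack.append(b)
    return out


def _check_overlaps(conf: Configuration, topology: Topology, limit: float = 0.5):
    from scipy.spatial import cKDTree

    pts = conf.wrapped_coords()
    tree = cKDTree(pts)
    pairs = tree.query_pairs(limit)
    bonded = {(min(i, j), max(i, j)) for i, j, _ in topology.bonds}
    bad = sorted(p for p in pairs if p not in bonded)
    if bad:
        raise ConfigurationError(
            f"atoms closer than {limit} Å in built structure: {bad[:10]}"
        )
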