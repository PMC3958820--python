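"""Jacobian factors of the local coordinate transformations.

Sampling in mixed Cartesian/internal coordinates under hard bond-length
constraints changes the volume element of the configuration integral:
dGamma = J prod dq_i prod dc_j, with J the inverse determinant of the matrix
of partial derivatives of the sampled-plus-constrained local coordinates with
respect to the Cartesian coordinates of the moved fragment.  The Metropolis
acceptance therefore carries the ratio J(n)/J(m).

For the move classes used here the determinants are analytic:

* breakage fragment: per closure atom the local coordinates are its two
  constrained bond lengths plus the free azimuth about the anchor axis, for
  which |det d(psi, u, v)/dx| = d / (l_a l_b) with d the anchor-anchor
  distance; hence J(n)/J(m) = prod d(m)/d(n).
* crankshaft and torsion rotations about a fixed axis: volume preserving,
  ratio 1.
* driven bond angle: spherical volume element, ratio sin(theta_n)/sin(theta_m).

:func:`closure_jacobian_fd` provides the central finite-difference evaluation
of the same determinant for validation.
"""

from __future__ import annotations

import numpy as np

from ..errors import GeometryError
from .proposals import MoveProposal


def jacobian_ratio(proposal: MoveProposal) -> float:
    """J(n)/J(m) for a feasible proposal (stored by the proposal builder)."""
    if not proposal.feasible:
        raise GeometryError("jacobian ratio undefined for infeasible proposal")
    return proposal.jacobian_ratio


def closure_local_coords(x, anchor_a, anchor_b, ref):
    """Local coordinates (psi, u, v) of a closure atom at ``x``: azimuth about
    the anchor axis measured from the fixed direction ``ref``, and the two
    anchor distances."""
    e = anchor_b - anchor_a
    e = e / np.linalg.norm(e)
    u1 = ref - np.dot(ref, e) * e
    u1 = u1 / np.linalg.norm(u1)
    v1 = np.cross(e, u1)
    w = x - anchor_a
    w_perp = w - np.dot(w, e) * e
    psi = np.arctan2(np.dot(w_perp, v1), np.dot(w_perp, u1))
    return np.array(
        [psi, np.linalg.norm(x - anchor_a), np.linalg.norm(x - anchor_b)]
    )


def closure_jacobian_fd(x, anchor_a, anchor_b, h: float = 1e-6) -> float:
    """|det d(psi, u, v)/dx| by central finite differences (= d/(u v))."""
    x = np.asarray(x, float)
    anchor_a = np.asarray(anchor_a, float)
    anchor_b = np.asarray(anchor_b, float)
    # any reference not parallel to the axis
    e = anchor_b - anchor_a
    e = e / np.linalg.norm(e)
    ref = (
        np.array([1.0, 0.0, 0.0])
        if abs(e[0]) < 0.9
        else np.array([0.0, 1.0, 0.0])
    )
    m = np.zeros((3, 3))
    for k in range(3):
        xp = x.copy()
        xm = x.copy()
        xp[k] += h
        xm[k] -= h
        fp = closure_local_coords(xp, anchor_a, anchor_b, ref)
        fm = closure_local_coords(xm, anchor_a, anchor_b, ref)
        df = fp - fm
        df[0] = (df[0] + np.pi) % (2 * np.pi) - np.pi
        m[:, k] = df / (2 * h)
    det = abs(np.linalg.det(m))
    if det < 1e-14:
        raise GeometryError("singular closure transformation")
    return det


def breakage_jacobian_fd(conf, entry, topology, trial_coords) -> float:
    """Finite-difference J(n)/J(m) for a breakage proposal.

    J = prod (l_a l_b / d) per closure atom, so the ratio equals
    prod det_m / det_n of the finite-difference determinants.
    """
    pts = conf.coords
    b = entry.atom
    ratio = 1.0
    for cl_atom, anchor in entry.closures:
        det_m = closure_jacobian_fd(pts[cl_atom], pts[b], pts[anchor])
        det_n = closure_jacobian_fd(
            trial_coords[cl_atom], trial_coords[b], pts[anchor]
        )
        ratio *= det_m / det_n
    return ratio
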