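"""Chain-closure geometry under the constant bond length approximation.

When a breakage atom moves, each bonded closure neighbor must be repositioned
so that its two bond lengths — to the moved atom and to its outer fixed
anchor — are restored.  The solution set is the intersection circle of two
spheres.  Two selection rules are provided:

:func:`solve_closure`
    Nearest point on the solution circle to the previous position (the
    proximity rule).  This is the natural "smallest displacement" choice but
    the map between the old and new solution circles it induces is *not*
    involutive: re-applying it with the displacement reversed misses the
    original position at second order in the step.

:func:`transport_closure`
    The reversible selection used by the breakage move: the closure atom
    keeps its azimuth about the anchor axis, measured from the common plane
    of the old and new axes.  Applying the rule with old and new anchors
    swapped recovers the original position exactly (involutive), which is
    what the reverse-proximity criterion of the acceptance rule demands.
    Its displacement of the closure atom vanishes with the anchor
    displacement, and it deviates from the nearest-point rule only
    proportionally to the anchor displacement.
"""

from __future__ import annotations

import numpy as np

from ..errors import GeometryError

_EPS = 1e-12


def _circle(anchor_a, anchor_b, len_a, len_b):
    """Center, axis unit vector and radius of the two-sphere intersection
    circle, or None when the spheres do not intersect in a circle."""
    d = anchor_b - anchor_a
    dn = float(np.sqrt(d @ d))
    if dn < _EPS:
        return None
    if dn > len_a + len_b or dn < abs(len_a - len_b):
        return None
    e = d / dn
    a = (dn * dn + len_a * len_a - len_b * len_b) / (2.0 * dn)
    r2 = len_a * len_a - a * a
    if r2 <= _EPS:
        return None
    return anchor_a + a * e, e, np.sqrt(r2)


def _cross3(a, b):
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def solve_closure(anchor_a, anchor_b, len_a, len_b, old_pos):
    """Nearest point on the closure circle to ``old_pos``.

    Returns None (infeasible) when the spheres do not intersect, when the
    anchors coincide, or when ``old_pos`` lies on the circle's axis so the
    nearest point is not unique.
    """
    if len_a <= 0 or len_b <= 0:
        raise GeometryError("bond lengths must be positive")
    anchor_a = np.asarray(anchor_a, float)
    anchor_b = np.asarray(anchor_b, float)
    old_pos = np.asarray(old_pos, float)
    circ = _circle(anchor_a, anchor_b, len_a, len_b)
    if circ is None:
        return None
    center, e, radius = circ
    w = old_pos - center
    w_perp = w - (w @ e) * e
    nw = float(np.sqrt(w_perp @ w_perp))
    if nw < 1e-9:
        return None            # on the axis: tie cannot be broken reversibly
    return center + radius * w_perp / nw


def transport_closure(
    anchor_a_old, anchor_a_new, anchor_b, len_a, len_b, old_pos
):
    """Reversible (involutive) closure selection.

    ``anchor_a_old``/``anchor_a_new`` are the moving anchor's positions before
    and after the Cartesian displacement; ``anchor_b`` stays fixed.  The
    closure atom's azimuth about the anchor axis — measured from the plane
    spanned by the old and new axes — is transported unchanged from the old
    to the new solution circle.
    """
    anchor_a_old = np.asarray(anchor_a_old, float)
    anchor_a_new = np.asarray(anchor_a_new, float)
    anchor_b = np.asarray(anchor_b, float)
    old_pos = np.asarray(old_pos, float)
    circ_m = _circle(anchor_a_old, anchor_b, len_a, len_b)
    circ_n = _circle(anchor_a_new, anchor_b, len_a, len_b)
    if circ_m is None or circ_n is None:
        return None
    c_m, e_m, r_m = circ_m
    c_n, e_n, r_n = circ_n
    # reference direction in each circle's plane, from the common plane of
    # the two axes.  The minus sign on u_n makes the map the identity in the
    # zero-displacement limit (u_n -> +u_m as e_n -> e_m); swapping old<->new
    # still inverts the map exactly because both frame vectors change sign,
    # which shifts measured and placed azimuths by pi simultaneously.
    u_m = e_n - (e_n @ e_m) * e_m
    u_n = -(e_m - (e_m @ e_n) * e_n)
    num = float(np.sqrt(u_m @ u_m))
    nun = float(np.sqrt(u_n @ u_n))
    if num < 1e-10 or nun < 1e-10:
        # (anti)parallel axes: use a shared lab-frame reference
        t = (
            np.array([1.0, 0.0, 0.0])
            if abs(e_m[0]) < 0.9
            else np.array([0.0, 1.0, 0.0])
        )
        u_m = t - (t @ e_m) * e_m
        u_n = t - (t @ e_n) * e_n
        num = float(np.sqrt(u_m @ u_m))
        nun = float(np.sqrt(u_n @ u_n))
        if num < _EPS or nun < _EPS:
            return None
    u_m = u_m / num
    u_n = u_n / nun
    v_m = _cross3(e_m, u_m)
    v_n = _cross3(e_n, u_n)
    w = old_pos - c_m
    x, y = float(w @ u_m), float(w @ v_m)
    nw = np.hypot(x, y)
    if nw < 1e-9:
        return None
    x, y = x / nw, y / nw
    return c_n + r_n * (x * u_n + y * v_n)


def rotate_about_axis(points, origin, axis, angle):
    """Rodrigues rotation of ``points`` about the line (origin, axis)."""
    axis = np.asarray(axis, float)
    na = np.linalg.norm(axis)
    if na < _EPS:
        raise GeometryError("rotation axis is degenerate")
    k = axis / na
    v = np.atleast_2d(points) - origin
    c, s = np.cos(angle), np.sin(angle)
    out = (
        v * c
        + np.cross(k, v) * s
        + np.outer(v @ k, k) * (1.0 - c)
    ) + origin
    return out if np.asarray(points).ndim > 1 else out[0]
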