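"""Sigmoidal distance-dependent dielectric for implicit water.

The screening function rises from the vacuum value 1 at contact to a plateau
``d`` (water, 78) with a slope parameter ``s`` (1/Å)::

    eps(r) = d - (d - 1)/2 * ((s r)^2 + 2 s r + 2) * exp(-s r)

At r = 0 the polynomial factor equals 2 and eps = 1; for s r >> 1 the
exponential kills the correction and eps -> d.  The argument is the product
s*r: with d = 78 this reproduces eps(10 Å) = 74.69 for s = 0.65 and
eps(10 Å) = 15.72 for s = 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import GeometryError


@dataclass(frozen=True)
class DielectricParams:
    """Plateau value and slope of the sigmoidal screening function."""

    plateau_d: float = 78.0
    slope_s: float = 0.654       # 1/Å

    def __post_init__(self):
        if self.plateau_d < 1:
            raise ValueError("plateau_d must be >= 1")
        if self.slope_s <= 0:
            raise ValueError("slope_s must be > 0")


def dielectric(r, params: DielectricParams = DielectricParams()):
    """Evaluate eps(r); ``r`` in Å, scalar or array.  Raises for r < 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise GeometryError("dielectric: distance must be non-negative")
    x = params.slope_s * r
    out = params.plateau_d - (params.plateau_d - 1.0) / 2.0 * (
        x * x + 2.0 * x + 2.0
    ) * np.exp(-x)
    return float(out) if out.ndim == 0 else out
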