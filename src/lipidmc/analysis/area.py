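"""Area per lipid and the area-fluctuation compressibility modulus."""

from __future__ import annotations

import warnings

import numpy as np

from ..constants import KB, KCAL_PER_MOL_A2_TO_MN_PER_M
from ..errors import AnalysisError

K_A_CAP = 1.0e6  # mN/m; reported when the area variance vanishes


def area_per_lipid(area_series: np.ndarray, lipids_per_leaflet: int) -> np.ndarray:
    """Per-cycle area per lipid in nm^2 from the box-area series (Å^2)."""
    area_series = np.asarray(area_series, float)
    if np.any(~np.isfinite(area_series)):
        raise AnalysisError(
            "area series contains NaN: not a bilayer (boxless) trajectory"
        )
    return area_series / lipids_per_leaflet / 100.0


def compressibility(
    area_series: np.ndarray, temperature: float, burn_in: int = 0
) -> float:
    """K_A = k_B T <A> / Var(A) in mN/m, with A the total leaflet area (Å^2).

    A vanishing variance (frozen area) gives a formally infinite modulus; the
    result is capped at K_A_CAP with a warning.
    """
    a = np.asarray(area_series, float)[burn_in:]
    if np.any(~np.isfinite(a)):
        raise AnalysisError("area series contains NaN: not a bilayer trajectory")
    if len(a) < 2:
        raise AnalysisError("need at least 2 area samples")
    var = float(np.var(a))
    mean = float(np.mean(a))
    if var == 0.0:
        warnings.warn("zero area variance; compressibility capped")
        return K_A_CAP
    ka = KB * temperature * mean / var * KCAL_PER_MOL_A2_TO_MN_PER_M
    if ka > K_A_CAP:
        warnings.warn("compressibility exceeds cap; reporting capped value")
        return K_A_CAP
    return ka
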