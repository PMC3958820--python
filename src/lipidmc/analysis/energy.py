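"""Energy-histogram statistics and the fluctuation heat capacity.

At equilibrium the probability density of the conformational energy (or
enthalpy, for NPT runs) is well approximated by a Gaussian; its fitted
standard deviation gives the heat capacity through the fluctuation formula
c = sigma^2 / (k_B T^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ..constants import KB
from ..errors import AnalysisError


@dataclass
class HistogramFit:
    mean: float           # kcal/mol
    sd: float             # kcal/mol
    amplitude: float      # counts
    bin_edges: np.ndarray
    residual: float       # RMS of (counts - fit)


def _gaussian(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_energy_histogram(
    series: np.ndarray, burn_in: int = 0, bins: int = 60
) -> HistogramFit:
    """Nonlinear least-squares Gaussian fit to the energy histogram of
    ``series[burn_in:]``."""
    data = np.asarray(series, float)[burn_in:]
    if len(data) < 1000:
        raise AnalysisError(
            f"need >= 1000 samples after burn-in, got {len(data)}"
        )
    sd0 = float(np.std(data))
    if sd0 == 0.0:
        raise AnalysisError("degenerate energy series (zero variance)")
    counts, edges = np.histogram(data, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(np.mean(data)), sd0)
    popt, _ = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=10000)
    a, mu, sigma = popt
    resid = float(np.sqrt(np.mean((counts - _gaussian(centers, *popt)) ** 2)))
    return HistogramFit(
        mean=float(mu),
        sd=abs(float(sigma)),
        amplitude=float(a),
        bin_edges=edges,
        residual=resid,
    )


def heat_capacity(fit: HistogramFit, temperature: float) -> float:
    """Fluctuation heat capacity sigma^2/(k_B T^2), kcal/(mol K)."""
    return fit.sd**2 / (KB * temperature**2)
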