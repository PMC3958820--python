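"""Mean-square displacement of molecular centers of mass.

The MSD at lag s averages |r(s0 + s) - r(s0)|^2 over every available time
origin s0 (sliding window) and over all molecules, using the *unwrapped*
center-of-mass series.  For in-plane (x, y) diffusion the Einstein relation
MSD(s) = 4 D s gives an apparent diffusion coefficient per MC cycle; no
physical-time meaning is attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import AnalysisError


@dataclass
class MSDResult:
    lag_grid: np.ndarray       # MC cycles
    msd: np.ndarray            # Å^2
    fit_window: tuple[int, int]
    d_apparent: float          # Å^2 / cycle
    intercept: float


def msd_curve(
    com_series: np.ndarray, dims: tuple[int, ...] = (0, 1), max_lag: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Time- and molecule-averaged MSD over all lag origins.

    ``com_series``: (n_cycles, n_molecules, 3) unwrapped positions.  Uses the
    FFT autocorrelation identity, which is exactly the double-loop average.
    """
    r = np.asarray(com_series, float)[:, :, list(dims)]
    n, m, d = r.shape
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    # sum over dims of per-molecule 1-D MSDs via FFT correlation
    msd = np.zeros(max_lag + 1)
    for j in range(m):
        for k in range(d):
            x = r[:, j, k]
            msd[1:] += _msd_1d(x, max_lag)[1:]
    msd /= m
    return np.arange(max_lag + 1), msd


def _msd_1d(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(x)
    # S1 recursion + FFT autocorrelation (exact, O(n log n))
    fft_len = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, fft_len)
    acf = np.fft.irfft(fx * np.conj(fx), fft_len)[:n].real
    sq = x * x
    ssum = 2.0 * sq.sum()
    out = np.empty(max_lag + 1)
    out[0] = 0.0
    for s in range(1, max_lag + 1):
        ssum -= sq[s - 1] + sq[n - s]
        out[s] = (ssum - 2.0 * acf[s]) / (n - s)
    return out


def msd_brute_force(
    com_series: np.ndarray, dims: tuple[int, ...] = (0, 1), max_lag: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Direct double-loop evaluation (reference implementation)."""
    r = np.asarray(com_series, float)[:, :, list(dims)]
    n, m, _ = r.shape
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    lags = np.arange(max_lag + 1)
    msd = np.zeros(max_lag + 1)
    for s in range(1, max_lag + 1):
        dv = r[s:] - r[:-s]
        msd[s] = np.mean(np.sum(dv * dv, axis=2))
    return lags, msd


def msd(
    com_series: np.ndarray,
    fit_window: tuple[int, int],
    dims: tuple[int, ...] = (0, 1),
    max_lag: int | None = None,
) -> MSDResult:
    """MSD curve plus a least-squares Einstein fit on ``fit_window`` lags.

    D = slope / (2 * len(dims)); for the default in-plane case slope/4.
    """
    lags, curve = msd_curve(com_series, dims=dims, max_lag=max_lag)
    lo, hi = fit_window
    if hi > lags[-1] + 1:
        hi = int(lags[-1] + 1)
    sel = (lags >= lo) & (lags < hi)
    if np.sum(sel) < 3:
        raise AnalysisError("fit window must span at least 3 lags")
    slope, intercept = np.polyfit(lags[sel], curve[sel], 1)
    return MSDResult(
        lag_grid=lags,
        msd=curve,
        fit_window=(lo, hi),
        d_apparent=float(slope) / (2.0 * len(dims)),
        intercept=float(intercept),
    )
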