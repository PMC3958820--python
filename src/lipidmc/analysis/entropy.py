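"""Configurational entropy from the mass-weighted covariance matrix.

The Schlitter estimator bounds the quantum-mechanical entropy of a harmonic
reference from the covariance C of the Cartesian coordinates:

    S = (k_B / 2) ln det( 1 + (k_B T e^2 / hbar^2) M^{1/2} C M^{1/2} )

with e Euler's number and M the diagonal mass matrix.  In one dimension this
reduces to the scalar form S = (k_B/2) ln(1 + k_B T e^2 m sigma^2 / hbar^2).
The estimate assumes Gaussian fluctuations about the mean; it is an upper
bound on the true configurational entropy.

No roto-translational superposition is applied before accumulating the
covariance by default; an optimal-superposition mode exists behind a flag
and changes the result (documented).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..constants import J_PER_MOL_TO_KCAL_PER_MOL, AVOGADRO, KB_SI, SCHLITTER_PREFACTOR
from ..errors import AnalysisError


@dataclass
class EntropyResult:
    covariance: np.ndarray       # (3n, 3n), Å^2
    entropy: float               # kcal/(mol K)
    free_energy: float | None    # kcal/mol, when mean energy given
    n_samples: int


def covariance_matrix(
    frames: np.ndarray,
    atom_selection: np.ndarray | None = None,
    window: slice | None = None,
    superpose: bool = False,
) -> np.ndarray:
    """Covariance sigma_ij = <(x_i - <x_i>)(x_j - <x_j>)> of the flattened
    Cartesian coordinates over the frame window, Å^2.

    ``frames``: (n_frames, n_atoms, 3).  With ``superpose=True`` every frame
    is first rigidly aligned (rotation + translation, Kabsch) onto the first
    frame of the window.
    """
    frames = np.asarray(frames, float)
    if window is not None:
        frames = frames[window]
    if atom_selection is not None:
        frames = frames[:, np.asarray(atom_selection, dtype=np.intp), :]
    if frames.shape[0] < 2:
        raise AnalysisError("covariance needs at least 2 frames")
    if superpose:
        frames = _superpose(frames)
    flat = frames.reshape(frames.shape[0], -1)
    mu = flat.mean(axis=0)
    dev = flat - mu
    cov = dev.T @ dev / flat.shape[0]
    return 0.5 * (cov + cov.T)


def _superpose(frames: np.ndarray) -> np.ndarray:
    ref = frames[0] - frames[0].mean(axis=0)
    out = np.empty_like(frames)
    for k, f in enumerate(frames):
        x = f - f.mean(axis=0)
        h = x.T @ ref
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        out[k] = x @ rot
    return out


def schlitter_entropy(
    covariance: np.ndarray, masses: np.ndarray, temperature: float
) -> float:
    """Schlitter entropy in kcal/(mol K) from a Cartesian covariance (Å^2)
    and per-atom masses (amu)."""
    masses = np.asarray(masses, float)
    if np.any(masses <= 0):
        raise AnalysisError("masses must be positive")
    n3 = covariance.shape[0]
    if covariance.shape != (n3, n3) or n3 % 3 != 0:
        raise AnalysisError("covariance must be (3n, 3n)")
    if len(masses) * 3 != n3:
        raise AnalysisError("mass vector does not match covariance size")
    m3 = np.repeat(masses, 3)
    sqrt_m = np.sqrt(m3)
    mw = covariance * np.outer(sqrt_m, sqrt_m)
    mat = np.eye(n3) + SCHLITTER_PREFACTOR * temperature * mw
    sign, logdet = np.linalg.slogdet(mat)
    if sign <= 0:
        raise AnalysisError(
            "non-positive determinant in entropy (covariance not PSD); "
            f"condition estimate {np.linalg.cond(mat):.2e}"
        )
    # (k_B/2) ln det, per mole, in kcal/(mol K)
    return 0.5 * KB_SI * AVOGADRO * J_PER_MOL_TO_KCAL_PER_MOL * logdet


def free_energy(mean_energy: float, entropy: float, temperature: float) -> float:
    """F = E - T S, kcal/mol."""
    return mean_energy - temperature * entropy


def entropy_from_frames(
    frames: np.ndarray,
    masses: np.ndarray,
    temperature: float,
    mean_energy: float | None = None,
    **cov_kwargs,
) -> EntropyResult:
    cov = covariance_matrix(frames, **cov_kwargs)
    s = schlitter_entropy(cov, masses, temperature)
    f = (
        free_energy(mean_energy, s, temperature)
        if mean_energy is not None
        else None
    )
    n = frames.shape[0] if cov_kwargs.get("window") is None else None
    return EntropyResult(
        covariance=cov,
        entropy=s,
        free_energy=f,
        n_samples=n or frames.shape[0],
    )
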