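"""Head-group orientation: the P-N vector against the bilayer normal."""

from __future__ import annotations

import numpy as np

from ..errors import AnalysisError
from ..model.topology import Topology


def pn_angles(
    frames: np.ndarray,
    topology: Topology,
    p_name: str = "P5",
    n_name: str = "N1",
) -> np.ndarray:
    """Angle (degrees, [0, 180]) between the P->N vector of each molecule and
    the +z bilayer normal; shape (n_frames, n_molecules)."""
    n_t = topology.n_atoms // topology.n_molecules
    names = [a.name for a in topology.atoms[:n_t]]
    try:
        ip = names.index(p_name)
        in_ = names.index(n_name)
    except ValueError:
        raise AnalysisError(
            f"atoms {p_name!r}/{n_name!r} not found in template"
        ) from None
    p_idx = np.array([ip + m * n_t for m in range(topology.n_molecules)])
    n_idx = np.array([in_ + m * n_t for m in range(topology.n_molecules)])
    v = frames[:, n_idx, :] - frames[:, p_idx, :]
    cosang = v[..., 2] / np.linalg.norm(v, axis=-1)
    return np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))


def pn_vector_distribution(
    frames: np.ndarray,
    topology: Topology,
    bin_width: float = 5.0,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy (percent) of the P-N angle per bin over [0, 180]."""
    ang = pn_angles(frames, topology, **kwargs).ravel()
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(ang, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, 100.0 * counts / counts.sum()
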