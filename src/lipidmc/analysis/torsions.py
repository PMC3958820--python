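"""Torsion-angle occupancy distributions.

Head-group torsions follow the conventional phosphatidylcholine naming:
alpha torsions run along the choline-phosphate-glycerol backbone, beta
torsions down the sn-2 chain.  The shipped table maps each name to its four
bonded atoms of the DPPC template; distributions are averaged over molecules
and frames and reported as percentage occupancy per bin on [-180, 180).
"""

from __future__ import annotations

import numpy as np

from ..errors import AnalysisError
from ..forcefield.energy import EnergyModel
from ..model.topology import Topology

# 1-based template serials for the united-atom DPPC torsion names
DPPC_TORSIONS = {
    "alpha1": (5, 6, 7, 8),
    "alpha2": (4, 5, 6, 7),
    "alpha3": (3, 4, 5, 6),
    "alpha4": (2, 3, 4, 5),
    "alpha5": (1, 2, 3, 4),
    "alpha6": (44, 1, 2, 3),
    "beta1": (7, 8, 9, 10),
    "beta4": (10, 11, 12, 13),
}


def torsion_atoms(torsion_name: str) -> tuple[int, int, int, int]:
    """0-based template atom quadruple for a named torsion."""
    try:
        quad = DPPC_TORSIONS[torsion_name]
    except KeyError:
        raise AnalysisError(
            f"unknown torsion {torsion_name!r}; known: "
            + ", ".join(sorted(DPPC_TORSIONS))
        ) from None
    return tuple(x - 1 for x in quad)


def torsion_series(
    frames: np.ndarray, topology: Topology, quad: tuple[int, int, int, int],
    template_n_atoms: int | None = None,
) -> np.ndarray:
    """Dihedral values (degrees) for the named quadruple in every molecule
    and frame; shape (n_frames, n_molecules)."""
    n_t = template_n_atoms or (topology.n_atoms // topology.n_molecules)
    idx = np.array(
        [[a + m * n_t for a in quad] for m in range(topology.n_molecules)],
        dtype=np.intp,
    )
    out = np.empty((frames.shape[0], len(idx)))
    for k, f in enumerate(frames):
        out[k] = np.rad2deg(EnergyModel.dihedrals(f, idx))
    return out


def torsion_distribution(
    frames: np.ndarray,
    topology: Topology,
    torsion_name: str,
    bin_width: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy percentage per bin over [-180, 180).

    Returns (bin_centers_deg, occupancy_percent); occupancies sum to 100.
    """
    quad = torsion_atoms(torsion_name)
    values = torsion_series(frames, topology, quad).ravel()
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(np.mod(values + 180.0, 360.0) - 180.0, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, 100.0 * counts / counts.sum()
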