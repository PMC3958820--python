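"""The Metropolis driver: sequential per-DOF sweeps with bookkeeping.

One MC cycle visits every move-plan entry once, in plan-file order, updating
the energy incrementally after each accepted move (sequential updating).  For
NPT bilayer runs one volume move is attempted at the end of each cycle; the
pair list is rebuilt on a fixed schedule and after every accepted volume
move.  A fixed master seed makes the whole trajectory reproducible
bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..constants import ATM_A3_TO_KCAL_MOL
from ..errors import LipidMCError, OverlapError
from ..forcefield.dielectric import DielectricParams
from ..forcefield.energy import EnergyModel
from ..model.moveplan import MovePlan
from ..model.topology import Configuration, Topology, molecule_centers_of_mass
from ..moves.metropolis import metropolis_accept
from ..moves.proposals import (
    propose_breakage_move,
    propose_crankshaft,
    propose_internal,
    propose_volume_move,
)

logger = logging.getLogger(__name__)

ENSEMBLES = ("NVT_monomer", "NPT_bilayer")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    temperature: float = 323.0          # K
    pressure: float = 1.0               # atm
    n_cycles: int = 1000
    save_every: int = 100               # cycles between saved frames
    list_update_every: int = 10         # pair-list refresh period, cycles
    seed: int = 0
    ensemble: str = "NVT_monomer"
    cutoff: float | None = None         # Å; None = all pairs (monomer)
    shell: float = 10.0
    dielectric: DielectricParams = field(default_factory=DielectricParams)
    dielectric_mode: str = "pair"
    constant_epsilon: float = 1.0
    max_dlnv: float = 0.02              # volume-move step in ln V
    step_scale: float = 1.0             # global multiplier on plan step sizes
    include_jacobian: bool = True       # False only for bias demonstrations
    check_every: int = 50               # CBLA verification period, cycles
    cbla_tol: float = 1e-6              # Å relative; abort beyond this

    def __post_init__(self):
        if self.n_cycles <= 0:
            raise ValueError("n_cycles must be positive")
        if self.list_update_every < 1:
            raise ValueError("list_update_every must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.ensemble not in ENSEMBLES:
            raise ValueError(f"unknown ensemble {self.ensemble!r}")


@dataclass
class Trajectory:
    """Saved frames plus per-cycle scalars.

    ``scalars`` holds one row per cycle: the conformational energy (NVT) or
    enthalpy E + PV (NPT), volume and box area (NaN without a box), and
    cumulative acceptance counts.  ``com_series`` holds the unwrapped
    per-molecule centers of mass each cycle, which is what the mean-square
    displacement needs (wrap jumps never enter).
    """

    frames: list[np.ndarray] = field(default_factory=list)
    frame_cycles: list[int] = field(default_factory=list)
    frame_boxes: list[float | None] = field(default_factory=list)
    scalars: dict[str, np.ndarray] = field(default_factory=dict)
    com_series: np.ndarray | None = None
    topology: Topology | None = None
    run_config: RunConfig | None = None
    acceptance: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_configuration(self, k: int) -> Configuration:
        periodic = (0, 1) if self.frame_boxes[k] is not None else ()
        return Configuration(
            self.frames[k].copy(), self.frame_boxes[k], periodic
        )


class AbortError(LipidMCError):
    """Mid-run constraint violation; carries a diagnostic frame."""

    def __init__(self, msg, coords=None, cycle=None):
        super().__init__(msg)
        self.coords = coords
        self.cycle = cycle


_PROPOSERS = {
    "breakage": "breakage",
    "crankshaft": "crankshaft",
    "torsion": "internal",
    "bond_angle": "internal",
}


def run_mc(
    configuration: Configuration,
    topology: Topology,
    plan: MovePlan,
    run_config: RunConfig,
    energy_model: EnergyModel | None = None,
) -> Trajectory:
    """Execute ``run_config.n_cycles`` sequential sweeps and return the
    trajectory.  The starting configuration is not modified."""
    rc = run_config
    conf = configuration.copy()
    dev = topology.max_bond_deviation(conf.coords)
    if dev > rc.cbla_tol:
        raise AbortError(
            f"start configuration violates bond constraints ({dev:.2e})"
        )
    if energy_model is None:
        energy_model = EnergyModel(
            topology,
            _require_ff(plan, topology),
            cutoff=rc.cutoff,
            shell=rc.shell,
            dielectric_params=rc.dielectric,
            dielectric_mode=rc.dielectric_mode,
            constant_epsilon=rc.constant_epsilon,
        )
    rng = np.random.default_rng(rc.seed)
    npt = rc.ensemble == "NPT_bilayer"
    if npt and conf.box is None:
        raise ValueError("NPT_bilayer needs a periodic box")

    nlist = (
        energy_model.build_neighbor_list(conf)
        if energy_model.cutoff is not None
        else None
    )
    energy = energy_model.total_energy(conf, nlist)

    n_cyc = rc.n_cycles
    scal_e = np.empty(n_cyc)
    scal_v = np.full(n_cyc, np.nan)
    scal_a = np.full(n_cyc, np.nan)
    n_mol = topology.n_molecules
    com_series = np.empty((n_cyc, n_mol, 3))
    attempts: dict[str, int] = {}
    accepts: dict[str, int] = {}
    traj = Trajectory(topology=topology, run_config=rc)

    def save_frame(cycle):
        traj.frames.append(conf.coords.copy())
        traj.frame_cycles.append(cycle)
        traj.frame_boxes.append(conf.box)

    save_frame(0)
    for cycle in range(1, n_cyc + 1):
        for entry in plan:
            cls = entry.move_class
            attempts[cls] = attempts.get(cls, 0) + 1
            if cls == "breakage":
                prop = propose_breakage_move(
                    conf, entry, topology, rng,
                    max_step=entry.max_step * rc.step_scale,
                )
            elif cls == "crankshaft":
                prop = propose_crankshaft(
                    conf, entry, rng, max_angle=entry.max_step * rc.step_scale
                )
            else:
                prop = propose_internal(
                    conf, entry, rng, max_step=entry.max_step * rc.step_scale
                )
            if prop.feasible:
                try:
                    prop.delta_E = energy_model.delta_energy(
                        conf, prop.trial_coords, nlist
                    )
                except OverlapError:
                    # hard-core overlap in the trial state: certain rejection
                    prop.feasible = False
            if metropolis_accept(
                prop, rc.temperature, rng,
                include_jacobian=rc.include_jacobian,
            ):
                for a, x in prop.trial_coords.items():
                    conf.coords[a] = x
                energy += prop.delta_E
                accepts[cls] = accepts.get(cls, 0) + 1

        if npt:
            attempts["volume"] = attempts.get("volume", 0) + 1
            min_box = (
                2.0 * (energy_model.cutoff + energy_model.shell)
                if energy_model.cutoff is not None
                else None
            )
            prop = propose_volume_move(
                conf, topology, rc.max_dlnv, rng, min_box=min_box
            )
            if prop.feasible:
                try:
                    prop.delta_E = energy_model.intermolecular_delta(
                        conf, prop.full_coords, prop.new_box, nlist
                    )
                except OverlapError:
                    prop.feasible = False
            if metropolis_accept(
                prop, rc.temperature, rng,
                pressure=rc.pressure, n_molecules=n_mol,
                include_jacobian=rc.include_jacobian,
            ):
                conf.coords[:] = prop.full_coords
                conf.box = prop.new_box
                energy += prop.delta_E
                accepts["volume"] = accepts.get("volume", 0) + 1
                if energy_model.cutoff is not None:
                    nlist = energy_model.build_neighbor_list(conf)

        # refresh on schedule, and before any saved frame so that recorded
        # scalars equal a full recompute on the saved configuration
        if energy_model.cutoff is not None and (
            cycle % rc.list_update_every == 0 or cycle % rc.save_every == 0
        ):
            nlist = energy_model.build_neighbor_list(conf)
            energy = energy_model.total_energy(conf, nlist)

        scal_e[cycle - 1] = (
            energy
            + (rc.pressure * conf.volume() * ATM_A3_TO_KCAL_MOL if npt else 0.0)
        )
        if conf.box is not None:
            scal_v[cycle - 1] = conf.volume()
            scal_a[cycle - 1] = conf.area()
        com_series[cycle - 1] = molecule_centers_of_mass(conf.coords, topology)

        if cycle % rc.check_every == 0 or cycle == n_cyc:
            dev = topology.max_bond_deviation(conf.coords)
            if dev > rc.cbla_tol:
                raise AbortError(
                    f"bond-length drift {dev:.2e} at cycle {cycle}",
                    coords=conf.coords.copy(),
                    cycle=cycle,
                )
        if cycle % rc.save_every == 0:
            save_frame(cycle)
        if cycle % 1000 == 0:
            stats = ", ".join(
                f"{k}: {accepts.get(k, 0) / max(v, 1):.2f}"
                for k, v in sorted(attempts.items())
            )
            logger.info("cycle %d  E=%.2f  acceptance %s", cycle, energy, stats)

    if traj.frame_cycles[-1] != n_cyc:
        save_frame(n_cyc)
    traj.scalars = {
        "cycle": np.arange(1, n_cyc + 1),
        "energy": scal_e,
        "volume": scal_v,
        "area": scal_a,
    }
    traj.com_series = com_series
    traj.acceptance = {
        k: (accepts.get(k, 0), attempts[k]) for k in attempts
    }
    return traj


def _require_ff(plan, topology):
    raise ValueError(
        "run_mc needs an EnergyModel (pass energy_model=...); "
        "building one requires the force field"
    )
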