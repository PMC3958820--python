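"""Configuration energies with cutoffs, pair lists, and fast local deltas.

Nonbonded: 6-12 Lennard-Jones (Lorentz-Berthelot combination) plus Coulomb
screened by the sigmoidal distance-dependent dielectric, truncated sharply at
``cutoff`` with minimum-image distances on the periodic dimensions.  Bonded
pairs (1-2) and angle pairs (1-3) are excluded; 1-4 pairs are scaled by the
parameter-file factors.  Bonded terms: harmonic bond angles, AMBER-style
Fourier torsions, and Ryckaert-Bellemans cosine polynomials for the acyl
chains.  There is no bond-stretch term: bond lengths are constraints.

``delta_energy`` evaluates E(trial) - E(current) restricted to terms that
involve moved atoms, which equals the full-recompute difference because the
pair list's shell guarantees that every pair within the cutoff in either
state is enumerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import COULOMB
from ..errors import GeometryError, OverlapError
from ..model.parameters import ForceField
from ..model.topology import Configuration, Topology
from .dielectric import DielectricParams, dielectric

OVERLAP_LIMIT = 0.1   # Å; closer nonbonded pairs indicate a corrupted state


@dataclass
class NeighborList:
    """Verlet-style pair list: inner pairs (within cutoff) are evaluated every
    step; shell pairs (cutoff..cutoff+shell) guarantee correctness of local
    energy deltas until atoms have moved by shell/2."""

    pairs_inner: np.ndarray          # (P, 2) int
    pairs_shell: np.ndarray
    cutoff: float
    shell: float
    age: int = 0
    generation: int = 0
    # per-atom candidate partners (inner + shell), for local deltas
    candidates: list = field(default_factory=list, repr=False)


def minimum_image(dv: np.ndarray, box: float | None, periodic_dims) -> np.ndarray:
    if box is not None:
        for d in periodic_dims:
            dv[..., d] -= box * np.round(dv[..., d] / box)
    return dv


class EnergyModel:
    """Energy evaluator bound to one topology + force field.

    Parameters
    ----------
    cutoff, shell : float or None
        Nonbonded truncation and pair-list shell width in Å.  ``cutoff=None``
        evaluates all pairs (single-molecule runs).
    dielectric_params : DielectricParams
    dielectric_mode : {"pair", "constant", "interface"}
        "pair" screens by interatomic distance (default); "constant" uses
        ``constant_epsilon``; "interface" screens by the pair midpoint's
        |z| distance from the bilayer midplane (z = 0).
    """

    def __init__(
        self,
        topology: Topology,
        ff: ForceField,
        *,
        cutoff: float | None = None,
        shell: float = 10.0,
        dielectric_params: DielectricParams = DielectricParams(),
        dielectric_mode: str = "pair",
        constant_epsilon: float = 1.0,
    ):
        if dielectric_mode not in ("pair", "constant", "interface"):
            raise ValueError(f"unknown dielectric mode {dielectric_mode!r}")
        self.topology = topology
        self.ff = ff
        self.cutoff = cutoff
        self.shell = shell
        self.dielectric_params = dielectric_params
        self.dielectric_mode = dielectric_mode
        self.constant_epsilon = constant_epsilon

        n = topology.n_atoms
        self.n_t = ff.n_atoms
        self.n_rep = n // self.n_t
        self.charges = topology.charges()
        sig = np.array([ff.lj_params(a.type_)[0] for a in ff.atoms])
        eps = np.array([ff.lj_params(a.type_)[1] for a in ff.atoms])
        self.sigma = np.tile(sig, self.n_rep)
        self.epsilon = np.tile(eps, self.n_rep)
        self._build_exclusions()
        self._build_bonded_terms()
        self._delta_cache: dict = {}
        self._nlist_generation = 0

    # ------------------------------------------------------------------
    # exclusions

    def _build_exclusions(self):
        """Template-molecule pair classes: 0 full, 1 excluded (1-2/1-3),
        2 scaled (1-4).  Stored as a dense (n_t, n_t) int8 matrix."""
        n_t = self.n_t
        cls = np.zeros((n_t, n_t), dtype=np.int8)
        nbrs = [
            [j for j in self.topology.neighbors(i) if j < n_t]
            for i in range(n_t)
        ]
        for i in range(n_t):
            for j in nbrs[i]:
                cls[i, j] = 1
                for k in nbrs[j]:
                    if k != i:
                        if cls[i, k] == 0:
                            cls[i, k] = 1
                        cls[k, i] = cls[i, k]
                        for l in nbrs[k]:
                            if l != j and l != i and cls[i, l] == 0:
                                cls[i, l] = 2
                                cls[l, i] = 2
        # re-mark 1-3 over any 1-4 assignment made through a different path
        for i in range(n_t):
            for j in nbrs[i]:
                for k in nbrs[j]:
                    if k != i:
                        cls[i, k] = 1
                        cls[k, i] = 1
                cls[i, j] = 1
                cls[j, i] = 1
        np.fill_diagonal(cls, 1)
        self.pair_class = cls

    def _pair_classes(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Pair class for absolute atom indices (0 across molecules)."""
        same = (i // self.n_t) == (j // self.n_t)
        out = np.zeros(len(i), dtype=np.int8)
        if np.any(same):
            out[same] = self.pair_class[i[same] % self.n_t, j[same] % self.n_t]
        return out

    # ------------------------------------------------------------------
    # bonded terms

    def _build_bonded_terms(self):
        ff, n_t = self.ff, self.n_t
        reps = np.arange(self.n_rep) * n_t

        def tile_idx(base):
            base = np.asarray(base, dtype=np.intp)
            if base.size == 0:
                return base.reshape(0, base.shape[-1] if base.ndim > 1 else 0)
            return (base[None, :, :] + reps[:, None, None]).reshape(
                -1, base.shape[1]
            )

        ang = np.array([[t.i, t.j, t.k] for t in ff.angles], dtype=np.intp)
        self.angle_idx = tile_idx(ang) if len(ang) else np.empty((0, 3), np.intp)
        self.angle_k = np.tile(np.array([t.k_theta for t in ff.angles]), self.n_rep)
        self.angle_th0 = np.tile(np.array([t.theta0 for t in ff.angles]), self.n_rep)

        four = np.array(
            [[t.i, t.j, t.k, t.l] for t in ff.torsions], dtype=np.intp
        )
        self.fourier_idx = (
            tile_idx(four) if len(four) else np.empty((0, 4), np.intp)
        )
        self.fourier_v = np.tile(np.array([t.v_n for t in ff.torsions]), self.n_rep)
        self.fourier_g = np.tile(np.array([t.gamma for t in ff.torsions]), self.n_rep)
        self.fourier_n = np.tile(
            np.array([t.n for t in ff.torsions], dtype=float), self.n_rep
        )

        rb = np.array(
            [[t.i, t.j, t.k, t.l] for t in ff.rb_torsions], dtype=np.intp
        )
        self.rb_idx = tile_idx(rb) if len(rb) else np.empty((0, 4), np.intp)
        self.rb_c = (
            np.tile(np.array([t.c for t in ff.rb_torsions]), (self.n_rep, 1))
            if len(rb)
            else np.empty((0, 6))
        )

        # incidence: atom -> bonded term ids per kind
        n = self.topology.n_atoms
        self._incidence = {}
        for kind, idx in (
            ("angle", self.angle_idx),
            ("fourier", self.fourier_idx),
            ("rb", self.rb_idx),
        ):
            inc = [[] for _ in range(n)]
            for t, row in enumerate(idx):
                for a in row:
                    inc[a].append(t)
            self._incidence[kind] = [np.array(x, dtype=np.intp) for x in inc]

    # ------------------------------------------------------------------
    # neighbor list

    def build_neighbor_list(
        self, conf: Configuration, cutoff: float | None = None, shell: float | None = None
    ) -> NeighborList:
        """Classify pairs by minimum-image distance (deterministic ordering).

        Excluded (1-2/1-3) pairs are dropped; 1-4 pairs are kept and scaled
        at evaluation time.
        """
        cutoff = self.cutoff if cutoff is None else cutoff
        shell = self.shell if shell is None else shell
        if cutoff is None:
            raise ValueError("neighbor list requires a finite cutoff")
        n = conf.n_atoms
        reach = cutoff + shell
        pts = conf.coords
        box = conf.box
        if box is not None and conf.periodic_dims and box < 2 * reach:
            import warnings

            warnings.warn(
                f"box ({box:.1f} Å) < 2*(cutoff+shell) ({2 * reach:.1f} Å); "
                "minimum image sees single closest image only"
            )
        ii, jj = np.triu_indices(n, k=1)
        dv = pts[jj] - pts[ii]
        dv = minimum_image(dv, box, conf.periodic_dims)
        r = np.linalg.norm(dv, axis=1)
        keep = r <= reach
        ii, jj, r = ii[keep], jj[keep], r[keep]
        cls = self._pair_classes(ii, jj)
        ok = cls != 1
        ii, jj, r = ii[ok], jj[ok], r[ok]
        inner = r <= cutoff
        nl = NeighborList(
            pairs_inner=np.column_stack([ii[inner], jj[inner]]),
            pairs_shell=np.column_stack([ii[~inner], jj[~inner]]),
            cutoff=cutoff,
            shell=shell,
        )
        cand = [[] for _ in range(n)]
        for a, b in np.concatenate([nl.pairs_inner, nl.pairs_shell]):
            cand[a].append(b)
            cand[b].append(a)
        nl.candidates = [np.array(sorted(c), dtype=np.intp) for c in cand]
        self._nlist_generation += 1
        nl.generation = self._nlist_generation
        self._delta_cache.clear()
        return nl

    # ------------------------------------------------------------------
    # nonbonded

    def _epsilon_of(self, r: np.ndarray, pos_i, pos_j) -> np.ndarray:
        if self.dielectric_mode == "constant":
            return np.full_like(r, self.constant_epsilon)
        if self.dielectric_mode == "interface":
            zmid = np.abs((pos_i[..., 2] + pos_j[..., 2]) / 2.0)
            return dielectric(zmid, self.dielectric_params)
        return dielectric(r, self.dielectric_params)

    def _pair_energy(
        self, i, j, pos_i, pos_j, box, periodic_dims, apply_cutoff=True
    ):
        """Summed LJ + screened Coulomb over index arrays i, j."""
        if len(i) == 0:
            return 0.0
        dv = minimum_image(pos_j - pos_i, box, periodic_dims)
        r = np.linalg.norm(dv, axis=1)
        mask = np.ones(len(r), bool)
        if apply_cutoff and self.cutoff is not None:
            mask = r <= self.cutoff
        cls = self._pair_classes(np.asarray(i), np.asarray(j))
        mask &= cls != 1
        if not np.any(mask):
            return 0.0
        ia, ja = np.asarray(i), np.asarray(j)
        interacting = mask & (
            (self.epsilon[ia] * self.epsilon[ja] > 0.0)
            | (self.charges[ia] * self.charges[ja] != 0.0)
        )
        if np.any(r[interacting] < OVERLAP_LIMIT):
            sub = np.where(interacting)[0]
            k = int(sub[np.argmin(r[sub])])
            raise OverlapError(
                f"atoms {int(ia[k])} and {int(ja[k])} at {r[k]:.3f} Å"
            )
        r = r[mask]
        im, jm = np.asarray(i)[mask], np.asarray(j)[mask]
        clsm = cls[mask]
        sij = 0.5 * (self.sigma[im] + self.sigma[jm])
        eij = np.sqrt(self.epsilon[im] * self.epsilon[jm])
        lj_scale = np.where(clsm == 2, self.ff.scale14_lj, 1.0)
        q_scale = np.where(clsm == 2, self.ff.scale14_coulomb, 1.0)
        x6 = (sij / r) ** 6
        e_lj = 4.0 * eij * (x6 * x6 - x6) * lj_scale
        epsr = self._epsilon_of(r, pos_i[mask], pos_j[mask])
        e_q = COULOMB * self.charges[im] * self.charges[jm] / (epsr * r) * q_scale
        return float(np.sum(e_lj + e_q))

    def nonbonded_energy(
        self, conf: Configuration, nlist: NeighborList | None = None
    ) -> float:
        """Total nonbonded energy (inner pairs of the list, or all pairs)."""
        pts = conf.coords
        if self.cutoff is None:
            n = conf.n_atoms
            ii, jj = np.triu_indices(n, k=1)
        elif nlist is not None:
            pairs = np.concatenate([nlist.pairs_inner, nlist.pairs_shell])
            if len(pairs) == 0:
                return 0.0
            ii, jj = pairs[:, 0], pairs[:, 1]
        else:
            ii, jj = np.triu_indices(conf.n_atoms, k=1)
        return self._pair_energy(
            ii, jj, pts[ii], pts[jj], conf.box, conf.periodic_dims
        )

    # ------------------------------------------------------------------
    # bonded

    @staticmethod
    def _angles(pts, idx):
        u = pts[idx[:, 0]] - pts[idx[:, 1]]
        v = pts[idx[:, 2]] - pts[idx[:, 1]]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        if np.any(nu < 1e-12) or np.any(nv < 1e-12):
            raise GeometryError("coincident atoms in angle evaluation")
        ct = np.einsum("ij,ij->i", u, v) / (nu * nv)
        return np.arccos(np.clip(ct, -1.0, 1.0))

    @staticmethod
    def dihedrals(pts, idx):
        b1 = pts[idx[:, 1]] - pts[idx[:, 0]]
        b2 = pts[idx[:, 2]] - pts[idx[:, 1]]
        b3 = pts[idx[:, 3]] - pts[idx[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        if np.any(np.linalg.norm(n1, axis=1) < 1e-12) or np.any(
            np.linalg.norm(n2, axis=1) < 1e-12
        ):
            raise GeometryError("collinear atoms in dihedral evaluation")
        m1 = np.cross(n1, b2 / nb2[:, None])
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", m1, n2)
        return np.arctan2(y, x)

    def _bonded_subset(self, pts, sel: dict[str, np.ndarray] | None = None) -> float:
        e = 0.0
        a_ids = sel["angle"] if sel is not None else slice(None)
        f_ids = sel["fourier"] if sel is not None else slice(None)
        r_ids = sel["rb"] if sel is not None else slice(None)
        idx = self.angle_idx[a_ids]
        if len(idx):
            th = self._angles(pts, idx)
            e += float(np.sum(self.angle_k[a_ids] * (th - self.angle_th0[a_ids]) ** 2))
        idx = self.fourier_idx[f_ids]
        if len(idx):
            phi = self.dihedrals(pts, idx)
            e += float(
                np.sum(
                    0.5
                    * self.fourier_v[f_ids]
                    * (1.0 + np.cos(self.fourier_n[f_ids] * phi - self.fourier_g[f_ids]))
                )
            )
        idx = self.rb_idx[r_ids]
        if len(idx):
            psi = self.dihedrals(pts, idx) - np.pi
            cp = np.cos(psi)
            c = self.rb_c[r_ids]
            e += float(np.sum(sum(c[:, m] * cp**m for m in range(6))))
        return e

    def bonded_energy(self, conf: Configuration) -> float:
        return self._bonded_subset(conf.coords)

    def total_energy(
        self, conf: Configuration, nlist: NeighborList | None = None
    ) -> float:
        return self.bonded_energy(conf) + self.nonbonded_energy(conf, nlist)

    # ------------------------------------------------------------------
    # local deltas

    def delta_energy(
        self,
        conf: Configuration,
        trial_coords: dict[int, np.ndarray],
        nlist: NeighborList | None = None,
    ) -> float:
        """E(trial) - E(current), restricted to terms involving moved atoms."""
        if not trial_coords:
            return 0.0
        pts = conf.coords
        moved = tuple(sorted(trial_coords))
        key = (
            nlist.generation if nlist is not None and self.cutoff is not None else -1,
            moved,
        )
        cached = self._delta_cache.get(key)
        if cached is None:
            moved_set = set(moved)
            ii, jj = [], []
            if self.cutoff is None or nlist is None:
                n = conf.n_atoms
                allidx = np.arange(n)
                for a in moved:
                    part = allidx[allidx != a]
                    ii.append(np.full(len(part), a))
                    jj.append(part)
            else:
                for a in moved:
                    part = nlist.candidates[int(a)]
                    ii.append(np.full(len(part), a))
                    jj.append(part)
            ii = np.concatenate(ii) if ii else np.empty(0, np.intp)
            jj = np.concatenate(jj) if jj else np.empty(0, np.intp)
            if len(ii):
                both = np.array([int(b) in moved_set for b in jj])
                keep = ~both | (jj > ii)
                ii, jj = ii[keep], jj[keep]
            sel = {
                kind: np.unique(
                    np.concatenate(
                        [self._incidence[kind][int(a)] for a in moved]
                        or [np.empty(0, np.intp)]
                    )
                )
                for kind in ("angle", "fourier", "rb")
            }
            cached = (ii, jj, sel)
            self._delta_cache[key] = cached
        ii, jj, sel = cached

        new_pts = pts.copy()
        for a, x in trial_coords.items():
            new_pts[a] = x
        e_nb_old = self._pair_energy(
            ii, jj, pts[ii], pts[jj], conf.box, conf.periodic_dims
        )
        e_nb_new = self._pair_energy(
            ii, jj, new_pts[ii], new_pts[jj], conf.box, conf.periodic_dims
        )
        e_b_old = self._bonded_subset(pts, sel)
        e_b_new = self._bonded_subset(new_pts, sel)
        return (e_nb_new + e_b_new) - (e_nb_old + e_b_old)

    def intermolecular_delta(
        self,
        conf: Configuration,
        new_coords: np.ndarray,
        new_box: float,
        nlist: NeighborList | None,
    ) -> float:
        """Energy change of intermolecular nonbonded terms under an affine
        center-of-mass rescaling (volume move).  Intramolecular geometry is
        rigid, so bonded and intramolecular nonbonded terms cancel."""
        if nlist is not None:
            pairs = np.concatenate([nlist.pairs_inner, nlist.pairs_shell])
        else:
            n = conf.n_atoms
            ii, jj = np.triu_indices(n, k=1)
            pairs = np.column_stack([ii, jj])
        if len(pairs) == 0:
            return 0.0
        inter = (pairs[:, 0] // self.n_t) != (pairs[:, 1] // self.n_t)
        pairs = pairs[inter]
        if len(pairs) == 0:
            return 0.0
        ii, jj = pairs[:, 0], pairs[:, 1]
        e_old = self._pair_energy(
            ii, jj, conf.coords[ii], conf.coords[jj], conf.box, conf.periodic_dims
        )
        e_new = self._pair_energy(
            ii, jj, new_coords[ii], new_coords[jj], new_box, conf.periodic_dims
        )
        return e_new - e_old
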