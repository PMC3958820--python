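"""Closure geometry, move proposals, Jacobians, Metropolis rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidmc.constants import KB
from lipidmc.errors import GeometryError
from lipidmc.moves import (
    MoveProposal,
    breakage_jacobian_fd,
    metropolis_accept,
    propose_breakage_move,
    propose_crankshaft,
    propose_internal,
    propose_volume_move,
    solve_closure,
    transport_closure,
)
from lipidmc.model import molecule_centers_of_mass


class TestSolveClosure:
    def test_algebraic_example(self):
        # anchors (0,0,0) and (3,0,0), lengths 2, 2: circle at x = 1.5,
        # radius sqrt(4 - 2.25); nearest to (1.5, 1, 0) is (1.5, sqrt(1.75), 0)
        p = solve_closure(
            np.zeros(3), np.array([3.0, 0, 0]), 2.0, 2.0, np.array([1.5, 1.0, 0.0])
        )
        assert np.allclose(p, [1.5, np.sqrt(1.75), 0.0], atol=1e-12)
        assert abs(np.linalg.norm(p) - 2.0) < 1e-10
        assert abs(np.linalg.norm(p - [3, 0, 0]) - 2.0) < 1e-10

    def test_identity_when_on_circle(self):
        a = np.zeros(3)
        b = np.array([2.5, 0, 0])
        old = solve_closure(a, b, 2.0, 2.0, np.array([1.25, 0.9, 0.4]))
        again = solve_closure(a, b, 2.0, 2.0, old)
        assert np.allclose(again, old, atol=1e-12)

    def test_triangle_inequality_infeasible(self):
        assert solve_closure(
            np.zeros(3), np.array([5.0, 0, 0]), 2.0, 2.0, np.ones(3)
        ) is None

    def test_coincident_anchors_infeasible(self):
        assert solve_closure(
            np.zeros(3), np.zeros(3), 2.0, 1.0, np.ones(3)
        ) is None

    def test_on_axis_tie_infeasible(self):
        assert solve_closure(
            np.zeros(3), np.array([3.0, 0, 0]), 2.0, 2.0, np.array([1.5, 0, 0])
        ) is None

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(GeometryError):
            solve_closure(np.zeros(3), np.ones(3), -1.0, 2.0, np.ones(3))


class TestTransportClosure:
    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(seed=st.integers(0, 10_000))
    def test_involutive(self, seed):
        rng = np.random.default_rng(seed)
        a_old = rng.normal(0, 1, 3)
        a_new = a_old + rng.normal(0, 0.3, 3)
        b = a_old + np.array([2.2, 0.3, -0.4]) + rng.normal(0, 0.2, 3)
        old = solve_closure(a_old, b, 1.5, 1.6, rng.normal(0, 2, 3))
        if old is None:
            return
        new = transport_closure(a_old, a_new, b, 1.5, 1.6, old)
        if new is None:
            return
        back = transport_closure(a_new, a_old, b, 1.5, 1.6, new)
        assert back is not None
        assert np.linalg.norm(back - old) < 1e-9
        # bond lengths restored exactly
        assert abs(np.linalg.norm(new - a_new) - 1.5) < 1e-10
        assert abs(np.linalg.norm(new - b) - 1.6) < 1e-10

    def test_agrees_with_nearest_point_for_small_steps(self):
        rng = np.random.default_rng(5)
        a_old = np.zeros(3)
        b = np.array([2.4, 0.2, 0.1])
        old = solve_closure(a_old, b, 1.5, 1.6, np.array([1.0, 1.0, 0.3]))
        for h in (1e-2, 1e-4):
            a_new = a_old + h * np.array([0.3, -0.5, 0.8])
            t = transport_closure(a_old, a_new, b, 1.5, 1.6, old)
            n = solve_closure(a_new, b, 1.5, 1.6, old)
            # both selections converge to the old point; their mutual
            # deviation shrinks linearly with the anchor displacement
            assert np.linalg.norm(t - old) < 5 * h
            assert np.linalg.norm(t - n) < 2 * h


class TestBreakage:
    def test_zero_displacement_is_identity(self, chain5):
        rng = np.random.default_rng(0)
        e = [x for x in chain5.plan if x.move_class == "breakage"][0]
        p = propose_breakage_move(
            chain5.configuration, e, chain5.topology, rng, max_step=0.0
        )
        assert p.feasible
        assert p.jacobian_ratio == pytest.approx(1.0)
        for a, x in p.trial_coords.items():
            assert np.allclose(x, chain5.configuration.coords[a], atol=1e-14)

    def test_bond_preservation_and_locality(self, chain5):
        rng = np.random.default_rng(1)
        top, conf = chain5.topology, chain5.configuration
        e = [x for x in chain5.plan if x.move_class == "breakage"
             and x.atom == 2][0]      # central atom: closures both sides
        for _ in range(50):
            p = propose_breakage_move(conf, e, top, rng, max_step=0.3)
            if not p.feasible:
                continue
            c2 = conf.copy()
            for a, x in p.trial_coords.items():
                c2.coords[a] = x
            assert top.max_bond_deviation(c2.coords) < 1e-10
            # atoms beyond the closure neighbors are bit-identical
            moved = set(p.trial_coords)
            assert moved == {1, 2, 3}
            for a in (0, 4):
                assert np.array_equal(c2.coords[a], conf.coords[a])

    def test_overstretched_closure_infeasible(self, chain5):
        rng = np.random.default_rng(2)
        top = chain5.topology
        conf = chain5.configuration.copy()
        e = [x for x in chain5.plan if x.move_class == "breakage"
             and x.atom == 2][0]
        # a displacement far beyond the sum of bond lengths cannot close
        p = propose_breakage_move(conf, e, top, rng, max_step=0.0)
        conf.coords[2] += np.array([50.0, 0.0, 0.0])   # corrupt current state
        p = propose_breakage_move(conf, e, top, rng, max_step=0.1)
        assert not p.feasible
        assert p.jacobian_ratio == 0.0

    def test_microscopic_reversibility(self, chain5):
        # applying the exact reverse displacement recovers the prior state
        rng = np.random.default_rng(3)
        top, conf = chain5.topology, chain5.configuration
        e = [x for x in chain5.plan if x.move_class == "breakage"
             and x.atom == 2][0]
        for _ in range(20):
            p = propose_breakage_move(conf, e, top, rng, max_step=0.3)
            if not p.feasible:
                continue
            c2 = conf.copy()
            for a, x in p.trial_coords.items():
                c2.coords[a] = x
            u = p.trial_coords[2] - conf.coords[2]
            back = transport_closure(
                c2.coords[2], c2.coords[2] - u, c2.coords[4],
                top.bond_length(3, 2), top.bond_length(3, 4), c2.coords[3],
            )
            assert np.linalg.norm(back - conf.coords[3]) < 1e-9


class TestCrankshaft:
    def test_zero_rotation_identity(self, chain4):
        rng = np.random.default_rng(0)
        e = [x for x in chain4.plan if x.move_class == "crankshaft"][0]
        p = propose_crankshaft(chain4.configuration, e, rng, max_angle=0.0)
        for a, x in p.trial_coords.items():
            assert np.allclose(x, chain4.configuration.coords[a], atol=1e-14)
        assert p.jacobian_ratio == 1.0 and p.selection_ratio == 1.0

    def test_rotation_reversibility_and_bonds(self, chain4):
        top, conf = chain4.topology, chain4.configuration
        e = [x for x in chain4.plan if x.move_class == "crankshaft"
             and x.atom == 1][0]
        from lipidmc.moves import rotate_about_axis

        pts = conf.coords
        axis = pts[2] - pts[0]
        for theta in (0.3, -1.2, 2.8):
            fwd = rotate_about_axis(pts[1], pts[0], axis, theta)
            back = rotate_about_axis(fwd, pts[0], axis, -theta)
            assert np.linalg.norm(back - pts[1]) < 1e-12
            # distances to both flanking atoms preserved
            for fl in (0, 2):
                assert abs(
                    np.linalg.norm(fwd - pts[fl])
                    - np.linalg.norm(pts[1] - pts[fl])
                ) < 1e-12

    def test_coincident_flank_atoms_raise(self, chain4):
        rng = np.random.default_rng(0)
        conf = chain4.configuration.copy()
        e = [x for x in chain4.plan if x.move_class == "crankshaft"
             and x.atom == 1][0]
        conf.coords[2] = conf.coords[0]
        with pytest.raises(GeometryError, match="coincide"):
            propose_crankshaft(conf, e, rng)


class TestInternalMoves:
    def test_torsion_reversibility(self, chain4):
        rng = np.random.default_rng(0)
        conf = chain4.configuration
        e = [x for x in chain4.plan if x.move_class == "torsion"][0]
        p = propose_internal(conf, e, rng)
        c2 = conf.copy()
        for a, x in p.trial_coords.items():
            c2.coords[a] = x
        assert chain4.topology.max_bond_deviation(c2.coords) < 1e-10
        assert p.jacobian_ratio == 1.0

    def test_methyl_torsion_moves_only_methyl(
        self, dppc_topology, monomer_conf, dppc_plan
    ):
        rng = np.random.default_rng(1)
        e = [x for x in dppc_plan if x.move_class == "torsion"
             and x.atom == 43][0]         # N-methyl C44 (0-based 43)
        p = propose_internal(monomer_conf, e, rng)
        assert set(p.trial_coords) == {43}

    def test_bond_angle_volume_element(self, chain4):
        rng = np.random.default_rng(2)
        conf = chain4.configuration
        e = [x for x in chain4.plan if x.move_class == "bond_angle"][0]
        p = propose_internal(conf, e, rng)
        assert p.feasible
        pts = conf.coords
        a, par, g = e.atom, e.parent, e.grandparent

        def ang(c):
            u = c[a] - c[par]
            v = c[g] - c[par]
            return np.arccos(
                u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            )

        c2 = conf.copy()
        for at, x in p.trial_coords.items():
            c2.coords[at] = x
        expected = np.sin(ang(c2.coords)) / np.sin(ang(pts))
        assert p.jacobian_ratio == pytest.approx(expected, rel=1e-9)

    def test_bond_angle_to_straight_infeasible(self, chain4):
        rng = np.random.default_rng(3)
        conf = chain4.configuration
        e = [x for x in chain4.plan if x.move_class == "bond_angle"][0]
        # force a proposal that would exceed 180 degrees
        big = e.max_step
        e2 = type(e)(
            e.dof_id, e.move_class, e.atom, np.deg2rad(200.0),
            parent=e.parent, grandparent=e.grandparent, subtree=e.subtree,
        )
        results = [
            propose_internal(conf, e2, np.random.default_rng(s)).feasible
            for s in range(40)
        ]
        assert not all(results)


class TestJacobian:
    def test_breakage_analytic_vs_finite_difference(self, chain5):
        rng = np.random.default_rng(4)
        top, conf = chain5.topology, chain5.configuration
        e = [x for x in chain5.plan if x.move_class == "breakage"
             and x.atom == 2][0]
        checked = 0
        while checked < 10:
            p = propose_breakage_move(conf, e, top, rng, max_step=0.25)
            if not p.feasible:
                continue
            fd = breakage_jacobian_fd(conf, e, top, p.trial_coords)
            assert p.jacobian_ratio == pytest.approx(fd, rel=1e-6)
            checked += 1

    def test_identity_and_crankshaft_unity(self, chain4):
        rng = np.random.default_rng(5)
        e = [x for x in chain4.plan if x.move_class == "breakage"][0]
        p = propose_breakage_move(
            chain4.configuration, e, chain4.topology, rng, max_step=0.0
        )
        assert p.jacobian_ratio == pytest.approx(1.0)
        ec = [x for x in chain4.plan if x.move_class == "crankshaft"][0]
        pc = propose_crankshaft(chain4.configuration, ec, rng)
        assert pc.jacobian_ratio == 1.0


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        p = MoveProposal("crankshaft", delta_E=-3.0)
        assert all(metropolis_accept(p, 323.0, rng) for _ in range(200))

    def test_half_acceptance_at_kT_ln2(self):
        rng = np.random.default_rng(1)
        T = 323.0
        p = MoveProposal("crankshaft", delta_E=KB * T * np.log(2.0))
        n = 100_000
        acc = sum(metropolis_accept(p, T, rng) for _ in range(n)) / n
        assert acc == pytest.approx(0.5, abs=0.01)

    def test_jacobian_ratio_enters_acceptance(self):
        rng = np.random.default_rng(2)
        p = MoveProposal("breakage", delta_E=0.0, jacobian_ratio=0.5)
        n = 100_000
        acc = sum(metropolis_accept(p, 323.0, rng) for _ in range(n)) / n
        assert acc == pytest.approx(0.5, abs=0.01)

    def test_infeasible_always_rejected(self):
        rng = np.random.default_rng(3)
        p = MoveProposal.infeasible("breakage")
        assert not any(metropolis_accept(p, 323.0, rng) for _ in range(100))

    def test_non_finite_delta_rejected(self):
        rng = np.random.default_rng(4)
        p = MoveProposal("crankshaft", delta_E=np.inf)
        assert not metropolis_accept(p, 323.0, rng)


class TestVolumeMove:
    def test_identity_scale(self, chain4):
        conf = chain4.configuration.copy()
        conf.box = 30.0
        conf.periodic_dims = (0, 1)
        rng = np.random.default_rng(0)
        p = propose_volume_move(conf, chain4.topology, 0.0, rng)
        assert p.delta_V == pytest.approx(0.0)
        assert np.allclose(p.full_coords, conf.coords)

    def test_rigid_molecule_scaling(self, dppc_ff):
        from lipidmc.model import topology_from_forcefield, build_bilayer_start

        top = topology_from_forcefield(dppc_ff, 2)
        from lipidmc.model import Configuration, build_template_coords
        t = build_template_coords(dppc_ff)
        coords = np.concatenate([t, t + np.array([20.0, 0, 0])])
        conf = Configuration(coords, box=60.0, periodic_dims=(0, 1))
        rng = np.random.default_rng(1)
        # force a known expansion by drawing until scale > 1
        p = propose_volume_move(conf, top, 0.3, rng)
        scale = (1.0 + p.delta_V / conf.volume()) ** (1.0 / 3.0)
        coms0 = molecule_centers_of_mass(conf.coords, top)
        coms1 = molecule_centers_of_mass(p.full_coords, top)
        sep0 = np.linalg.norm(coms0[1] - coms0[0])
        sep1 = np.linalg.norm(coms1[1] - coms1[0])
        assert sep1 / sep0 == pytest.approx(scale, rel=1e-10)
        # intramolecular distances untouched
        d0 = np.linalg.norm(conf.coords[5] - conf.coords[40])
        d1 = np.linalg.norm(p.full_coords[5] - p.full_coords[40])
        assert d1 == pytest.approx(d0, abs=1e-12)
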