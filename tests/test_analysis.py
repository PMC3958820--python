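"""Observable estimators against closed-form and constructed oracles."""

import numpy as np
import pytest

from lipidmc.analysis import (
    area_per_lipid,
    compressibility,
    covariance_matrix,
    electron_density_profile,
    fit_energy_histogram,
    free_energy,
    heat_capacity,
    msd,
    msd_brute_force,
    msd_curve,
    pn_angles,
    pn_vector_distribution,
    profile_integral,
    schlitter_entropy,
    torsion_distribution,
    torsion_atoms,
)
from lipidmc.constants import (
    KB,
    KCAL_PER_MOL_A2_TO_MN_PER_M,
    SCHLITTER_PREFACTOR,
)
from lipidmc.errors import AnalysisError
from lipidmc.model import topology_from_forcefield


class TestEnergyHistogram:
    def test_gaussian_fit_recovers_parameters(self):
        # synthetic draws at the scale of a one-lipid equilibrium energy series
        rng = np.random.default_rng(0)
        series = rng.normal(10.26, 5.71, 1_000_000)
        fit = fit_energy_histogram(series)
        assert fit.mean == pytest.approx(10.26, abs=0.02)
        assert fit.sd == pytest.approx(5.71, abs=0.02)

    def test_degenerate_series_rejected(self):
        with pytest.raises(AnalysisError, match="zero variance"):
            fit_energy_histogram(np.full(5000, 3.0))

    def test_heat_capacity_quadratic_in_sigma(self):
        rng = np.random.default_rng(1)
        f1 = fit_energy_histogram(rng.normal(0.0, 2.0, 200_000))
        f2 = fit_energy_histogram(rng.normal(0.0, 4.0, 200_000))
        c1 = heat_capacity(f1, 323.0)
        c2 = heat_capacity(f2, 323.0)
        assert c2 / c1 == pytest.approx(4.0, rel=0.05)
        assert c1 == pytest.approx(f1.sd**2 / (KB * 323.0**2), rel=1e-12)


class TestSchlitterEntropy:
    def test_identical_frames_zero_entropy(self):
        frames = np.tile(np.arange(12.0).reshape(4, 3), (5, 1, 1))
        with pytest.raises(AnalysisError):
            covariance_matrix(frames[:1])
        cov = covariance_matrix(frames)
        assert np.allclose(cov, 0.0)
        s = schlitter_entropy(cov, np.ones(4) * 12.0, 323.0)
        assert s == 0.0

    def test_one_dimensional_closed_form(self):
        # 1 atom fluctuating along x only: S -> (kB/2) ln(1 + kB T e^2 m s^2/hbar^2)
        rng = np.random.default_rng(2)
        sigma = 0.4       # Å
        mass = 14.0       # amu
        T = 323.0
        n = 100_000
        frames = np.zeros((n, 1, 3))
        frames[:, 0, 0] = rng.normal(0.0, sigma, n)
        cov = covariance_matrix(frames)
        s = schlitter_entropy(cov, np.array([mass]), T)
        exact = 0.5 * KB * np.log(1.0 + SCHLITTER_PREFACTOR * T * mass * sigma**2)
        assert s == pytest.approx(exact, rel=0.01)

    def test_free_energy_identity(self):
        assert free_energy(10.0, 0.02, 323.0) == pytest.approx(10.0 - 323.0 * 0.02)

    def test_rigid_rotation_invariance_with_superposition(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1.0, (200, 5, 3))
        theta = 1.1
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        rotated = base @ rot.T
        masses = np.full(5, 14.0)
        s1 = schlitter_entropy(
            covariance_matrix(base, superpose=True), masses, 300.0
        )
        s2 = schlitter_entropy(
            covariance_matrix(rotated, superpose=True), masses, 300.0
        )
        assert s1 == pytest.approx(s2, rel=1e-6)


class TestTorsions:
    def test_start_frame_is_delta_like(self, dppc_topology, monomer_conf):
        frames = monomer_conf.coords[None, :, :]
        centers, occ = torsion_distribution(frames, dppc_topology, "alpha4")
        assert occ.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.max(occ) == 100.0      # a single occupied bin

    def test_two_state_series(self, dppc_topology, monomer_conf):
        from lipidmc.forcefield import EnergyModel
        from lipidmc.moves import rotate_about_axis

        # frames with the alpha6 methyl torsion at +60/-60 in equal numbers
        quad = np.array([torsion_atoms("alpha6")])
        base = monomer_conf.coords
        phi0 = np.rad2deg(EnergyModel.dihedrals(base, quad)[0])
        frames = []
        for target in (60.0, -60.0):
            f = base.copy()
            f[quad[0, 0]] = rotate_about_axis(
                base[quad[0, 0]], base[quad[0, 1]],
                base[quad[0, 1]] - base[quad[0, 2]],
                np.deg2rad(target - phi0),
            )
            got = np.rad2deg(EnergyModel.dihedrals(f, quad)[0])
            if abs((got - target + 180) % 360 - 180) > 1e-6:
                f[quad[0, 0]] = rotate_about_axis(
                    base[quad[0, 0]], base[quad[0, 1]],
                    base[quad[0, 1]] - base[quad[0, 2]],
                    np.deg2rad(phi0 - target),
                )
            for _ in range(10):
                frames.append(f)
        frames = np.array(frames)
        centers, occ = torsion_distribution(frames, dppc_topology, "alpha6")
        assert occ.sum() == pytest.approx(100.0, abs=1e-9)
        # two equal peaks at +/-60 degrees
        peaks = centers[occ > 0]
        assert len(peaks) == 2
        assert occ[occ > 0] == pytest.approx([50.0, 50.0])
        assert np.allclose(np.sort(np.abs(peaks)), [57.5, 57.5], atol=5)

    def test_uniform_random_torsions_flat(self):
        # against the multinomial null: a uniform sample puts ~equal mass in
        # every 5-degree bin
        rng = np.random.default_rng(4)
        vals = rng.uniform(-180, 180, 500_000)
        counts, _ = np.histogram(vals, bins=np.arange(-180, 185, 5))
        occ = 100 * counts / counts.sum()
        assert np.all(np.abs(occ - 100 / 72) < 0.2)

    def test_unknown_torsion_lists_names(self, dppc_topology, monomer_conf):
        with pytest.raises(AnalysisError, match="alpha1"):
            torsion_distribution(
                monomer_conf.coords[None], dppc_topology, "gamma9"
            )


class TestElectronDensity:
    def test_single_atom_integrates_to_electron_count(self, dppc_ff):
        # one oxygen-like atom (8 electrons) at z = 0
        from lipidmc.io import FixtureSpec, generate_fixture

        fix = generate_fixture(
            FixtureSpec(kind="ideal_gas", n_molecules=1, box=30.0, seed=0)
        )
        frames = np.zeros((1, 1, 3))
        prof = electron_density_profile(
            frames, [30.0], fix.topology, center=False
        )
        total = fix.topology.electron_counts().sum()
        assert profile_integral(prof) == pytest.approx(total, rel=1e-6)
        k = np.argmax(prof.density)
        assert abs(prof.z_grid[k]) < 0.3

    def test_two_slabs_head_to_head_distance(self, dppc_ff):
        top = topology_from_forcefield(dppc_ff, 2)
        frames = np.zeros((1, 100, 3))
        frames[0, :50, 2] = 18.0
        frames[0, 50:, 2] = -18.0
        prof = electron_density_profile(
            frames, [40.0], top, headgroup_band=(10.0, 30.0)
        )
        assert prof.d_hh == pytest.approx(36.0, abs=0.5)

    def test_normalization_every_frame(self, dppc_ff):
        from lipidmc.model import build_bilayer_start

        top = topology_from_forcefield(dppc_ff, 8)
        conf = build_bilayer_start(top, dppc_ff, 4, 10.1, seed=5)
        total = top.electron_counts().sum()
        for shift in (0.0, 3.7):
            frame = conf.coords[None] + np.array([0, 0, shift])
            prof = electron_density_profile(frame, [conf.box], top)
            assert profile_integral(prof) == pytest.approx(total, rel=1e-6)


class TestPNVector:
    def test_cardinal_orientations(self, dppc_ff):
        top = topology_from_forcefield(dppc_ff, 1)
        frames = np.zeros((1, 50, 3))
        # place N (index 0) straight above P (index 4)
        frames[0, 0] = [0, 0, 3.0]
        frames[0, 4] = [0, 0, 0.0]
        assert pn_angles(frames, top)[0, 0] == pytest.approx(0.0)
        frames[0, 0] = [3.0, 0, 0.0]
        assert pn_angles(frames, top)[0, 0] == pytest.approx(90.0)

    def test_isotropic_null_is_sine_weighted(self, dppc_ff):
        top = topology_from_forcefield(dppc_ff, 1)
        rng = np.random.default_rng(5)
        n = 200_000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        frames = np.zeros((n, 50, 3))
        frames[:, 0] = 3.0 * v
        centers, occ = pn_vector_distribution(frames, top, bin_width=10.0)
        expected = 100.0 * (
            np.cos(np.deg2rad(centers - 5.0)) - np.cos(np.deg2rad(centers + 5.0))
        ) / 2.0
        assert np.max(np.abs(occ - expected)) < 0.3


class TestAreaAndCompressibility:
    def test_constant_box_area_per_lipid(self):
        series = np.full(50, 400.0)          # 20x20 Å, 4 lipids per leaflet
        apl = area_per_lipid(series, 4)
        assert np.allclose(apl, 1.0)         # nm^2

    def test_known_moments_oracle(self):
        rng = np.random.default_rng(6)
        mean, sd = 3200.0, 40.0
        series = rng.normal(mean, sd, 400_000)
        ka = compressibility(series, 323.0)
        exact = (
            KB * 323.0 * series.mean() / series.var()
            * KCAL_PER_MOL_A2_TO_MN_PER_M
        )
        assert ka == pytest.approx(exact, rel=1e-12)

    def test_zero_variance_capped(self):
        with pytest.warns(UserWarning, match="capped"):
            ka = compressibility(np.full(100, 3200.0), 323.0)
        assert ka == pytest.approx(1.0e6)

    def test_monomer_trajectory_rejected(self):
        with pytest.raises(AnalysisError, match="bilayer"):
            area_per_lipid(np.full(10, np.nan), 4)


class TestMSD:
    def test_static_positions(self):
        com = np.tile(np.array([[1.0, 2.0, 3.0]]), (100, 1, 1))
        lags, curve = msd_curve(com)
        assert np.allclose(curve, 0.0, atol=1e-12)
        res = msd(com, fit_window=(10, 50))
        assert res.d_apparent == pytest.approx(0.0, abs=1e-12)

    def test_ballistic_drift(self):
        v = np.array([0.3, -0.2])
        t = np.arange(200)
        com = np.zeros((200, 1, 3))
        com[:, 0, :2] = t[:, None] * v
        lags, curve = msd_curve(com)
        assert np.allclose(curve, (v @ v) * lags**2, rtol=1e-10, atol=1e-8)

    def test_fft_equals_brute_force(self):
        rng = np.random.default_rng(7)
        com = np.cumsum(rng.normal(0, 0.5, (1000, 3, 3)), axis=0)
        lags_f, fast = msd_curve(com)
        lags_b, brute = msd_brute_force(com)
        assert np.allclose(fast, brute, rtol=1e-10, atol=1e-10)

    def test_random_walk_recovers_diffusion_coefficient(self):
        rng = np.random.default_rng(8)
        d0 = 0.17        # Å^2/step
        n_steps, n_walkers = 10_000, 64
        steps = rng.normal(0.0, np.sqrt(2 * d0), (n_steps, n_walkers, 2))
        com = np.zeros((n_steps, n_walkers, 3))
        com[:, :, :2] = np.cumsum(steps, axis=0)
        res = msd(com, fit_window=(1, 100))
        assert res.d_apparent == pytest.approx(d0, rel=0.05)

    def test_short_fit_window_rejected(self):
        com = np.zeros((50, 1, 3))
        with pytest.raises(AnalysisError, match="3 lags"):
            msd(com, fit_window=(10, 12))
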