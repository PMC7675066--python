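"""Phantom voxelization, forward RF model, structured noise, full-scan simulation."""

import numpy as np
import pytest
from scipy.ndimage import label

import fanpat as fp


class TestVoxelizePhantom:
    def test_empty_phantom_is_background(self):
        grid = fp.VoxelGrid(origin=(0, 0, 0), spacing=0.1, shape=(8, 8, 8))
        vol = fp.voxelize_phantom(fp.PhantomModel(background_absorption=0.3), grid)
        assert np.all(vol == 0.3)

    def test_cylinder_volume_matches_analytic(self):
        grid = fp.VoxelGrid(origin=(-1.0, -1.0, -1.0), spacing=0.05, shape=(40, 40, 40))
        radius = 1.5 * grid.spacing
        # generic (non-lattice-aligned) axis avoids discretization resonance
        wire = ((-0.8, 0.013, 0.021), (0.8, 0.013, 0.021), radius, 1.0)
        vol = fp.voxelize_phantom(fp.PhantomModel(wires=(wire,)), grid)
        n = int((vol > 0).sum())
        analytic = np.pi * radius**2 * 1.6 / grid.spacing**3
        assert abs(n - analytic) / analytic < 0.15

    def test_separated_wires_form_disjoint_components(self):
        grid = fp.VoxelGrid(origin=(-1.0, -1.0, -1.0), spacing=0.05, shape=(40, 40, 40))
        w1 = ((-0.8, -0.5, 0.0), (0.8, -0.5, 0.0), 0.08, 1.0)
        w2 = ((-0.8, 0.5, 0.0), (0.8, 0.5, 0.0), 0.08, 1.0)
        vol = fp.voxelize_phantom(fp.PhantomModel(wires=(w1, w2)), grid)
        _, n_components = label(vol > 0)
        assert n_components == 2

    def test_outside_wire_warns(self):
        grid = fp.VoxelGrid(origin=(0, 0, 0), spacing=0.1, shape=(4, 4, 4))
        wire = ((10.0, 10.0, 10.0), (11.0, 10.0, 10.0), 0.05, 1.0)
        with pytest.warns(UserWarning):
            fp.voxelize_phantom(fp.PhantomModel(wires=(wire,)), grid)


@pytest.fixture(scope="module")
def single_point_setup():
    geom = fp.build_array()
    plan = fp.AcquisitionPlan(n_angles=1, n_samples=2080)
    grid = fp.VoxelGrid(origin=(6.0, 0.0, 6.0), spacing=0.05, shape=(1, 1, 1))
    fluence = fp.FluenceVolume(grid=grid, pose_angle=0.0, values=np.ones((1, 1, 1)))
    return geom, plan, grid, fluence


class TestForwardRF:
    def test_point_absorber_peak_at_geometric_delay(self, single_point_setup):
        geom, plan, grid, fluence = single_point_setup
        plane = fp.forward_rf(
            np.ones((1, 1, 1)), geom, plan, fluence, pulse=fp.gaussian_pulse(plan.sampling_rate)
        )
        src = np.array(grid.origin)
        for e in (0, 100, 383):  # hand-picked elements across the arc
            d = np.linalg.norm(geom.element_positions[e] - src)
            expected = round(d / plan.sound_speed_cm * plan.sampling_rate)
            assert abs(int(np.argmax(plane.samples[e])) - expected) <= 1

    def test_no_absorption_gives_silence(self, single_point_setup):
        geom, plan, grid, fluence = single_point_setup
        plane = fp.forward_rf(np.zeros((1, 1, 1)), geom, plan, fluence)
        assert np.all(plane.samples == 0)

    def test_linear_in_fluence(self, single_point_setup):
        geom, plan, grid, fluence = single_point_setup
        p1 = fp.forward_rf(np.ones((1, 1, 1)), geom, plan, fluence)
        doubled = fp.FluenceVolume(grid=grid, pose_angle=0.0, values=2 * fluence.values)
        p2 = fp.forward_rf(np.ones((1, 1, 1)), geom, plan, doubled)
        assert np.allclose(p2.samples, 2 * p1.samples, rtol=1e-12)

    def test_superposition_over_phantoms(self, rng):
        geom = fp.build_array(16, 4.0, 12.0)
        plan = fp.AcquisitionPlan(n_angles=1, n_samples=2080)
        grid = fp.VoxelGrid(origin=(5.8, -0.2, 5.8), spacing=0.1, shape=(5, 5, 5))
        fl = fp.FluenceVolume(grid=grid, pose_angle=0.0, values=np.ones(grid.shape))
        va = rng.random(grid.shape) * (rng.random(grid.shape) > 0.7)
        vb = rng.random(grid.shape) * (rng.random(grid.shape) > 0.7)
        pa = fp.forward_rf(va, geom, plan, fl)
        pb = fp.forward_rf(vb, geom, plan, fl)
        pab = fp.forward_rf(va + vb, geom, plan, fl)
        assert np.allclose(pab.samples, pa.samples + pb.samples, atol=1e-9)

    def test_strict_coverage_check_raises(self):
        geom = fp.build_array()
        plan = fp.AcquisitionPlan(n_angles=1, n_samples=64)  # window far too short
        grid = fp.VoxelGrid(origin=(6.0, 0.0, 6.0), spacing=0.05, shape=(1, 1, 1))
        fl = fp.FluenceVolume(grid=grid, pose_angle=0.0, values=np.ones((1, 1, 1)))
        with pytest.raises(ValueError):
            fp.forward_rf(np.ones((1, 1, 1)), geom, plan, fl, require_coverage=True)


class TestAddNoise:
    def _plane(self, rng):
        return fp.RFPlane(pose_angle=0.0, samples=rng.normal(size=(32, 256)))

    def test_all_zero_model_is_identity(self, rng):
        plane = self._plane(rng)
        quiet = fp.NoiseModel(band_count=0, band_amplitude=0.0, white_sigma=0.0, energy_jitter=0.0)
        out = fp.add_noise(plane, quiet)
        assert np.array_equal(out.samples, plane.samples)
        assert out.pulse_energy == plane.pulse_energy

    def test_single_band_on_silence_is_rank_one(self):
        plane = fp.RFPlane(pose_angle=0.0, samples=np.zeros((32, 256)))
        nm = fp.NoiseModel(band_count=1, band_rank=1, band_amplitude=1.0,
                           white_sigma=0.0, energy_jitter=0.0, seed=3)
        out = fp.add_noise(plane, nm)
        s = np.linalg.svd(out.samples, compute_uv=False)
        assert s[0] > 0
        assert s[1] < 1e-10 * s[0]

    def test_seeded_noise_is_bitwise_reproducible(self, rng):
        plane = self._plane(rng)
        nm = fp.NoiseModel(seed=11)
        a = fp.add_noise(plane, nm)
        b = fp.add_noise(plane, nm)
        assert np.array_equal(a.samples, b.samples)
        assert a.pulse_energy == b.pulse_energy


class TestSimulateScan:
    @pytest.fixture(scope="class")
    def small(self):
        geom = fp.build_array(64, 11.5, 12.0)
        plan = fp.AcquisitionPlan(n_angles=4, angular_step=90.0, n_samples=4000)
        illum = fp.default_illuminator(geom)
        optics = fp.MILK_MIX_OPTICS
        return geom, plan, illum, optics

    def test_single_pose_matches_direct_forward(self, small):
        geom, _, illum, optics = small
        plan1 = fp.AcquisitionPlan(n_angles=1, n_samples=4000)
        wire = ((6.0, -0.05, 6.0), (6.0, 0.05, 6.0), 0.02, 1.0)
        phantom = fp.PhantomModel(wires=(wire,))
        planes = fp.simulate_scan(phantom, geom, illum, plan1, optics)
        pts, strength = fp.phantom_point_sources(phantom, 0.05 / 4)
        psi = fp.fluence_at_points(pts, illum, optics)
        from fanpat.simulate import _forward_points

        direct = _forward_points(pts, strength, psi, geom, plan1, 0.0)
        assert np.allclose(planes[0].samples, direct.samples, atol=1e-12)

    def test_on_axis_wire_gives_identical_planes_at_all_poses(self, small):
        geom, plan, illum, optics = small
        phantom = fp.PhantomModel(wires=(((0, 0, 2.0), (0, 0, 2.5), 0.02, 1.0),))
        planes = fp.simulate_scan(phantom, geom, illum, plan, optics)
        ref = planes[0].samples
        scale = np.abs(ref).max()
        for p in planes[1:]:
            assert np.allclose(p.samples, ref, atol=1e-6 * scale)

    def test_pose_angles_follow_the_plan(self, small):
        geom, _, illum, optics = small
        plan = fp.AcquisitionPlan(n_angles=5, angular_step=1.8, n_samples=4000)
        planes = fp.simulate_scan(fp.PhantomModel(), geom, illum, plan, optics)
        assert [p.pose_angle for p in planes] == [0.0, 1.8, 3.6, 5.4, 7.2]

    def test_scan_reproducible_for_fixed_seed(self, small):
        geom, plan, illum, optics = small
        phantom = fp.PhantomModel(wires=(((6.0, -0.3, 6.0), (6.0, 0.3, 6.0), 0.02, 1.0),))
        nm = fp.NoiseModel(seed=5)
        a = fp.simulate_scan(phantom, geom, illum, plan, optics, noise=nm)
        b = fp.simulate_scan(phantom, geom, illum, plan, optics, noise=nm)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.samples, pb.samples)
            assert pa.pulse_energy == pb.pulse_energy
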