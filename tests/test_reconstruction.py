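"""Water-equivalent depth, point/volume reconstruction and DVH metrics."""

import numpy as np
import pytest

import vmatqa as vq
from vmatqa.reconstruction import (
    RayMissError,
    compute_dvh,
    d50_percent_difference,
    reconstruct_point,
    reconstruct_volume,
    trace_ray,
    water_equivalent_depth,
)


def water_box(voxel=5.0, size=200.0):
    return vq.make_phantom("homogeneous_water", size_mm=(size, size, size), voxel_mm=voxel)


class TestWaterEquivalentDepth:
    def test_homogeneous_water_equals_geometric(self):
        ph = water_box()
        ray = trace_ray(ph, (0.0, 0.0, -50.0))  # front face at z = -100
        assert water_equivalent_depth(ray) == pytest.approx(50.0, rel=1e-3)
        assert ray.geom_depth_mm == pytest.approx(50.0, rel=1e-3)

    def test_uniform_half_density(self):
        ph = water_box()
        ph.density[:] = 0.5
        ray = trace_ray(ph, (0.0, 0.0, -20.0))  # geometric depth 80
        assert water_equivalent_depth(ray) == pytest.approx(40.0, rel=1e-3)

    def test_two_layer_mean_density(self):
        """First 20 mm water, next 20 mm density 0.25: depth 40 -> 25 mm."""
        ph = water_box()
        zc = ph.z
        ph.density[(zc >= -80) & (zc < -60), :, :] = 0.25
        ray = trace_ray(ph, (0.0, 0.0, -60.0))
        assert water_equivalent_depth(ray) == pytest.approx(25.0, rel=1e-3)

    def test_ray_missing_phantom_raises(self):
        ph = vq.make_phantom("cylinder", radius_mm=50.0, voxel_mm=5.0, size_mm=(110, 200, 110))
        with pytest.raises(RayMissError):
            trace_ray(ph, (200.0, 0.0, 0.0))


class TestReconstructPoint:
    def test_identity_case(self, beam):
        assert reconstruct_point(2.5, 50.0, 50.0, 900.0, 900.0, beam) == pytest.approx(2.5)

    def test_inverse_square_term(self, flat_tpr_beam):
        v = reconstruct_point(1.0, 50.0, 50.0, 500.0, 1000.0, flat_tpr_beam)
        assert v == pytest.approx(0.25, rel=1e-12)

    def test_exponential_tpr_closed_form(self):
        mu = 0.005
        beam = vq.make_beam_model(
            pdd_fn=lambda d: np.exp(-mu * np.asarray(d, dtype=float))
            * ((900.0 + 15.0) / (900.0 + np.asarray(d, dtype=float))) ** 2
        )
        v = reconstruct_point(1.0, 100.0, 50.0, 1000.0, 1000.0, beam)
        assert v == pytest.approx(np.exp(0.25), rel=1e-9)

    def test_invalid_distances_rejected(self, beam):
        with pytest.raises(ValueError):
            reconstruct_point(1.0, 50.0, 50.0, 0.0, 1000.0, beam)

    def test_heterogeneity_raises_downstream_dose(self, beam):
        """A low-density slab upstream shortens the water-equivalent depth,
        which for a decreasing TPR strictly increases the reconstructed
        dose."""
        water = water_box()
        thorax = vq.make_phantom(
            "thorax_like", size_mm=(200, 200, 200), voxel_mm=5.0,
            insert_density=0.25, insert_z_mm=(-60, -20),
        )
        point = (0.0, 0.0, 40.0)
        z_w = water_equivalent_depth(trace_ray(water, point))
        z_h = water_equivalent_depth(trace_ray(thorax, point))
        assert z_h < z_w
        d_w = reconstruct_point(1.0, 100.0, z_w, 1000.0, 1040.0, beam)
        d_h = reconstruct_point(1.0, 100.0, z_h, 1000.0, 1040.0, beam)
        assert d_h > d_w


@pytest.fixture(scope="module")
def small_recon_setup(modulated_dose):
    d1500 = vq.build_array("d1500")
    measured = vq.acquire_coalesced(modulated_dose, d1500)
    # odd voxel count puts a voxel plane exactly at the detector plane z=0
    phantom = vq.make_phantom("homogeneous_water", size_mm=(310, 310, 150), voxel_mm=10.0)
    return measured, phantom


class TestReconstructVolume:
    def test_linear_in_measured_dose(self, small_recon_setup, beam):
        measured, phantom = small_recon_setup
        rec1 = reconstruct_volume(measured, phantom, beam)
        scaled = vq.MeasuredMap(
            positions=measured.positions,
            values=3.0 * measured.values,
            shift_mm=measured.shift_mm,
            array_model=measured.array_model,
        )
        rec3 = reconstruct_volume(scaled, phantom, beam)
        assert np.allclose(rec3.values, 3.0 * rec1.values, rtol=1e-9)

    def test_homogeneous_identity_at_detector_plane(self, small_recon_setup, beam):
        """On a water phantom a voxel at the detector's own depth and
        distance reproduces the measured dose."""
        measured, phantom = small_recon_setup
        rec = reconstruct_volume(measured, phantom, beam)
        iz = int(np.argmin(np.abs(phantom.z)))
        assert abs(phantom.z[iz]) < 1e-9
        # voxel centres that coincide with chamber positions
        plane = rec.values[iz]
        hits = 0
        for k, (px, py) in enumerate(measured.positions):
            ix = np.where(np.isclose(phantom.x, px))[0]
            iy = np.where(np.isclose(phantom.y, py))[0]
            if ix.size and iy.size and plane[iy[0], ix[0]] > 0:
                assert plane[iy[0], ix[0]] == pytest.approx(measured.values[k], rel=1e-9)
                hits += 1
        assert hits > 100

    def test_uniform_map_flat_tpr_pure_inverse_square(self, flat_tpr_beam):
        """A uniform planar map on water with flat TPR reconstructs to the
        inverse-square law alone."""
        d729 = vq.build_array("d729")
        n = 321
        uniform = vq.GroundTruthDose(np.full((n, n), 2.0), (-160, -160), (1.0, 1.0))
        measured = vq.sample(uniform, d729)
        phantom = vq.make_phantom("homogeneous_water", size_mm=(310, 310, 150), voxel_mm=10.0)
        rec = reconstruct_volume(measured, phantom, flat_tpr_beam, n_depth_samples=64)
        fz = phantom.focus[2]
        for iz, zv in enumerate(phantom.z):
            core = rec.values[iz, 12:19, 12:19]  # central voxels, inside the hull
            expected = 2.0 * ((0.0 - fz) / (zv - fz)) ** 2
            assert np.allclose(core, expected, rtol=1e-9)

    def test_denser_sampling_does_not_worsen_recovery(self, flat_tpr_beam):
        """Reconstruction from the coalesced 1500 map recovers a smooth
        analytic dose at least as well as from the sparse 729 SA map."""
        n = 321
        x = np.linspace(-160, 160, n)
        xx, yy = np.meshgrid(x, x)
        smooth = vq.GroundTruthDose(
            1.0 + np.exp(-(xx**2 + yy**2) / (2 * 45.0**2)), (-160, -160), (1.0, 1.0)
        )
        phantom = vq.make_phantom("homogeneous_water", size_mm=(310, 310, 150), voxel_mm=10.0)
        iz = int(np.argmin(np.abs(phantom.z)))
        xg, yg = np.meshgrid(phantom.x, phantom.y)
        analytic = 1.0 + np.exp(-(xg**2 + yg**2) / (2 * 45.0**2))
        core = (np.abs(xg) < 100) & (np.abs(yg) < 100)

        errs = {}
        for model, proc in (("d729", "sa"), ("d1500", "coalescence")):
            arr = vq.build_array(model)
            mm = vq.sample(smooth, arr) if proc == "sa" else vq.acquire_coalesced(smooth, arr)
            rec = reconstruct_volume(mm, phantom, flat_tpr_beam)
            errs[model] = np.max(np.abs(rec.values[iz][core] - analytic[core]))
        assert errs["d1500"] <= errs["d729"] + 1e-9

    def test_empty_map_rejected(self, beam):
        phantom = water_box()
        empty = vq.MeasuredMap(np.empty((0, 2)), np.empty(0), (0, 0), "d729")
        with pytest.raises(ValueError):
            reconstruct_volume(empty, phantom, beam)


class TestDvh:
    def test_uniform_dose_d50(self):
        vals = np.full((4, 5, 5), 7.0)
        mask = np.ones_like(vals, bool)
        dvh = compute_dvh(vals, mask)
        assert dvh.d50 == pytest.approx(7.0, rel=1e-3)

    def test_linear_gradient_d50_is_half_max(self):
        vals = np.tile(np.linspace(0, 10, 101), (3, 3, 1)).reshape(3, 3, 101)
        mask = np.ones_like(vals, bool)
        dvh = compute_dvh(vals, mask)
        assert dvh.d50 == pytest.approx(5.0, abs=0.1)

    def test_dvh_monotone_non_increasing(self):
        rng = np.random.default_rng(3)
        vals = rng.random((5, 6, 7)) * 4
        dvh = compute_dvh(vals, np.ones_like(vals, bool))
        assert np.all(np.diff(dvh.volume_fraction) <= 1e-12)

    def test_percent_difference(self):
        assert d50_percent_difference(5.0, 5.0) == 0.0
        assert d50_percent_difference(4.5, 5.0) == pytest.approx(10.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_dvh(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))
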