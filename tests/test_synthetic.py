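"""Dose-map generator, error injection, phantoms and beam model."""

import numpy as np
import pytest

import vmatqa as vq
from vmatqa.synthetic import DoseModelError

from conftest import open_square_spec


class TestGenerator:
    def test_open_field_tophat_limit(self):
        """Zero penumbra: uniform plateau inside the aperture, zero outside."""
        spec = open_square_spec(half_mm=50.0, penumbra_mm=0.0, weight=1.0)
        dose = vq.generate_vmat_dosemap(spec, 0)
        x, y = dose.x, dose.y
        xx, yy = np.meshgrid(x, y)
        interior = (np.abs(xx) < 48) & (np.abs(yy) < 48)
        exterior = (np.abs(xx) > 52) | (np.abs(yy) > 52)
        assert np.allclose(dose.values[interior], 1.0)
        assert np.allclose(dose.values[exterior], 0.0)

    def test_determinism_same_seed(self):
        rng = np.random.default_rng(7)
        spec = vq.random_field_spec(rng, noise_sigma=0.01)
        a = vq.generate_vmat_dosemap(spec, 123)
        b = vq.generate_vmat_dosemap(spec, 123)
        assert np.array_equal(a.values, b.values)
        c = vq.generate_vmat_dosemap(spec, 124)
        assert not np.array_equal(a.values, c.values)

    def test_plateau_and_integral_scale_with_weight(self):
        """Weight w gives plateau w and a plane integral linear in w."""
        w = 1.7
        spec1 = open_square_spec(half_mm=40.0, penumbra_mm=2.0, weight=1.0)
        specw = open_square_spec(half_mm=40.0, penumbra_mm=2.0, weight=w)
        d1 = vq.generate_vmat_dosemap(spec1, 0)
        dw = vq.generate_vmat_dosemap(specw, 0)
        centre = dw.values[dw.values.shape[0] // 2, dw.values.shape[1] // 2]
        assert centre == pytest.approx(w, rel=1e-6)
        assert dw.values.sum() == pytest.approx(w * d1.values.sum(), rel=1e-12)

    def test_aperture_outside_grid_rejected(self):
        spec = open_square_spec(half_mm=50.0)
        with pytest.raises(DoseModelError):
            vq.generate_vmat_dosemap(spec, 0, half_extent_mm=40.0)

    def test_resolution_coarser_than_1mm_rejected(self):
        spec = open_square_spec()
        with pytest.raises(DoseModelError):
            vq.generate_vmat_dosemap(spec, 0, spacing_mm=2.0)

    @pytest.mark.parametrize("sigmas", [(0.5, 1.0, 2.0, 3.0, 5.0)])
    def test_penumbra_widens_edges_monotonically(self, sigmas):
        """The 20-80% edge width of a field profile grows with the penumbra."""
        widths = []
        for s in sigmas:
            spec = open_square_spec(half_mm=40.0, penumbra_mm=s)
            dose = vq.generate_vmat_dosemap(spec, 0)
            profile = dose.values[dose.values.shape[0] // 2]
            x = dose.x
            rising = (x < 0) & (x > -60)
            x20 = np.interp(0.2, profile[rising], x[rising])
            x80 = np.interp(0.8, profile[rising], x[rising])
            widths.append(x80 - x20)
        assert np.all(np.diff(widths) > 0)


class TestErrors:
    def test_mu_scale_on_grid(self):
        dose = vq.GroundTruthDose(np.full((30, 30), 1.0), (0, 0), (1, 1))
        out = vq.apply_error(dose, vq.ErrorSpec("MU_scale", 0.02))
        assert np.allclose(out.values, 1.020)

    def test_mu_scale_zero_is_identity(self):
        dose = vq.GroundTruthDose(np.random.default_rng(0).random((20, 20)), (0, 0), (1, 1))
        out = vq.apply_error(dose, vq.ErrorSpec("MU_scale", 0.0))
        assert np.array_equal(out.values, dose.values)

    def test_mu_scale_composition(self):
        """Scaling by a then b equals scaling by (1+a)(1+b)-1."""
        dose = vq.GroundTruthDose(np.random.default_rng(1).random((15, 15)), (0, 0), (1, 1))
        a, b = 0.02, -0.05
        seq = vq.apply_error(vq.apply_error(dose, vq.ErrorSpec("MU_scale", a)), vq.ErrorSpec("MU_scale", b))
        combined = vq.apply_error(dose, vq.ErrorSpec("MU_scale", (1 + a) * (1 + b) - 1))
        assert np.allclose(seq.values, combined.values, rtol=1e-12)

    def test_dlg_shift_moves_each_bank_half(self):
        """+1 mm leaf-gap widening retracts each bank edge by 0.5 mm."""
        spec = open_square_spec(half_mm=50.0)
        widened = vq.apply_error(spec, vq.ErrorSpec("DLG_shift", 1.0))
        base = spec.segments[0].openings
        out = widened.segments[0].openings
        open_pairs = base[:, 1] > base[:, 0]
        assert np.allclose(out[open_pairs, 0], base[open_pairs, 0] - 0.5)
        assert np.allclose(out[open_pairs, 1], base[open_pairs, 1] + 0.5)
        assert np.array_equal(out[~open_pairs], base[~open_pairs])

    def test_dlg_shift_needs_aperture_description(self):
        dose = vq.GroundTruthDose(np.ones((10, 10)), (0, 0), (1, 1))
        with pytest.raises(DoseModelError):
            vq.apply_error(dose, vq.ErrorSpec("DLG_shift", 1.0))

    def test_dlg_integral_monotone(self):
        """Plane-integrated dose is non-decreasing in the gap widening."""
        spec = open_square_spec(half_mm=40.0, penumbra_mm=2.0)
        integrals = []
        for mag in (0.0, 0.5, 1.0, 2.0):
            rendered = vq.apply_error(spec, vq.ErrorSpec("DLG_shift", mag), render=True)
            integrals.append(rendered.values.sum())
        assert np.all(np.diff(integrals) >= 0)

    def test_unknown_error_kind_rejected(self):
        with pytest.raises(DoseModelError):
            vq.ErrorSpec("gantry_sag", 1.0)


class TestPhantoms:
    def test_homogeneous_water(self):
        ph = vq.make_phantom("homogeneous_water")
        assert np.all(ph.density[ph.contour] == 1.0)

    def test_thorax_insert_density(self):
        ph = vq.make_phantom("thorax_like", insert_density=0.25, insert_z_mm=(-60, -20))
        zc = ph.z
        in_slab = (zc >= -60) & (zc < -20)
        assert np.all(ph.density[in_slab] == 0.25)
        assert np.all(ph.density[~in_slab] == 1.0)

    def test_cylinder_voxel_count_matches_area(self):
        """In-contour voxel count approximates the analytic cylinder volume."""
        r = 100.0
        ph = vq.make_phantom("cylinder", radius_mm=r, voxel_mm=2.0, size_mm=(210, 100, 210))
        ny = ph.density.shape[1]
        count = np.count_nonzero(ph.contour)
        expected = np.pi * r**2 * ny / (2.0**2)  # per-slice area in voxel units
        assert count == pytest.approx(expected, rel=0.02)

    def test_bad_kind_rejected(self):
        with pytest.raises(DoseModelError):
            vq.make_phantom("anthropomorphic")


class TestBeamModel:
    def test_tpr_unity_for_attenuation_free_beam(self, flat_tpr_beam):
        """A PDD falling only by inverse square has TPR of 1 at every depth."""
        d = np.linspace(0, 300, 50)
        assert np.allclose(flat_tpr_beam.tpr(d), 1.0, atol=1e-12)

    def test_tpr_ratio_identity(self, beam):
        for d in (5.0, 50.0, 212.3):
            assert float(beam.tpr(d)) / float(beam.tpr(d)) == 1.0

    def test_exponential_tpr_closed_form(self):
        """With inverse square divided out of the PDD, the TPR ratio between
        depths is the pure attenuation factor e^(-mu (d1 - d2))."""
        mu = 0.005
        beam = vq.make_beam_model(
            pdd_fn=lambda d: np.exp(-mu * np.asarray(d, dtype=float))
            * ((900.0 + 15.0) / (900.0 + np.asarray(d, dtype=float))) ** 2
        )
        d1, d2 = 130.0, 40.0
        ratio = float(beam.tpr(d1)) / float(beam.tpr(d2))
        assert ratio == pytest.approx(np.exp(-mu * (d1 - d2)), rel=1e-12)

    def test_negative_depth_rejected(self, beam):
        with pytest.raises(DoseModelError):
            beam.tpr(-1.0)

    def test_pdd_normalized_at_reference_depth(self, beam):
        assert float(beam.pdd_at(beam.d_ref_mm)) == pytest.approx(1.0)
        assert float(beam.tpr(beam.d_ref_mm)) == pytest.approx(1.0)

    def test_tpr_monotone_beyond_buildup(self, beam):
        d = np.linspace(20.0, 300.0, 200)
        assert np.all(np.diff(beam.tpr(d)) < 0)

    def test_tabulated_pdd(self):
        tab = [(0.0, 0.5), (15.0, 1.0), (100.0, 0.65), (300.0, 0.3)]
        beam = vq.make_beam_model(pdd_table=tab)
        assert float(beam.pdd_at(15.0)) == pytest.approx(1.0)
        # linear interpolation between table nodes
        assert float(beam.pdd_at(57.5)) == pytest.approx((1.0 + 0.65) / 2, rel=1e-12)
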