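"""Gamma-index kernel: identity, formula, oracle equivalence, invariances."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

import vmatqa as vq
from vmatqa.gamma import GammaCriteria, gamma_map, gamma_map_3d, pass_rate, profile_compare


def grid(values, spacing=1.0, origin=None):
    values = np.asarray(values, dtype=float)
    if origin is None:
        origin = (0.0, 0.0)
    return vq.GroundTruthDose(values, origin, (spacing, spacing))


def brute_force_gamma(reference, evaluated, dd_abs_global, dta, subgrid):
    """Independent oracle: exhaustive minimum over the whole interpolated
    evaluated grid (no search cap, no windowing)."""
    itp = RegularGridInterpolator(
        (evaluated.y, evaluated.x), evaluated.values, bounds_error=False, fill_value=np.nan
    )
    fy = np.arange(evaluated.y[0], evaluated.y[-1] + subgrid / 2, subgrid)
    fx = np.arange(evaluated.x[0], evaluated.x[-1] + subgrid / 2, subgrid)
    YY, XX = np.meshgrid(fy, fx, indexing="ij")
    F = itp(np.stack([YY.ravel(), XX.ravel()], axis=1)).reshape(YY.shape)
    out = np.full(reference.values.shape, np.nan)
    mask = reference.values >= 0.1 * reference.values.max()
    for iy, ix in zip(*np.nonzero(mask)):
        dref = reference.values[iy, ix]
        dist2 = (YY - reference.y[iy]) ** 2 + (XX - reference.x[ix]) ** 2
        g2 = dist2 / dta**2 + (F - dref) ** 2 / dd_abs_global**2
        out[iy, ix] = np.sqrt(np.nanmin(g2))
    return out, mask


class TestGammaMap:
    def test_identity_is_zero_everywhere(self, modulated_dose):
        ref = modulated_dose.decimate(5)
        res = gamma_map(ref, ref, GammaCriteria(3.0, 2.0))
        assert np.nanmax(res.gamma) < 1e-9
        assert pass_rate(res) == 100.0

    def test_pure_dose_difference_formula(self):
        """Uniform 100 vs uniform 103 at 3%/2 mm global: gamma = 1 exactly."""
        ref = grid(np.full((20, 20), 100.0))
        ev = grid(np.full((20, 20), 103.0))
        res = gamma_map(ref, ev, GammaCriteria(3.0, 2.0))
        assert np.allclose(res.gamma[res.mask], 1.0, atol=1e-9)

    def test_matches_brute_force_oracle(self):
        """Windowed search equals an exhaustive fine-grid minimum search."""
        rng = np.random.default_rng(11)
        ref = grid(rng.random((20, 20)) * 100)
        ev = grid(np.clip(ref.values + rng.normal(0, 2.5, (20, 20)), 0, None))
        crit = GammaCriteria(3.0, 2.0, search_cap_mm=30.0)
        res = gamma_map(ref, ev, crit)
        oracle, mask = brute_force_gamma(ref, ev, 0.03 * ref.values.max(), 2.0, crit.subgrid)
        assert np.array_equal(mask, res.mask)
        assert np.nanmax(np.abs(res.gamma[mask] - oracle[mask])) < 1e-9

    def test_low_dose_threshold_mask(self):
        vals = np.ones((10, 10))
        vals[:5] = 0.05  # below 10% of max
        ref = grid(vals)
        res = gamma_map(ref, ref, GammaCriteria(3.0, 2.0))
        assert res.n_evaluated == 50
        assert np.all(np.isnan(res.gamma[:5]))

    def test_all_below_threshold_warns(self):
        ref = grid(np.zeros((5, 5)))
        with pytest.warns(UserWarning):
            res = gamma_map(ref, ref, GammaCriteria(3.0, 2.0))
        with pytest.raises(ValueError):
            pass_rate(res)

    def test_joint_rescaling_invariance(self, modulated_dose):
        """Global gamma is unchanged when both distributions are rescaled."""
        rng = np.random.default_rng(4)
        ref = modulated_dose.decimate(5)
        ev = modulated_dose.copy(
            values=np.clip(modulated_dose.values + rng.normal(0, 0.01, modulated_dose.values.shape), 0, None)
        )
        crit = GammaCriteria(3.0, 2.0)
        res1 = gamma_map(ref, ev, crit)
        res2 = gamma_map(ref.copy(values=5.0 * ref.values), ev.copy(values=5.0 * ev.values), crit)
        assert np.allclose(res1.gamma[res1.mask], res2.gamma[res2.mask], rtol=1e-9)

    def test_criteria_monotonicity(self, modulated_dose):
        """Loosening dose or distance tolerance never lowers the pass rate.

        The search cap and sub-grid are pinned so all four criteria share
        one candidate set, making the pointwise ordering exact.
        """
        rng = np.random.default_rng(9)
        ref = modulated_dose.decimate(5)
        ev = modulated_dose.copy(
            values=np.clip(modulated_dose.values + rng.normal(0, 0.015, modulated_dose.values.shape), 0, None)
        )
        rates = []
        for dd, dta in ((3, 2), (2, 2), (2, 1), (1, 1)):
            crit = GammaCriteria(dd, dta, search_cap_mm=6.0, subgrid_mm=0.25)
            rates.append(pass_rate(gamma_map(ref, ev, crit)))
        assert rates[0] >= rates[1] >= rates[2] >= rates[3]

    def test_local_at_least_global(self, modulated_dose):
        rng = np.random.default_rng(12)
        ref = modulated_dose.decimate(5)
        ev = modulated_dose.copy(
            values=np.clip(modulated_dose.values + rng.normal(0, 0.01, modulated_dose.values.shape), 0, None)
        )
        g = gamma_map(ref, ev, GammaCriteria(3.0, 2.0, normalization="global"))
        l = gamma_map(ref, ev, GammaCriteria(3.0, 2.0, normalization="local"))
        sel = g.mask & (ref.values < ref.values.max())
        assert np.all(l.gamma[sel] >= g.gamma[sel] - 1e-9)

    def test_subgrid_refinement_never_increases_gamma(self, modulated_dose):
        """More interpolation candidates can only lower each minimum."""
        rng = np.random.default_rng(13)
        ref = modulated_dose.decimate(7)
        ev = modulated_dose.copy(
            values=np.clip(modulated_dose.values + rng.normal(0, 0.02, modulated_dose.values.shape), 0, None)
        )
        coarse = gamma_map(ref, ev, GammaCriteria(3.0, 2.0, subgrid_mm=1.0))
        fine = gamma_map(ref, ev, GammaCriteria(3.0, 2.0, subgrid_mm=0.5))
        assert np.all(fine.gamma[fine.mask] <= coarse.gamma[coarse.mask] + 1e-9)

    def test_scattered_map_evaluated(self, modulated_dose, d729):
        measured = vq.sample(modulated_dose, d729)
        ref = modulated_dose.decimate(5)
        res = gamma_map(ref, measured, GammaCriteria(3.0, 2.0))
        assert 0.0 <= pass_rate(res) <= 100.0
        assert np.all(res.gamma[res.mask] >= 0)


class TestPassRate:
    def test_counting_against_recount_oracle(self, modulated_dose):
        rng = np.random.default_rng(21)
        ref = modulated_dose.decimate(5)
        ev = modulated_dose.copy(
            values=np.clip(modulated_dose.values + rng.normal(0, 0.03, modulated_dose.values.shape), 0, None)
        )
        res = gamma_map(ref, ev, GammaCriteria(2.0, 1.0))
        g = res.gamma[res.mask]
        assert pass_rate(res) == pytest.approx(100.0 * np.sum(g <= 1) / g.size)

    def test_half_failing_counts_exactly(self):
        """Points spaced beyond the search cap cannot rescue each other, so
        half grossly-wrong points give exactly a 50% pass rate."""
        ref = grid(np.full((10, 10), 100.0), spacing=10.0)
        vals = np.full((10, 10), 100.0)
        vals[:5] = 150.0  # gamma >> 1 on half the points
        res = gamma_map(ref, grid(vals, spacing=10.0), GammaCriteria(3.0, 2.0))
        assert pass_rate(res) == pytest.approx(50.0)


class TestGamma3d:
    def test_identity(self):
        rng = np.random.default_rng(6)
        vals = rng.random((8, 8, 8)) + 0.5
        res = gamma_map_3d(vals, vals, (2.0, 2.0, 2.0), GammaCriteria(3.0, 2.0), subgrid_mm=1.0)
        assert np.nanmax(res.gamma) < 1e-9

    def test_uniform_dose_difference(self):
        ref = np.full((6, 6, 6), 100.0)
        ev = np.full((6, 6, 6), 102.0)
        res = gamma_map_3d(ref, ev, (2.0, 2.0, 2.0), GammaCriteria(2.0, 2.0), subgrid_mm=1.0)
        assert np.allclose(res.gamma[res.mask], 1.0, atol=1e-9)


class TestProfiles:
    def test_identical_profiles_zero_gamma(self, modulated_dose):
        prof = profile_compare(modulated_dose, modulated_dose, direction="lateral")
        valid = prof["gamma"].dropna()
        assert len(valid) > 50
        assert valid.max() < 1e-6

    def test_shifted_map_fails_in_penumbra_only(self):
        """A 1 mm shift is within DTA on the plateau; the 2 mm profile search
        keeps plateau gamma low while penumbra gamma peaks."""
        from conftest import open_square_spec

        spec = open_square_spec(half_mm=50.0, penumbra_mm=3.0)
        calc = vq.generate_vmat_dosemap(spec, 0)
        shifted = vq.GroundTruthDose(calc.values, (calc.origin[0] + 1.0, calc.origin[1]), calc.spacing)
        prof = profile_compare(shifted, calc, direction="lateral")
        plateau = prof[np.abs(prof["position_mm"]) < 30]["gamma"]
        penumbra = prof[(np.abs(prof["position_mm"]) > 45) & (np.abs(prof["position_mm"]) < 56)]["gamma"]
        assert plateau.max() < 0.6
        assert penumbra.max() > plateau.max()

    def test_diagonal_direction_supported(self, modulated_dose):
        prof = profile_compare(modulated_dose, modulated_dose, direction="diagonal")
        assert len(prof) > 50

    def test_unknown_direction_rejected(self, modulated_dose):
        with pytest.raises(ValueError):
            profile_compare(modulated_dose, modulated_dose, direction="circular")


class TestCriteriaValidation:
    @pytest.mark.parametrize("dd,dta,norm,th", [(-1, 2, "global", 10), (3, 0, "global", 10), (3, 2, "median", 10), (3, 2, "global", 100)])
    def test_invalid_criteria_rejected(self, dd, dta, norm, th):
        with pytest.raises(ValueError):
            GammaCriteria(dd, dta, normalization=norm, threshold_percent=th)
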