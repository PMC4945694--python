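"""Moment-based ellipsoid fitting and derived nuclear shape features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleoflux.morphometry import (ellipsoid_surface, fit_ellipsoid,
                                    group_summary, normalize_features,
                                    shape_indices, _surface_quadrature)
from nucleoflux.synthetic import GridSpec, VoxelGrid, make_ellipsoid_mask

from .conftest import rotation_about_z


class TestFitEllipsoid:
    def test_recovers_sphere_radius(self):
        fit = fit_ellipsoid(make_ellipsoid_mask((5, 5, 5)))
        assert np.all(np.abs(fit.semi_axes - 5.0) / 5.0 < 0.03)
        assert fit.volume == pytest.approx(4 / 3 * math.pi * np.prod(fit.semi_axes),
                                           rel=1e-6)

    def test_recovers_axis_aligned_ellipsoid(self):
        fit = fit_ellipsoid(make_ellipsoid_mask((8, 6, 4)))
        np.testing.assert_allclose(fit.semi_axes, [8, 6, 4], rtol=0.03)
        # recovered axes within 5 degrees of the grid axes
        for k in range(3):
            cosang = abs(fit.orientation[k, k])
            assert cosang > math.cos(math.radians(5.0))

    def test_rotation_invariance_of_semi_axes(self):
        ref = fit_ellipsoid(make_ellipsoid_mask((8, 6, 4)))
        rot = fit_ellipsoid(make_ellipsoid_mask((8, 6, 4), rotation_about_z(45)))
        np.testing.assert_allclose(rot.semi_axes, ref.semi_axes, rtol=0.03)

    @pytest.mark.parametrize("axes,angle", [
        ((4.5, 3.6, 3.0), 0.0),
        ((10.0, 7.0, 4.0), 30.0),
        ((6.0, 6.0, 3.0), 60.0),
    ])
    def test_roundtrip_recovery(self, axes, angle):
        """Generator -> fit round trip recovers parameters within 3 %."""
        fit = fit_ellipsoid(make_ellipsoid_mask(axes, rotation_about_z(angle)))
        np.testing.assert_allclose(fit.semi_axes, axes, rtol=0.03)

    def test_spacing_invariance(self):
        fits = []
        for sp in [(0.207, 0.207, 1.0), (0.1035, 0.1035, 0.5)]:
            shape = tuple(int(round(20 / s)) for s in sp)
            v = make_ellipsoid_mask((7, 6, 5), grid=GridSpec(shape, sp))
            fits.append(fit_ellipsoid(v).semi_axes)
        assert np.all(np.abs(fits[1] - fits[0]) / fits[0] < 0.01)

    def test_empty_mask_raises(self):
        v = VoxelGrid(GridSpec((8, 8, 4)), np.zeros((8, 8, 4), bool))
        with pytest.raises(ValueError, match="empty"):
            fit_ellipsoid(v)

    def test_planar_mask_raises_rank_deficiency(self):
        m = np.zeros((20, 20, 5), bool)
        m[4:16, 4:16, 2] = True
        with pytest.raises(ValueError, match="rank"):
            fit_ellipsoid(VoxelGrid(GridSpec((20, 20, 5)), m))

    def test_disconnected_mask_raises(self):
        m = np.zeros((30, 30, 10), bool)
        m[2:6, 2:6, 2:5] = True
        m[20:24, 20:24, 5:8] = True
        with pytest.raises(ValueError, match="6-connected"):
            fit_ellipsoid(VoxelGrid(GridSpec((30, 30, 10)), m))


class TestEllipsoidSurface:
    def test_sphere_closed_form(self):
        assert ellipsoid_surface((5, 5, 5)) == pytest.approx(100 * math.pi,
                                                             rel=1e-9)

    def test_matches_quadrature_oracle(self):
        for axes in [(8, 6, 4), (10, 9.5, 2.0), (7, 7, 3)]:
            S = ellipsoid_surface(axes)
            S_ref = _surface_quadrature(*axes)
            assert S == pytest.approx(S_ref, rel=1e-6)

    def test_matches_triangulation_oracle(self):
        """Independent fine-triangulation area for a generic triaxial case."""
        a, b, c = 8.0, 6.0, 4.0
        n = 400
        th = np.linspace(0, math.pi, n + 1)
        ph = np.linspace(0, 2 * math.pi, 2 * n + 1)
        T, P = np.meshgrid(th, ph, indexing="ij")
        X = np.stack([a * np.sin(T) * np.cos(P), b * np.sin(T) * np.sin(P),
                      c * np.cos(T)], axis=-1)
        # sum of quad areas via the two triangle cross products
        a1 = X[1:, :-1] - X[:-1, :-1]
        a2 = X[:-1, 1:] - X[:-1, :-1]
        b1 = X[1:, 1:] - X[1:, :-1]
        b2 = X[:-1, 1:] - X[1:, :-1]
        area = 0.5 * (np.linalg.norm(np.cross(a1, a2), axis=-1).sum()
                      + np.linalg.norm(np.cross(b1, b2), axis=-1).sum())
        assert ellipsoid_surface((a, b, c)) == pytest.approx(area, rel=1e-3)

    def test_oblate_limit_tends_to_sphere(self):
        S = ellipsoid_surface((5, 5, 4.9999999))
        assert S == pytest.approx(100 * math.pi, rel=1e-5)

    def test_exceeds_equal_volume_sphere(self):
        for axes in [(8, 6, 4), (9, 5, 3), (6, 6, 5)]:
            S = ellipsoid_surface(axes)
            r_eq = (np.prod(axes)) ** (1 / 3)
            assert S >= 4 * math.pi * r_eq**2 - 1e-9

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(3.0, 10.0), st.floats(0.4, 1.0), st.floats(0.3, 1.0),
           st.floats(1.01, 1.3))
    def test_monotone_in_each_axis(self, a, eb, ec, grow):
        b = max(a * eb, 1e-2)
        c = min(max(b * ec, 1e-2), b)
        S0 = ellipsoid_surface((a, b, c))
        assert ellipsoid_surface((a * grow, b, c)) > S0
        bigger_c = min(c * grow, b)
        if bigger_c > c:
            assert ellipsoid_surface((a, b, bigger_c)) > S0

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            ellipsoid_surface((4, 5, 3))
        with pytest.raises(ValueError):
            ellipsoid_surface((5, 4, -1))


class TestShapeIndices:
    @pytest.mark.parametrize("axes,expect", [
        ((5, 5, 5), "spherical"),
        ((8, 7.6, 4), "disk_like"),
        ((8, 3, 2.8), "rod_like"),
        ((8, 6, 3), "other"),
    ])
    def test_classification(self, axes, expect):
        fit = fit_ellipsoid(make_ellipsoid_mask(axes))
        si = shape_indices(fit)
        assert si.shape_class == expect
        assert si.elongation == pytest.approx(axes[1] / axes[0], rel=0.05)
        assert si.flatness == pytest.approx(axes[2] / axes[0], rel=0.05)


class TestGroupSummary:
    def test_constant_sample(self):
        s = group_summary({"a": np.array([5.0, 5.0, 5.0])}, "roundish")
        assert s.mean["a"] == 5.0
        assert s.sd["a"] == 0.0
        assert s.halfwidth99["a"] == 0.0

    def test_parameter_recovery_roundish(self):
        rng = np.random.default_rng(0)
        a = rng.normal(5.30, 0.73, 1000)
        s = group_summary({"a": a}, "roundish")
        assert abs(s.mean["a"] - 5.30) < 3 * 0.73 / math.sqrt(1000)
        assert abs(s.sd["a"] - 0.73) / 0.73 < 0.10
        assert s.halfwidth99["a"] == pytest.approx(2.5758 * s.sd["a"], rel=1e-3)

    def test_standard_error_mode(self):
        vals = {"a": np.arange(1.0, 11.0)}
        disp = group_summary(vals, "spread", interval="dispersion")
        se = group_summary(vals, "spread", interval="standard-error")
        assert se.halfwidth99["a"] == pytest.approx(
            disp.halfwidth99["a"] / math.sqrt(10))

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            group_summary({"a": np.array([1.0])}, "spread")


class TestNormalizeFeatures:
    def _summary(self, a, S, V, label):
        return group_summary({"a": np.array([a, a]), "S": np.array([S, S]),
                              "V": np.array([V, V])}, label)

    def test_identity(self):
        s = self._summary(5.3, 282.4, 148.0, "roundish")
        nf = normalize_features(s, s)
        assert (nf.a_ratio, nf.S_ratio, nf.V_ratio) == (1.0, 1.0, 1.0)

    def test_spread_over_roundish_means(self):
        spread = self._summary(7.89, 417.74, 163.0, "spread")
        ref = self._summary(5.30, 282.42, 148.0, "roundish")
        nf = normalize_features(spread, ref)
        assert nf.a_ratio == pytest.approx(7.89 / 5.30, rel=1e-12)
        assert nf.S_ratio == pytest.approx(417.74 / 282.42, rel=1e-12)

    def test_volume_ratio_recovery_on_synthetic_groups(self):
        """Groups built with V_spread = 1.10 V_round recover the 10 % gain."""
        rng = np.random.default_rng(1)
        v_r = rng.normal(150.0, 8.0, 400)
        v_s = rng.normal(165.0, 9.0, 400)
        ref = group_summary({"V": v_r}, "roundish")
        spread = group_summary({"V": v_s}, "spread")
        nf = normalize_features(spread, ref, features=("V", "V", "V"))
        se = 1.10 * math.sqrt((8 / 150) ** 2 + (9 / 165) ** 2) / math.sqrt(400)
        assert abs(nf.V_ratio - 1.10) < 4 * se

    def test_zero_reference_rejected(self):
        ref = self._summary(5.3, 282.4, 148.0, "roundish")
        ref.mean["V"] = 0.0
        spread = self._summary(7.9, 417.7, 163.0, "spread")
        with pytest.raises(ValueError):
            normalize_features(spread, ref)
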