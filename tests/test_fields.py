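"""Field-analysis primitives: divergence, decomposition, profiles, means."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actogel.fields import (
    ActivationRegion,
    ScalarFieldSeries,
    VectorFieldSeries,
    boundary_velocity,
    decompose_radial,
    divergence,
    radial_profile,
    recompose,
    region_mean,
    tangential_fraction,
)


def make_field(fx, fy, n=41, h=1.0, times=(0.0,), centered=True):
    """Vector field series from component functions of (x, y)."""
    origin = (-(n - 1) / 2 * h, -(n - 1) / 2 * h) if centered else (0.0, 0.0)
    x = origin[0] + h * np.arange(n)
    y = origin[1] + h * np.arange(n)
    X, Y = np.meshgrid(x, y, indexing="ij")
    t = np.asarray(times, dtype=float)
    vx = np.broadcast_to(fx(X, Y), (t.size, n, n)).copy()
    vy = np.broadcast_to(fy(X, Y), (t.size, n, n)).copy()
    return VectorFieldSeries(t, vx, vy, h, origin)


CENTER = ActivationRegion((0.0, 0.0), 10.0)


class TestDivergence:
    def test_uniform_contraction(self):
        a = 0.01
        fld = make_field(lambda x, y: -a * x, lambda x, y: -a * y)
        div = divergence(fld)
        assert np.allclose(div.values[0, 1:-1, 1:-1], -2 * a, atol=1e-14)

    def test_uniform_translation_divergence_free(self):
        fld = make_field(lambda x, y: 0.3 * np.ones_like(x), lambda x, y: np.zeros_like(x))
        assert np.allclose(divergence(fld).values, 0.0, atol=1e-14)

    def test_quadratic_exact_in_interior(self):
        # central differences are exact for quadratics: div (x^2, 0) = 2x
        fld = make_field(lambda x, y: x**2, lambda x, y: np.zeros_like(x))
        x = fld.coords()[0].ravel()
        div = divergence(fld).values[0]
        expected = np.broadcast_to(2 * x[:, None], div.shape)
        assert np.allclose(div[1:-1, :], expected[1:-1, :], atol=1e-11)

    def test_small_grid_rejected(self):
        fld = VectorFieldSeries(np.array([0.0]), np.zeros((1, 2, 2)), np.zeros((1, 2, 2)), 1.0)
        with pytest.raises(ValueError, match="3x3"):
            divergence(fld)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(st.lists(st.floats(-2, 2), min_size=10, max_size=10))
    def test_solenoidal_polynomial_fields(self, coeffs):
        # vx = dpsi/dy, vy = -dpsi/dx is divergence-free for any psi;
        # cubic psi keeps the central differences exact in the interior
        c = np.array(coeffs)

        def psi_x(x, y):  # dpsi/dx
            return c[0] + 2 * c[1] * x + c[2] * y + 3 * c[3] * x**2 + 2 * c[4] * x * y + c[5] * y**2

        def psi_y(x, y):  # dpsi/dy
            return c[6] + c[2] * x + 2 * c[7] * y + c[4] * x**2 + 2 * c[5] * x * y + 3 * c[8] * y**2

        fld = make_field(psi_y, lambda x, y: -psi_x(x, y), n=15)
        div = divergence(fld).values[0]
        assert np.allclose(div[1:-1, 1:-1], 0.0, atol=1e-10 * max(1, np.abs(c).max()))


class TestDecomposeRadial:
    def test_pure_sink_is_inward_positive(self):
        a = 0.05
        fld = make_field(
            lambda x, y: -a * x / np.where(np.hypot(x, y) > 0, np.hypot(x, y), np.inf),
            lambda x, y: -a * y / np.where(np.hypot(x, y) > 0, np.hypot(x, y), np.inf),
        )
        v_r, v_t = decompose_radial(fld, CENTER)
        r = CENTER.radius_grid(fld)
        off = r > fld.spacing
        assert np.allclose(v_r.values[0][off], a, atol=1e-12)
        assert np.allclose(v_t.values[0][off], 0.0, atol=1e-12)

    def test_rigid_rotation(self):
        w = 0.02
        fld = make_field(lambda x, y: -w * y, lambda x, y: w * x)
        v_r, v_t = decompose_radial(fld, CENTER)
        r = CENTER.radius_grid(fld)
        off = r > fld.spacing
        assert np.allclose(v_r.values[0][off], 0.0, atol=1e-12)
        assert np.allclose(v_t.values[0][off], (w * r)[off], atol=1e-12)

    def test_magnitude_identity_and_recompose(self):
        rng = np.random.default_rng(11)
        n = 21
        fld = VectorFieldSeries(
            np.array([0.0, 10.0]),
            rng.normal(size=(2, n, n)),
            rng.normal(size=(2, n, n)),
            1.0,
            (-(n - 1) / 2, -(n - 1) / 2),
        )
        v_r, v_t = decompose_radial(fld, CENTER)
        r = CENTER.radius_grid(fld)
        off = r > fld.spacing / 2
        speed2 = fld.vx**2 + fld.vy**2
        assert np.allclose(
            (v_r.values**2 + v_t.values**2)[:, off], speed2[:, off], atol=1e-12
        )
        back = recompose(v_r, v_t, CENTER)
        assert np.allclose(back.vx[:, off], fld.vx[:, off], atol=1e-12)
        assert np.allclose(back.vy[:, off], fld.vy[:, off], atol=1e-12)

    def test_center_node_zeroed(self):
        fld = make_field(lambda x, y: np.ones_like(x), lambda x, y: np.ones_like(x))
        v_r, v_t = decompose_radial(fld, CENTER)
        ic = fld.shape[0] // 2
        assert v_r.values[0, ic, ic] == 0.0
        assert v_t.values[0, ic, ic] == 0.0


class TestRadialProfile:
    def test_constant_field(self):
        fld = make_field(lambda x, y: np.ones_like(x), lambda x, y: np.zeros_like(x))
        scalar = ScalarFieldSeries(fld.times, np.full((1, 41, 41), 3.5), 1.0, fld.origin)
        prof = radial_profile(scalar, CENTER, 2.0)[0]
        assert np.allclose(prof.mean[~prof.empty], 3.5)

    def test_linear_in_r(self):
        n, h = 201, 0.2
        origin = (-(n - 1) / 2 * h,) * 2
        x = origin[0] + h * np.arange(n)
        X, Y = np.meshgrid(x, x, indexing="ij")
        scalar = ScalarFieldSeries(np.array([0.0]), np.hypot(X, Y)[None], h, origin)
        prof = radial_profile(scalar, CENTER, 1.0)[0]
        sel = (~prof.empty) & (prof.r < 15)
        # oracle: the area-weighted mean radius of the annulus [r1, r2] is
        # 2 (r2^3 - r1^3) / (3 (r2^2 - r1^2)), not the bin center
        r1 = prof.r[sel] - 0.5
        r2 = prof.r[sel] + 0.5
        annulus_mean = 2 * (r2**3 - r1**3) / (3 * (r2**2 - r1**2))
        assert np.all(np.abs(prof.mean[sel] - annulus_mean) < h / 2)

    def test_single_giant_bin(self):
        fld = make_field(lambda x, y: np.zeros_like(x), lambda x, y: np.zeros_like(x), n=11)
        scalar = ScalarFieldSeries(fld.times, np.arange(121, dtype=float).reshape(1, 11, 11), 1.0, fld.origin)
        prof = radial_profile(scalar, CENTER, 1e3)[0]
        assert prof.r.size == 1
        assert np.isclose(prof.mean[0], scalar.values.mean())

    def test_rotation_invariance_of_sink_divergence_profile(self):
        a = 0.05
        fld = make_field(
            lambda x, y: -a * x / np.where(np.hypot(x, y) > 0, np.hypot(x, y), np.inf),
            lambda x, y: -a * y / np.where(np.hypot(x, y) > 0, np.hypot(x, y), np.inf),
        )
        div = divergence(fld)
        rot = VectorFieldSeries(
            fld.times,
            -np.rot90(fld.vy[0], 1)[None],
            np.rot90(fld.vx[0], 1)[None],
            fld.spacing,
            fld.origin,
        )
        div_rot = divergence(rot)
        p1 = radial_profile(div, CENTER, 2.0)[0]
        p2 = radial_profile(div_rot, CENTER, 2.0)[0]
        assert np.allclose(p1.mean[~p1.empty], p2.mean[~p2.empty], atol=1e-12)


class TestBoundaryVelocityAndRegionMean:
    def test_constant_vr_any_window(self):
        fld = make_field(lambda x, y: np.zeros_like(x), lambda x, y: np.zeros_like(x))
        vr = ScalarFieldSeries(fld.times, np.full((1, 41, 41), 0.7), 1.0, fld.origin)
        for w in (1.0, 2.65, 6.0):
            assert np.isclose(boundary_velocity(vr, CENTER, w)[0], 0.7)

    def test_linear_vr_narrow_window(self):
        n, h = 401, 0.1
        origin = (-(n - 1) / 2 * h,) * 2
        x = origin[0] + h * np.arange(n)
        X, Y = np.meshgrid(x, x, indexing="ij")
        vr = ScalarFieldSeries(np.array([0.0]), np.hypot(X, Y)[None], h, origin)
        got = boundary_velocity(vr, ActivationRegion((0, 0), 10.0), 0.5)[0]
        assert abs(got - 10.0) < 0.05

    def test_zero_field(self):
        fld = make_field(lambda x, y: np.zeros_like(x), lambda x, y: np.zeros_like(x))
        vr = ScalarFieldSeries(fld.times, np.zeros((1, 41, 41)), 1.0, fld.origin)
        assert boundary_velocity(vr, CENTER)[0] == 0.0

    def test_empty_annulus_error_names_geometry(self):
        vr = ScalarFieldSeries(np.array([0.0]), np.zeros((1, 5, 5)), 1.0, (0, 0))
        with pytest.raises(ValueError, match="annulus"):
            boundary_velocity(vr, ActivationRegion((2, 2), 100.0), 0.001)

    def test_region_mean_cases(self):
        n = 41
        origin = (-(n - 1) / 2, -(n - 1) / 2)
        x = origin[0] + np.arange(n)
        X, Y = np.meshgrid(x, x, indexing="ij")
        t = np.array([0.0])
        const = ScalarFieldSeries(t, np.full((1, n, n), 2.2), 1.0, origin)
        assert np.isclose(region_mean(const, CENTER)[0], 2.2)
        ind = ScalarFieldSeries(t, (np.hypot(X, Y) <= 10.0)[None].astype(float), 1.0, origin)
        assert np.isclose(region_mean(ind, CENTER)[0], 1.0)
        linear = ScalarFieldSeries(t, X[None].astype(float), 1.0, origin)
        assert np.isclose(region_mean(linear, CENTER)[0], 0.0, atol=1e-12)

    def test_region_mean_no_nodes(self):
        vr = ScalarFieldSeries(np.array([0.0]), np.zeros((1, 5, 5)), 1.0, (0, 0))
        with pytest.raises(ValueError, match="inside"):
            region_mean(vr, ActivationRegion((200.0, 200.0), 0.5))


class TestIngestion:
    def test_gap_infill_flags_and_fills(self):
        rng = np.random.default_rng(5)
        vx = rng.normal(size=(2, 15, 15))
        vy = rng.normal(size=(2, 15, 15))
        drop = rng.random((2, 15, 15)) < 0.1
        vx_raw = vx.copy()
        vx_raw[drop] = np.nan
        fld = VectorFieldSeries.from_raw(np.array([0.0, 10.0]), vx_raw, vy, 1.0)
        assert np.isfinite(fld.vx).all()
        assert np.allclose(fld.gap_fraction, drop.reshape(2, -1).mean(axis=1))
        # untouched nodes unchanged
        assert np.allclose(fld.vx[~drop], vx[~drop])

    def test_nonfinite_rejected_in_strict_constructor(self):
        vx = np.zeros((1, 5, 5))
        vx[0, 2, 2] = np.nan
        with pytest.raises(ValueError, match="from_raw"):
            VectorFieldSeries(np.array([0.0]), vx, np.zeros((1, 5, 5)), 1.0)

    def test_tangential_fraction_extremes(self):
        sink = make_field(
            lambda x, y: -x / np.where(np.hypot(x, y) > 0, np.hypot(x, y), np.inf),
            lambda x, y: -y / np.where(np.hypot(x, y) > 0, np.hypot(x, y), np.inf),
        )
        rot = make_field(lambda x, y: -y, lambda x, y: x)
        assert tangential_fraction(sink, CENTER)[0] < 0.01
        assert tangential_fraction(rot, CENTER)[0] > 0.99
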