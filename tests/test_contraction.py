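"""Strain timecourse, phase segmentation, strain rate and plateau strain."""

import numpy as np
import pytest
from scipy.integrate import quad

from actogel.contraction import (
    StrainTimecourse,
    max_strain,
    segment_phases,
    strain_rate,
    strain_timecourse,
)
from actogel.fields import ActivationRegion, VectorFieldSeries

REGION = ActivationRegion((0.0, 0.0), 10.0)


def uniform_contraction_series(a=0.005, n=41, h=1.0, times=None):
    times = np.arange(0.0, 401.0, 10.0) if times is None else times
    origin = (-(n - 1) / 2 * h,) * 2
    x = origin[0] + h * np.arange(n)
    X, Y = np.meshgrid(x, x, indexing="ij")
    vx = np.broadcast_to(-a * X, (times.size, n, n)).copy()
    vy = np.broadcast_to(-a * Y, (times.size, n, n)).copy()
    return VectorFieldSeries(times, vx, vy, h, origin)


class TestStrainTimecourse:
    def test_uniform_contraction_exact(self):
        a = 0.005
        fld = uniform_contraction_series(a)
        tc = strain_timecourse(fld, REGION)
        assert np.allclose(tc.strain, 2 * a * fld.times, atol=1e-12)
        assert tc.strain[0] == 0.0

    def test_zero_field(self):
        fld = uniform_contraction_series(0.0)
        tc = strain_timecourse(fld, REGION)
        assert np.allclose(tc.strain, 0.0)

    def test_single_frame_rejected(self):
        fld = uniform_contraction_series(times=np.array([0.0]))
        with pytest.raises(ValueError, match="2 frames"):
            strain_timecourse(fld, REGION)

    def test_time_reversal_flips_sign(self):
        fld = uniform_contraction_series(0.004)
        rev = VectorFieldSeries(fld.times, -fld.vx, -fld.vy, fld.spacing, fld.origin)
        tc = strain_timecourse(fld, REGION)
        tc_rev = strain_timecourse(rev, REGION)
        assert np.allclose(tc_rev.strain, -tc.strain, atol=1e-14)

    def test_rotation_invariance_of_summary_metrics(self):
        # rotate a generic contracting field by 90 degrees about the center
        rng = np.random.default_rng(3)
        n = 41
        times = np.arange(0.0, 401.0, 10.0)
        base = uniform_contraction_series(0.003, n=n, times=times)
        noise = 0.02 * rng.normal(size=(1, n, n))
        vx = base.vx + noise
        vy = base.vy + noise[:, ::-1]
        fld = VectorFieldSeries(times, vx, vy, 1.0, base.origin)
        rot = VectorFieldSeries(
            times,
            np.stack([-np.rot90(fld.vy[k], 1) for k in range(times.size)]),
            np.stack([np.rot90(fld.vx[k], 1) for k in range(times.size)]),
            1.0,
            base.origin,
        )
        tc, tc_rot = strain_timecourse(fld, REGION), strain_timecourse(rot, REGION)
        assert np.isclose(strain_rate(tc), strain_rate(tc_rot), rtol=1e-10)
        assert np.isclose(max_strain(tc), max_strain(tc_rot), rtol=1e-10)

    def test_tangential_fraction_attached(self):
        fld = uniform_contraction_series()
        tc = strain_timecourse(fld, REGION)
        assert tc.tangential_fraction is not None
        assert np.all(tc.tangential_fraction < 0.05)


class TestSegmentPhases:
    def test_default_windows(self):
        times = np.arange(0.0, 401.0, 10.0)
        tc = StrainTimecourse(times, np.zeros_like(times))
        ph = segment_phases(tc)
        assert np.all(times[ph.p1] < 100.0)
        assert np.all((times[ph.p2] >= 100.0) & (times[ph.p2] <= 300.0))
        assert np.all(times[ph.p3] > 300.0)
        assert ph.p1.size + ph.p2.size + ph.p3.size == times.size

    def test_short_series_flags_empty_plateau(self):
        times = np.arange(0.0, 251.0, 10.0)
        tc = StrainTimecourse(times, np.zeros_like(times))
        with pytest.warns(UserWarning, match="P3 is empty"):
            ph = segment_phases(tc)
        assert ph.p3_empty

    def test_t1_zero_empties_lag(self):
        times = np.arange(0.0, 401.0, 10.0)
        tc = StrainTimecourse(times, np.zeros_like(times), t1=0.0)
        ph = segment_phases(tc)
        assert ph.p1.size == 0

    def test_inverted_boundaries_rejected(self):
        tc = StrainTimecourse(np.arange(0.0, 401.0, 10.0), np.zeros(41))
        with pytest.raises(ValueError, match="t1 < t2"):
            segment_phases(tc, t1=300.0, t2=100.0)


class TestStrainRate:
    def test_linear_strain_recovered_exactly(self):
        times = np.arange(0.0, 401.0, 10.0)
        tc = StrainTimecourse(times, 0.003 * times)
        assert np.isclose(strain_rate(tc), 0.003, rtol=1e-12)

    def test_saturating_curve_matches_continuous_ols(self):
        # independent oracle: continuous least-squares slope over [t1, t2],
        # slope = int (t - tbar) eps(t) dt / int (t - tbar)^2 dt
        eps0, tau, t1, t2 = 1.2, 150.0, 100.0, 300.0
        f = lambda t: eps0 * (1 - np.exp(-t / tau))
        tbar = (t1 + t2) / 2
        num = quad(lambda t: (t - tbar) * f(t), t1, t2)[0]
        den = quad(lambda t: (t - tbar) ** 2, t1, t2)[0]
        continuous = num / den
        times = np.arange(0.0, 401.0, 10.0)
        got = strain_rate(StrainTimecourse(times, f(times)))
        # 10 s sampling of the window introduces O((dt/tau)^2) discrepancy
        assert np.isclose(got, continuous, rtol=1e-2)

    def test_noisy_slope_within_standard_error(self):
        rng = np.random.default_rng(21)
        b, sd = 0.003, 0.01
        times = np.arange(100.0, 301.0, 10.0)
        full_t = np.arange(0.0, 401.0, 10.0)
        eps = b * full_t + sd * rng.normal(size=full_t.size)
        got = strain_rate(StrainTimecourse(full_t, eps))
        n = times.size
        se = sd / np.sqrt(np.sum((times - times.mean()) ** 2))
        assert abs(got - b) < 3 * se

    def test_too_few_p2_samples(self):
        tc = StrainTimecourse(np.array([0.0, 150.0, 400.0]), np.zeros(3))
        with pytest.raises(ValueError, match="3 samples"):
            strain_rate(tc)


class TestMaxStrain:
    def test_constant_plateau(self):
        times = np.arange(0.0, 601.0, 10.0)
        eps = np.where(times > 300, 1.4, 1.4 * times / 300)
        assert np.isclose(max_strain(StrainTimecourse(times, eps)), 1.4)

    def test_saturating_curve_matches_analytic_window_mean(self):
        eps0, tau = 1.3, 40.0
        times = np.arange(0.0, 601.0, 10.0)
        tc = StrainTimecourse(times, eps0 * (1 - np.exp(-times / tau)))
        got = max_strain(tc)
        t3 = times[times > 300.0]
        analytic = eps0 * (1 - np.exp(-t3 / tau)).mean()
        assert np.isclose(got, analytic, rtol=1e-12)
        assert np.isclose(got, eps0, rtol=1e-3)  # tau << t2

    def test_monotone_series_dominates_t2_value(self):
        times = np.arange(0.0, 601.0, 10.0)
        eps = np.sqrt(times)
        tc = StrainTimecourse(times, eps)
        assert max_strain(tc) >= eps[times <= 300][-1]

    def test_empty_plateau_rejected(self):
        tc = StrainTimecourse(np.arange(0.0, 251.0, 10.0), np.zeros(26))
        with pytest.raises(ValueError, match="longer series"):
            max_strain(tc)
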