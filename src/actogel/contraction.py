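"""Strain timecourses and contraction summary metrics.

Turns velocity-field series into the headline scalars of a contraction
experiment: the area-averaged contractile strain ``eps(t)`` inside the
activation disc, its phase segmentation (lag / linear / plateau), the strain
rate (slope of the linear phase) and the maximum strain (plateau mean).

Strain is **contraction-positive**: the displacement field is the cumulative
time integral of the velocity field, and

    eps(t) = - < div u(t) >_disc

so inward flow yields positive, typically monotonically increasing strain.
Because both the time integral and the divergence stencil are linear, this
equals the time integral of the area-averaged divergence of the velocity to
round-off; the implementation asserts that agreement as a self-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .fields import (
    ActivationRegion,
    VectorFieldSeries,
    boundary_velocity,
    decompose_radial,
    divergence,
    region_mean,
    tangential_fraction,
)

__all__ = [
    "StrainTimecourse",
    "PhaseWindows",
    "ContractionSummary",
    "strain_timecourse",
    "segment_phases",
    "strain_rate",
    "max_strain",
    "contraction_summary",
]

#: default phase boundaries (s): lag P1 = [0, t1), linear P2 = [t1, t2],
#: plateau P3 = (t2, inf)
DEFAULT_T1 = 100.0
DEFAULT_T2 = 300.0


@dataclass
class StrainTimecourse:
    """Area-averaged contractile strain over time.

    ``strain`` is dimensionless and contraction-positive; values above one
    are legitimate because the measure accumulates deformation in both the
    radial and orthoradial directions and material flows into the disc.
    """

    times: np.ndarray
    strain: np.ndarray
    t1: float = DEFAULT_T1
    t2: float = DEFAULT_T2
    tangential_fraction: np.ndarray | None = dc_field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if self.times.shape != self.strain.shape:
            raise ValueError("times and strain must have matching shapes")


@dataclass
class PhaseWindows:
    """Index arrays for the lag (P1), linear (P2) and plateau (P3) phases."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray

    @property
    def p3_empty(self) -> bool:
        return self.p3.size == 0


def strain_timecourse(
    fld: VectorFieldSeries,
    region: ActivationRegion,
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
) -> StrainTimecourse:
    """Contractile strain eps(t) over the activation disc from a velocity series.

    The local displacement field is the cumulative trapezoidal time integral
    of the velocity field; the strain is minus the disc average of its
    divergence.  The per-frame tangential flow fraction is attached so that
    the exclusion of the tangentially dominated lag phase from rate
    estimates stays auditable.
    """
    if fld.n_frames < 2:
        raise ValueError("strain timecourse requires at least 2 frames")
    ux = cumulative_trapezoid(fld.vx, fld.times, axis=0, initial=0.0)
    uy = cumulative_trapezoid(fld.vy, fld.times, axis=0, initial=0.0)
    disp = VectorFieldSeries(fld.times, ux, uy, fld.spacing, fld.origin)
    eps = -region_mean(divergence(disp), region)

    # self-check: integrating the divergence of the velocity must agree
    # (all operations are linear and commute on a uniform grid)
    eps_alt = -cumulative_trapezoid(
        region_mean(divergence(fld), region), fld.times, initial=0.0
    )
    scale = max(np.abs(eps).max(), 1e-30)
    if not np.allclose(eps, eps_alt, atol=1e-9 * scale):  # pragma: no cover
        raise AssertionError(
            "strain self-check failed: div(integral v) != integral(div v)"
        )

    return StrainTimecourse(
        fld.times, eps, t1, t2, tangential_fraction=tangential_fraction(fld, region)
    )


def segment_phases(
    tc: StrainTimecourse, t1: float | None = None, t2: float | None = None
) -> PhaseWindows:
    """Split sample indices into P1 [0, t1), P2 [t1, t2] and P3 (t2, end].

    An empty plateau (series ending before ``t2``) is flagged with a warning
    rather than an error so that short model runs can still be segmented.
    """
    t1 = tc.t1 if t1 is None else t1
    t2 = tc.t2 if t2 is None else t2
    if t1 >= t2:
        raise ValueError(f"phase boundaries must satisfy t1 < t2, got {t1} >= {t2}")
    if tc.times[-1] <= t1:
        raise ValueError(
            f"series ends at {tc.times[-1]:.3g} s, before the lag phase ends at {t1:.3g} s"
        )
    idx = np.arange(tc.times.size)
    p1 = idx[tc.times < t1]
    p2 = idx[(tc.times >= t1) & (tc.times <= t2)]
    p3 = idx[tc.times > t2]
    if p3.size == 0:
        warnings.warn(
            f"series ends at {tc.times[-1]:.3g} s <= t2 = {t2:.3g} s: plateau P3 is empty",
            stacklevel=2,
        )
    return PhaseWindows(p1, p2, p3)


def strain_rate(tc: StrainTimecourse) -> float:
    """Strain rate (1/s): ordinary least-squares slope of eps(t) on P2.

    The lag phase P1 is excluded because its flow has a significant
    tangential component; the plateau is excluded because contraction has
    arrested there.
    """
    ph = segment_phases(tc)
    if ph.p2.size < 3:
        raise ValueError(
            f"need >= 3 samples in P2 [{tc.t1:.3g}, {tc.t2:.3g}] s for a slope, "
            f"got {ph.p2.size}"
        )
    slope, _ = np.polyfit(tc.times[ph.p2], tc.strain[ph.p2], 1)
    return float(slope)


def max_strain(tc: StrainTimecourse) -> float:
    """Maximum strain eps_max: mean of eps over the plateau phase P3."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ph = segment_phases(tc)
    if ph.p3_empty:
        raise ValueError(
            f"plateau P3 is empty (series ends at {tc.times[-1]:.3g} s <= "
            f"t2 = {tc.t2:.3g} s); acquire a longer series"
        )
    return float(tc.strain[ph.p3].mean())


@dataclass
class ContractionSummary:
    """Per-condition scalars: strain rate, eps_max, peak boundary velocity."""

    strain_rate: float
    eps_max: float
    peak_boundary_velocity: float
    xi: float
    rho: float | None = None
    seed: int | None = None
    config_hash: str | None = None

    def to_row(self) -> dict:
        return {
            "strain_rate_per_s": self.strain_rate,
            "eps_max": self.eps_max,
            "peak_boundary_velocity_um_per_s": self.peak_boundary_velocity,
            "xi_um": self.xi,
            "rho_per_um2": self.rho,
            "seed": self.seed,
            "config_hash": self.config_hash,
        }


def contraction_summary(
    fld: VectorFieldSeries,
    region: ActivationRegion,
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
    window: float = 2.65,
    rho: float | None = None,
) -> ContractionSummary:
    """Full per-condition reduction: strain rate, eps_max, peak boundary velocity."""
    tc = strain_timecourse(fld, region, t1, t2)
    v_r, _ = decompose_radial(fld, region)
    vb = boundary_velocity(v_r, region, window)
    return ContractionSummary(
        strain_rate=strain_rate(tc),
        eps_max=max_strain(tc),
        peak_boundary_velocity=float(vb.max()),
        xi=region.radius,
        rho=rho,
    )
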