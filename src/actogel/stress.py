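"""Radial network-stress reconstruction from the measured flow profile.

With the network overdamped and frictionally coupled to the substrate
(friction coefficient ``zeta``), and with radially symmetric deformation,
the 1-D radial force balance reads

    zeta * v_outward(r) = d sigma / d r

under the closure sigma_rr ~ sigma_thetatheta (isotropic in-plane stress),
which is the minimal assumption letting the balance integrate directly from
the radial velocity alone — no material constants of the network enter.
With the package's inward-positive convention v_r = -v_outward,

    sigma(r) = zeta * Int_r^{R_out} v_r(r') dr'

so a flow concentrated near the activation boundary yields a stress that
peaks at the center and decays outward, vanishing at ``R_out`` by
construction.  Unless ``zeta`` is given in physical units the stress is in
friction-normalized units (zeta * um^2 / s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import (
    ActivationRegion,
    RadialProfile,
    VectorFieldSeries,
    tangential_fraction,
)

__all__ = ["StressProfile", "ApplicabilityReport", "radial_stress", "applicability_check"]


@dataclass
class StressProfile:
    """Reconstructed radial stress sigma(r); sigma(r_out) = 0 by construction."""

    r: np.ndarray
    sigma: np.ndarray
    r_out: float
    zeta: float = 1.0
    units: str = "zeta*um^2/s"


def radial_stress(
    v_r_profile: RadialProfile, zeta: float = 1.0, r_out: float | None = None
) -> StressProfile:
    """Integrate the radial force balance to reconstruct sigma(r).

    Parameters
    ----------
    v_r_profile : RadialProfile
        Annular-bin means of the inward-positive radial velocity (um/s).
    zeta : float
        Substrate friction coefficient.  Defaults to 1, i.e. stress in
        friction-normalized units.
    r_out : float, optional
        Outer radius where the stress is taken to vanish.  Defaults to the
        largest radius with a sampled (non-empty) bin, since stress extends
        beyond the activation disc into the passive medium.
    """
    if not zeta > 0:
        raise ValueError("friction coefficient zeta must be positive")
    r = np.asarray(v_r_profile.r, dtype=float)
    v = np.asarray(v_r_profile.mean, dtype=float)
    nonempty = ~v_r_profile.empty
    if r_out is None:
        r_out = float(r[nonempty][-1])
    sel = r <= r_out + 1e-12
    r, v, nonempty = r[sel], v[sel], nonempty[sel]
    if not nonempty.all():
        bad = r[~nonempty]
        raise ValueError(
            f"empty interior bins at r = {np.round(bad, 3)} um; "
            "coarsen the bin width or supply a denser field"
        )
    # sigma(r) = zeta * int_r^{r_out} v_r dr' by reversed cumulative trapezoid
    dr = np.diff(r)
    seg = 0.5 * (v[1:] + v[:-1]) * dr
    inner = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    # tail correction from the last bin center to r_out (constant extrapolation)
    sigma = zeta * (inner + v[-1] * max(r_out - r[-1], 0.0))
    if r[-1] >= r_out - 1e-12:
        sigma[-1] = 0.0
    return StressProfile(r, sigma, r_out, zeta)


@dataclass
class ApplicabilityReport:
    """Frame-by-frame verdict on the radial-symmetry assumption."""

    ok: bool
    frame_ok: np.ndarray
    ratio: np.ndarray
    threshold: float
    message: str


def applicability_check(
    fld: VectorFieldSeries,
    region: ActivationRegion,
    threshold: float = 0.25,
) -> ApplicabilityReport:
    """Check that tangential flow is suppressed enough for the stress inversion.

    The inversion assumes radially symmetric deformation, valid only once
    flow is pronounced at the boundary and tangential flow is suppressed —
    typically after the first minute of activation and before aggregation.
    A frame passes when the disc-averaged tangential fraction
    ``<|v_t|> / (<|v_r|> + <|v_t|>)`` is below ``threshold``.
    """
    ratio = tangential_fraction(fld, region)
    frame_ok = ratio < threshold
    ok = bool(frame_ok.all())
    if ok:
        message = (
            f"radial-symmetry assumption holds for all {ratio.size} frames "
            f"(tangential fraction < {threshold})"
        )
    else:
        bad = np.flatnonzero(~frame_ok)
        tlist = ", ".join(f"{fld.times[i]:.0f}" for i in bad[:20])
        message = (
            f"{bad.size}/{ratio.size} frames exceed tangential fraction "
            f"{threshold}: t = {tlist} s"
        )
    return ApplicabilityReport(ok, frame_ok, ratio, threshold, message)
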