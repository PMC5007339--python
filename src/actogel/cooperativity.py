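"""Hill-equation cooperativity analysis of contraction vs myosin density.

The maximum contractile strain of a disordered actomyosin network is a
switch-like function of the myosin thick-filament density rho (um^-2).  The
transition is modelled by the Hill equation

    eps_max(rho) = eps_sat / (1 + (rho_half / rho)**n)

whose exponent ``n`` (the Hill coefficient) quantifies cooperativity; the
half-saturation density ``rho_half`` is identified with the critical density
rho_c above which networks contract strongly.  Steep Hill fits are
notoriously multimodal in (rho_half, n), so the fit is bounded nonlinear
least squares restarted from several initial exponents and the best optimum
by residual is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "HillFitResult",
    "hill",
    "fit_hill",
    "linear_rate_fit",
    "classify_contractile",
]


def hill(rho, eps_sat: float, rho_half: float, n: float):
    """Hill curve eps_sat / (1 + (rho_half/rho)**n); vectorized over rho.

    All parameters must be positive; densities must be strictly positive.
    """
    if not (eps_sat > 0 and rho_half > 0 and n > 0):
        raise ValueError("eps_sat, rho_half and n must all be positive")
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("densities must be strictly positive")
    out = eps_sat / (1.0 + (rho_half / rho) ** n)
    return out if out.ndim else float(out)


@dataclass
class HillFitResult:
    """Fitted Hill parameters with Jacobian-based standard errors."""

    eps_sat: float
    rho_half: float
    n: float
    eps_sat_se: float
    rho_half_se: float
    n_se: float
    rss: float
    converged: bool
    message: str = ""

    def predict(self, rho):
        return hill(rho, self.eps_sat, self.rho_half, self.n)


#: initial Hill exponents for the multi-start strategy
_N_STARTS = (1.0, 2.0, 5.0, 10.0, 20.0)
_N_BOUNDS = (0.5, 30.0)
_EPS_SAT_MAX = 10.0


def fit_hill(rho, eps_max) -> HillFitResult:
    """Fit the Hill equation to (rho, eps_max) data.

    Multi-start bounded nonlinear least squares: exponent starts at
    {1, 2, 5, 10, 20} with n in [0.5, 30], eps_sat in (0, 10] and rho_half
    within the data range +/- 50%.  Degenerate data (flat response, or no
    coverage of the transition) yields ``converged=False`` with an
    explanatory message rather than a silent bad fit.
    """
    rho = np.asarray(rho, dtype=float)
    eps = np.asarray(eps_max, dtype=float)
    if rho.shape != eps.shape or rho.ndim != 1:
        raise ValueError("rho and eps_max must be 1-D arrays of equal length")
    if rho.size < 5:
        raise ValueError("need at least 5 points to fit the Hill equation")
    if np.any(rho <= 0):
        raise ValueError("densities must be strictly positive")

    def _failure(msg: str) -> HillFitResult:
        return HillFitResult(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, msg
        )

    if np.ptp(eps) < 1e-12 * max(1.0, np.abs(eps).max()):
        return _failure("all eps_max values are equal; the transition is not resolved")

    lo = np.array([1e-9, 0.5 * rho.min(), _N_BOUNDS[0]])
    hi = np.array([_EPS_SAT_MAX, 1.5 * rho.max(), _N_BOUNDS[1]])

    def resid(p):
        return hill(rho, *p) - eps

    best = None
    for n0 in _N_STARTS:
        p0 = np.clip(
            [max(eps.max(), 1e-3), np.median(rho), n0], lo + 1e-12, hi - 1e-12
        )
        try:
            sol = optimize.least_squares(
                resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:  # pragma: no cover - scipy failures are unusual here
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return _failure("nonlinear least squares failed from every start")

    eps_sat, rho_half, n = best.x
    rss = float(2.0 * best.cost)
    m, p = rho.size, 3
    # covariance from the Jacobian at the optimum
    J = best.jac
    try:
        cov = np.linalg.pinv(J.T @ J) * (rss / max(m - p, 1))
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(3, np.nan)

    # sanity: the fit must actually bracket the transition it claims
    converged = True
    message = "ok"
    if rho_half <= rho.min() or rho_half >= rho.max():
        converged = False
        message = (
            f"fitted rho_half = {rho_half:.3g} lies outside the sampled density "
            f"range [{rho.min():.3g}, {rho.max():.3g}]; transition not covered"
        )
    return HillFitResult(
        float(eps_sat), float(rho_half), float(n), *se, rss, converged, message
    )


def linear_rate_fit(rho, rate) -> tuple[float, float, float]:
    """OLS line through (rho, strain rate): returns (slope, intercept, R^2).

    The strain rate of a contracting network grows linearly with myosin
    density, in contrast to the switch-like eps_max.
    """
    rho = np.asarray(rho, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if rho.size < 2 or rho.size != rate.size:
        raise ValueError("need at least 2 (rho, rate) pairs")
    if np.ptp(rho) == 0:
        raise ValueError("all densities equal: design matrix is rank-deficient")
    res = stats.linregress(rho, rate)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def classify_contractile(eps_max: float) -> str:
    """Label a condition by plateau strain: 'high' (>1), 'low' (<0.5), else 'intermediate'."""
    if not np.isfinite(eps_max):
        raise ValueError("eps_max must be finite")
    if eps_max > 1.0:
        return "high"
    if eps_max < 0.5:
        return "low"
    return "intermediate"
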