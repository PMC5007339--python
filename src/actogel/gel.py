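"""Active-gel continuum model of disordered actomyosin contraction.

The network is an overdamped, substrate-coupled Kelvin-Voigt viscoelastic
solid in two dimensions.  Myosin activity inside a disc of radius ``xi``
exerts an isotropic contractile stress that ramps in time,

    sigma_a(r, t) = sigma_0 * (1 - exp(-t / tau_a))   for r <= xi, else 0,

with sigma_0 > 0 representing network tension (it drives inward flow at the
activation boundary).  In radial symmetry the displacement u(r, t)
(outward-positive internally) obeys

    zeta du/dt = d(sigma_rr)/dr + (sigma_rr - sigma_tt) / r

with the plane-stress constitutive law

    sigma_rr = Ebar (u' + nu u/r) + eta d/dt(u')   + sigma_a
    sigma_tt = Ebar (u/r + nu u') + eta d/dt(u/r)  + sigma_a

and Ebar = E / (1 - nu^2).  Since the active stress is isotropic, the
right-hand side collapses to (Ebar + eta d/dt) L[u] + d(sigma_a)/dr with
the axisymmetric vector Laplacian L[u] = u'' + u'/r - u/r^2, which is
discretized by second-order central differences and stepped in time by
Crank-Nicolson; the viscous coupling of du/dt into the flux makes each step
a banded (tridiagonal) linear solve.

Boundary conditions: u(0) = 0 always; the outer edge is clamped
(u(R_domain) = 0) by default, approximating a quiescent far field, with a
stress-free alternative (sigma_rr(R_domain) = 0) available.

The long-time limit has a closed form (piecewise u = A r inside the disc,
u = B r + C / r outside, with constants fixed by continuity of u and
sigma_rr at xi and by the outer boundary condition); it serves as the
solver's independent oracle and is exposed as :func:`steady_state`.

Units: lengths um, times s, stresses in units of E (the solver is linear,
so only the ratio E/sigma_0 matters up to overall scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .contraction import (
    DEFAULT_T1,
    DEFAULT_T2,
    StrainTimecourse,
    max_strain,
    strain_rate,
)
from .fields import VectorFieldSeries

__all__ = [
    "GelParameters",
    "GelSolution",
    "solve_gel",
    "steady_state",
    "sweep_activation",
    "export_velocity_field",
]


@dataclass(frozen=True)
class GelParameters:
    """Parameters of the active Kelvin-Voigt gel.

    Attributes
    ----------
    E : float
        Young's modulus (Pa; the stress unit is arbitrary, only E/sigma_0
        matters for the dimensionless response).
    nu : float
        Poisson ratio, 0 <= nu < 1.
    eta : float
        Network viscosity (Pa s); sets the short-time dissipation.
    zeta : float
        Substrate friction coefficient (Pa s / um^2); makes the dynamics
        overdamped and sets the frictional relaxation time zeta L^2 / E.
    sigma0 : float
        Active stress amplitude (Pa), positive = contractile tension.
    tau_a : float
        Timescale (s) for the accumulation of active stress.
    xi : float
        Activation radius (um).
    r_domain : float or None
        Outer radius (um); defaults to 10 xi.
    n_grid : int
        Radial grid intervals.
    t_total, dt : float
        Simulated time span and time step (s).
    bc : str
        Outer boundary condition: 'clamped' (u = 0) or 'free'
        (sigma_rr = 0).
    plane : str
        'stress' (thin free-standing film, default) or 'strain'.
    """

    E: float = 1.0
    nu: float = 0.5
    eta: float = 10.0
    zeta: float = 0.01
    sigma0: float = 1.0
    tau_a: float = 120.0
    xi: float = 10.0
    r_domain: float | None = None
    n_grid: int = 800
    t_total: float = 600.0
    dt: float = 1.0
    bc: str = "clamped"
    plane: str = "stress"

    def __post_init__(self) -> None:
        for name in ("E", "eta", "zeta", "tau_a", "xi", "dt", "t_total"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be non-negative")
        if not 0 <= self.nu < 1:
            raise ValueError("Poisson ratio must satisfy 0 <= nu < 1")
        if self.R < self.xi - 1e-9:
            raise ValueError("r_domain must be at least xi")
        if self.R < 5 * self.xi - 1e-9:
            warnings.warn(
                "r_domain < 5 xi: the far field is not quiescent and the "
                "clamped edge will suppress contraction", stacklevel=2,
            )
        if self.n_grid < 100:
            raise ValueError("n_grid must be at least 100")
        if self.bc not in ("clamped", "free"):
            raise ValueError("bc must be 'clamped' or 'free'")
        if self.plane not in ("stress", "strain"):
            raise ValueError("plane must be 'stress' or 'strain'")

    @property
    def R(self) -> float:
        return 10.0 * self.xi if self.r_domain is None else self.r_domain

    @property
    def effective_moduli(self) -> tuple[float, float]:
        """(E*, nu*) after the plane-strain <-> plane-stress substitution."""
        if self.plane == "stress":
            return self.E, self.nu
        return self.E / (1.0 - self.nu**2), self.nu / (1.0 - self.nu)

    @property
    def Ebar(self) -> float:
        E_eff, nu_eff = self.effective_moduli
        return E_eff / (1.0 - nu_eff**2)


@dataclass
class GelSolution:
    """Radial displacement/velocity/stress fields from the gel solver.

    ``u`` is outward-positive (so contraction means u < 0); the derived
    strain timecourse and boundary velocity follow the package's
    contraction-positive / inward-positive conventions.
    """

    r: np.ndarray
    times: np.ndarray
    u: np.ndarray  # (nt, nr), um, outward-positive
    params: GelParameters
    _v: np.ndarray | None = dc_field(default=None, repr=False)

    @property
    def v(self) -> np.ndarray:
        """Outward radial velocity du/dt (um/s), shape (nt, nr)."""
        if self._v is None:
            self._v = np.gradient(self.u, self.times, axis=0)
        return self._v

    def _interp_r(self, arr: np.ndarray, r0: float) -> np.ndarray:
        j = np.searchsorted(self.r, r0)
        j = np.clip(j, 1, self.r.size - 1)
        w = (r0 - self.r[j - 1]) / (self.r[j] - self.r[j - 1])
        return (1 - w) * arr[:, j - 1] + w * arr[:, j]

    def boundary_velocity(self) -> np.ndarray:
        """Inward velocity at the activation boundary, -du/dt(xi, t) (um/s)."""
        return -self._interp_r(self.v, self.params.xi)

    def strain_timecourse(
        self, t1: float = DEFAULT_T1, t2: float = DEFAULT_T2
    ) -> StrainTimecourse:
        """Areal strain over the disc, contraction-positive.

        The disc average of div u = u' + u/r is (2/xi^2) int_0^xi (r u)' dr
        = 2 u(xi)/xi, so eps(t) = -2 u(xi, t) / xi exactly.
        """
        eps = -2.0 * self._interp_r(self.u, self.params.xi) / self.params.xi
        return StrainTimecourse(self.times, eps, t1, t2)

    def stresses(self) -> tuple[np.ndarray, np.ndarray]:
        """Total (sigma_rr, sigma_tt) including viscous and active parts, (nt, nr)."""
        p = self.params
        Ebar, (_, nu) = p.Ebar, p.effective_moduli
        du = np.gradient(self.u, self.r, axis=1)
        dv = np.gradient(self.v, self.r, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            uor = np.where(self.r > 0, self.u / self.r, du)
            vor = np.where(self.r > 0, self.v / self.r, dv)
        uor[:, 0] = du[:, 0]
        vor[:, 0] = dv[:, 0]
        act = active_stress_profile(p, self.r)[None, :] * (
            1.0 - np.exp(-self.times / p.tau_a)
        )[:, None]
        s_rr = Ebar * (du + nu * uor) + p.eta * dv + act
        s_tt = Ebar * (uor + nu * du) + p.eta * vor + act
        return s_rr, s_tt


def active_stress_profile(p: GelParameters, r: np.ndarray) -> np.ndarray:
    """Spatial factor of the active stress: sigma_0 inside the disc, 0 outside.

    The node straddling r = xi carries the fractional coverage of its cell,
    which keeps the discrete forcing consistent to O(h) at the interface.
    """
    h = r[1] - r[0]
    return p.sigma0 * np.clip((p.xi - r) / h + 0.5, 0.0, 1.0)


def _laplacian_bands(r: np.ndarray) -> np.ndarray:
    """Tridiagonal bands of L[u] = u'' + u'/r - u/r^2 on interior nodes.

    Returns bands in `solve_banded` layout for the (n-1)-point interior
    system (nodes 1 .. n-1 of a grid with n+1 nodes).
    """
    h = r[1] - r[0]
    ri = r[1:-1]
    lower = 1.0 / h**2 - 1.0 / (2 * h * ri)  # coefficient of u_{i-1}
    diag = -2.0 / h**2 - 1.0 / ri**2
    upper = 1.0 / h**2 + 1.0 / (2 * h * ri)  # coefficient of u_{i+1}
    n = ri.size
    bands = np.zeros((3, n))
    bands[0, 1:] = upper[:-1]
    bands[1, :] = diag
    bands[2, :-1] = lower[1:]
    return bands


def solve_gel(p: GelParameters, store_stride: int = 1) -> GelSolution:
    """Integrate the gel equations of motion; Crank-Nicolson in time.

    Raises if a single step produces a boundary displacement increment
    larger than 10% of xi (time-step instability diagnostic).
    """
    R, N = p.R, p.n_grid
    r = np.linspace(0.0, R, N + 1)
    h = r[1] - r[0]
    Ebar = p.Ebar

    L = _laplacian_bands(r)
    n_int = N - 1

    # LHS = zeta I - eta L - (dt Ebar / 2) L ; RHS = zeta I - eta L + (dt Ebar / 2) L
    lhs = -(p.eta + 0.5 * p.dt * Ebar) * L
    rhs = -(p.eta - 0.5 * p.dt * Ebar) * L
    lhs[1, :] += p.zeta
    rhs[1, :] += p.zeta

    sig_prof = active_stress_profile(p, r)
    # forcing g = d(sigma_a)/dr on interior nodes (central differences)
    g_int = (sig_prof[2:] - sig_prof[:-2]) / (2 * h)

    nt = int(round(p.t_total / p.dt))
    times_all = p.dt * np.arange(nt + 1)
    keep = np.arange(0, nt + 1, store_stride)
    if keep[-1] != nt:
        keep = np.append(keep, nt)
    u_store = np.zeros((keep.size, N + 1))
    u = np.zeros(n_int)

    free_bc = p.bc == "free"
    if free_bc:
        # sigma_rr(R) = 0 with backward difference:
        # Dx(u) = (u_N - u_{N-1})/h + nu u_N / R; CN-averaged elastic +
        # implicit viscous parts give Dx(u^{n+1}) = cf * Dx(u^n).
        _, nu_eff = p.effective_moduli
        cf = (p.eta / p.dt - 0.5 * Ebar) / (p.eta / p.dt + 0.5 * Ebar)
        a_N = 1.0 / h + nu_eff / R
        a_Nm1 = -1.0 / h
        uN = 0.0

    store_ptr = 0
    if keep[0] == 0:
        store_ptr = 1  # u(0) = 0 already stored
    check_lim = 0.1 * p.xi
    for k in range(1, nt + 1):
        t_mid = times_all[k] - 0.5 * p.dt
        f_mid = 1.0 - np.exp(-t_mid / p.tau_a)
        b = (
            rhs[1, :] * u
            + np.concatenate([rhs[0, 1:] * u[1:], [0.0]])
            + np.concatenate([[0.0], rhs[2, :-1] * u[:-1]])
            + p.dt * f_mid * g_int
        )
        if free_bc:
            # eliminate u_N via the boundary row:
            # u_N^{new} = (cf * d_old - a_Nm1 * u_{N-1}^{new}) / a_N
            lhs_k = lhs.copy()
            d_old = a_N * uN + a_Nm1 * u[-1]
            # coupling of the last interior row to u_N:
            c_up = -(p.eta + 0.5 * p.dt * Ebar) * (
                1.0 / h**2 + 1.0 / (2 * h * r[-2])
            )
            c_up_rhs = -(p.eta - 0.5 * p.dt * Ebar) * (
                1.0 / h**2 + 1.0 / (2 * h * r[-2])
            )
            b[-1] += c_up_rhs * uN
            b[-1] -= c_up * (cf * d_old) / a_N
            lhs_k[1, -1] += -c_up * a_Nm1 / a_N
            u_new = solve_banded((1, 1), lhs_k, b)
            uN = (cf * d_old - a_Nm1 * u_new[-1]) / a_N
        else:
            u_new = solve_banded((1, 1), lhs, b)
        if np.max(np.abs(u_new - u)) > check_lim:
            raise RuntimeError(
                f"time-step instability at t = {times_all[k]:.3g} s: boundary "
                f"displacement increment exceeds 10% of xi; reduce dt"
            )
        u = u_new
        if store_ptr < keep.size and k == keep[store_ptr]:
            u_store[store_ptr, 1:-1] = u
            if free_bc:
                u_store[store_ptr, -1] = uN
            store_ptr += 1

    return GelSolution(r, times_all[keep], u_store, p)


def steady_state(p: GelParameters, r: np.ndarray | None = None) -> np.ndarray:
    """Closed-form long-time displacement of the disc-inclusion problem.

    u = A r for r <= xi and u = B r + C / r outside, with constants fixed by
    continuity of u and of total sigma_rr at xi plus the outer boundary
    condition.  Inside the disc the strain u' + u/r = 2A is spatially
    uniform.  Serves as the independent oracle for :func:`solve_gel`.
    """
    R, xi, s0 = p.R, p.xi, p.sigma0
    Ebar = p.Ebar
    _, nu = p.effective_moduli
    if p.bc == "clamped":
        # C = -B R^2 ; A = B (1 - R^2/xi^2) ; sigma_rr continuity gives
        # B = sigma0 xi^2 / (2 Ebar R^2)
        B = s0 * xi**2 / (2.0 * Ebar * R**2)
        C = -B * R**2
        A = B * (1.0 - R**2 / xi**2)
    else:
        # free outer edge: sigma_rr(R) = 0 -> B(1+nu) = C (1-nu)/R^2
        # continuity of u: A xi = B xi + C/xi
        # sigma_rr jump: Ebar[A(1+nu) - B(1+nu) + C(1-nu)/xi^2] = -sigma0... sign:
        # total sigma_rr continuous: Ebar A(1+nu) + s0 = Ebar[B(1+nu) - C(1-nu)/xi^2]
        # solve the 3x3 system directly for robustness
        M = np.array(
            [
                [xi, -xi, -1.0 / xi],
                [Ebar * (1 + nu), -Ebar * (1 + nu), Ebar * (1 - nu) / xi**2],
                [0.0, (1 + nu), -(1 - nu) / R**2],
            ]
        )
        rhs = np.array([0.0, -s0, 0.0])
        A, B, C = np.linalg.solve(M, rhs)
    if r is None:
        r = np.linspace(0.0, R, p.n_grid + 1)
    u = np.where(r <= xi, A * r, B * r + np.divide(C, np.where(r > 0, r, np.inf)))
    return u


def sweep_activation(
    p: GelParameters,
    xi_list,
    stiffness_list,
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
) -> pd.DataFrame:
    """Telescopic sweep: solve the gel for each (xi, E/sigma_0) combination.

    The outer domain scales with the activation radius (R = 10 xi) so that
    the far field is equally quiescent in every run.  Returns one row per
    combination with the max-over-time inward boundary velocity, the
    linear-phase strain rate and the plateau strain, extracted with the same
    conventions as the experimental analysis chain.
    """
    xi_list = list(xi_list)
    stiffness_list = list(stiffness_list)
    if not xi_list or not stiffness_list:
        raise ValueError("xi_list and stiffness_list must be non-empty")
    rows = []
    for stiff in stiffness_list:
        for xi in xi_list:
            pi = replace(p, xi=xi, r_domain=None, E=stiff * p.sigma0)
            sol = solve_gel(pi)
            tc = sol.strain_timecourse(t1, t2)
            rows.append(
                {
                    "xi_um": xi,
                    "E_over_sigma0": stiff,
                    "v_max_um_per_s": float(sol.boundary_velocity().max()),
                    "strain_rate_per_s": strain_rate(tc),
                    "max_strain_rate_per_s": float(
                        np.gradient(tc.strain, tc.times).max()
                    ),
                    "eps_max": max_strain(tc),
                }
            )
    return pd.DataFrame(rows)


def export_velocity_field(
    sol: GelSolution,
    spacing: float = 1.0,
    interval: float = 10.0,
    half_width: float | None = None,
) -> VectorFieldSeries:
    """Rasterize the radial gel flow onto a Cartesian grid.

    Bridges the model to the analysis pipeline: frames are sampled every
    ``interval`` seconds (default 10 s, the acquisition cadence the pipeline
    assumes) on a grid centered on the activation zone.  The activation
    center lands at coordinate (0, 0).
    """
    p = sol.params
    if half_width is None:
        half_width = 2.0 * p.xi
    n_half = int(round(half_width / spacing))
    coords = spacing * np.arange(-n_half, n_half + 1)
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    rr = np.hypot(X, Y)
    t_out = np.arange(0.0, sol.times[-1] + 1e-9, interval)

    # time-interpolate the outward radial velocity, then radially interpolate
    v_t = np.empty((t_out.size, sol.r.size))
    for j in range(sol.r.size):
        v_t[:, j] = np.interp(t_out, sol.times, sol.v[:, j])
    vx = np.empty((t_out.size, coords.size, coords.size))
    vy = np.empty_like(vx)
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(rr > 0, X / rr, 0.0)
        ey = np.where(rr > 0, Y / rr, 0.0)
    for k in range(t_out.size):
        v_out = np.interp(rr.ravel(), sol.r, v_t[k]).reshape(rr.shape)
        vx[k] = v_out * ex
        vy[k] = v_out * ey
    return VectorFieldSeries(
        t_out, vx, vy, spacing, origin=(-n_half * spacing, -n_half * spacing)
    )
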