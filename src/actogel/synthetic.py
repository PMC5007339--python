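"""Synthetic inputs with the statistical structure the analysis assumes.

Every pipeline stage is testable offline: this module fabricates PIV-style
velocity-field series (gel-model-derived or analytic scenarios, with
Gaussian measurement noise and dropped vectors emulating PIV gaps),
maximum-strain vs myosin-density datasets on a Hill curve, and disordered
filament sets (truncated-exponential lengths, uniform orientations) with
the 2-D apolar nematic order parameter to quantify their disorder.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cooperativity import hill
from .fields import VectorFieldSeries
from .gel import GelSolution, export_velocity_field

__all__ = [
    "SynthConfig",
    "gen_piv_series",
    "gen_hill_dataset",
    "gen_filament_set",
    "nematic_order",
]

#: generating parameters of the cooperative transition: half-saturation
#: density (um^-2) and Hill exponent are the fitted experimental values;
#: the saturation strain is a generator choice consistent with strongly
#: contracting networks reaching eps_max > 1.
RHO_HALF = 0.56
N_HILL = 11.0
EPS_SAT = 1.4


@dataclass
class SynthConfig:
    """Configuration of the PIV-series generator.

    ``scenario`` selects the clean field: 'gel-derived' rasterizes a
    :class:`~actogel.gel.GelSolution`; 'analytic-sink' is uniform inward
    radial flow v = -a r_hat; 'rotation' is rigid rotation omega r theta_hat;
    'mixed' is their sum.  Gaussian noise of sd ``noise_sd`` (um/s) is added
    per component and a fraction ``drop_fraction`` of vectors is removed
    (NaN) to emulate PIV interrogation failures, then infilled on ingestion.
    """

    spacing: float = 1.0
    interval: float = 10.0
    noise_sd: float = 0.005
    drop_fraction: float = 0.05
    seed: int = 0
    scenario: str = "gel-derived"
    n_frames: int = 40
    half_width: float = 20.0
    sink_strength: float = 0.05
    omega: float = 0.005

    def __post_init__(self) -> None:
        if not (self.spacing > 0 and self.interval > 0):
            raise ValueError("spacing and interval must be positive")
        if self.noise_sd < 0 or not 0 <= self.drop_fraction < 1:
            raise ValueError("noise_sd must be >= 0 and drop_fraction in [0, 1)")
        if self.scenario not in ("gel-derived", "analytic-sink", "rotation", "mixed"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


def _analytic_components(cfg: SynthConfig, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    r = np.hypot(X, Y)
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(r > 0, X / r, 0.0)
        ey = np.where(r > 0, Y / r, 0.0)
    vx = np.zeros_like(X)
    vy = np.zeros_like(Y)
    if cfg.scenario in ("analytic-sink", "mixed"):
        vx += -cfg.sink_strength * ex
        vy += -cfg.sink_strength * ey
    if cfg.scenario in ("rotation", "mixed"):
        vx += -cfg.omega * Y
        vy += cfg.omega * X
    return vx, vy


def gen_piv_series(cfg: SynthConfig, sol: GelSolution | None = None) -> VectorFieldSeries:
    """Emulated PIV velocity-field series: clean scenario + noise + gaps."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.scenario == "gel-derived":
        if sol is None:
            raise ValueError("scenario 'gel-derived' requires a GelSolution")
        clean = export_velocity_field(
            sol, spacing=cfg.spacing, interval=cfg.interval, half_width=cfg.half_width
        )
        times, vx, vy = clean.times, clean.vx.copy(), clean.vy.copy()
        origin = clean.origin
    else:
        n_half = int(round(cfg.half_width / cfg.spacing))
        coords = cfg.spacing * np.arange(-n_half, n_half + 1)
        fx, fy = _analytic_components(cfg, coords)
        times = cfg.interval * np.arange(cfg.n_frames)
        vx = np.broadcast_to(fx, (cfg.n_frames, *fx.shape)).copy()
        vy = np.broadcast_to(fy, (cfg.n_frames, *fy.shape)).copy()
        origin = (coords[0], coords[0])
    if cfg.noise_sd > 0:
        vx += rng.normal(0.0, cfg.noise_sd, vx.shape)
        vy += rng.normal(0.0, cfg.noise_sd, vy.shape)
    if cfg.drop_fraction > 0:
        drop = rng.random(vx.shape) < cfg.drop_fraction
        vx[drop] = np.nan
        vy[drop] = np.nan
        return VectorFieldSeries.from_raw(times, vx, vy, cfg.spacing, origin)
    return VectorFieldSeries(times, vx, vy, cfg.spacing, origin)


def gen_hill_dataset(
    n: int = 50,
    eps_sat: float = EPS_SAT,
    rho_half: float = RHO_HALF,
    n_hill: float = N_HILL,
    noise: float = 0.05,
    seed: int = 0,
    rho_range: tuple[float, float] = (0.2, 1.2),
) -> pd.DataFrame:
    """Synthetic (rho, eps_max) table emulating the cooperative transition.

    Densities are uniform on ``rho_range`` (um^-2), bracketing the critical
    density; the response is the Hill curve with multiplicative lognormal
    noise, since strain magnitudes span an order of magnitude across the
    transition and additive noise would distort the low-density branch.
    """
    if n < 5:
        raise ValueError("need at least 5 points")
    rng = np.random.default_rng(seed)
    rho = rng.uniform(*rho_range, size=n)
    eps = hill(rho, eps_sat, rho_half, n_hill)
    if noise > 0:
        eps = eps * np.exp(rng.normal(0.0, noise, size=n))
    return pd.DataFrame({"rho_per_um2": rho, "epsilon_max": eps})


@lru_cache(maxsize=8)
def _exp_scale_for_truncated_mean(mean: float, lo: float, hi: float) -> float:
    """Scale beta of an exponential whose [lo, hi]-truncation has the given mean."""

    def trunc_mean(beta: float) -> float:
        a, b = lo / beta, hi / beta
        ea, eb = np.exp(-a), np.exp(-b)
        return beta * ((1 + a) * ea - (1 + b) * eb) / (ea - eb)

    # the truncated mean is monotone in beta and bounded by (lo+hi)/2
    if not lo < mean < (lo + hi) / 2:
        raise ValueError(f"mean {mean} not attainable on [{lo}, {hi}]")
    return brentq(lambda b: trunc_mean(b) - mean, 1e-3, 1e4)


def gen_filament_set(
    n: int,
    mean_length: float = 7.1,
    bounds: tuple[float, float] = (0.56, 25.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disordered filament set: truncated-exponential lengths, uniform angles.

    The exponential scale is corrected so the *truncated* distribution has
    the requested mean contour length (default 7.1 um).  Orientations are
    uniform on [0, pi); the network is apolar-disordered by construction.

    Returns ``(lengths_um, orientations_rad)``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    lo, hi = bounds
    beta = _exp_scale_for_truncated_mean(mean_length, lo, hi)
    rng = np.random.default_rng(seed)
    # inverse-CDF sampling of the truncated exponential
    u = rng.random(n)
    ea, eb = np.exp(-lo / beta), np.exp(-hi / beta)
    lengths = -beta * np.log(ea - u * (ea - eb))
    orientations = rng.uniform(0.0, np.pi, size=n)
    return lengths, orientations


def nematic_order(orientations) -> float:
    """2-D apolar nematic order parameter q = |<exp(2 i theta)>| in [0, 1].

    Invariant under theta -> theta + pi; 1 for perfectly aligned filaments,
    ~1/sqrt(N) for an isotropic sample.
    """
    th = np.asarray(orientations, dtype=float)
    if th.size < 2:
        raise ValueError("need at least 2 orientations")
    return float(np.hypot(np.mean(np.cos(2 * th)), np.mean(np.sin(2 * th))))
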