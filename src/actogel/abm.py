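"""Agent-based model of a 2-D disordered actomyosin network.

F-actin is a bead-spring chain of 280 nm cylindrical segments with fixed
polarity (bead order runs pointed end -> barbed end) and worm-like-chain
bending stiffness kappa = l_p k_B T.  Myosin thick filaments are short
rigid-ish backbones of three 42 nm segments with two motor arms at each of
the four backbone joints (eight arms per motor).  Arms bind to sites spaced
7 nm along actin, walk toward the barbed end with a linear force-velocity
relation, and unbind with load-dependent kinetics: inside the circular
activation disc the off-rate is slow and load-stabilized (catch-like);
outside, motors are non-processive (constant fast off-rate), representing
ATPase-inhibited myosin.  All network connectivity is via motors — there
are no passive crosslinkers.  Dynamics are overdamped and athermal by
default (motor forces dominate); a 1 um rim of the box is softly pinned to
its initial configuration, mimicking the quiescent surrounding network.

Reduced-scale parameter sets (20 um box, ~100 s) make the qualitative
phenomenology — cooperative onset with motor density, slower contraction
for stiff filaments, boundary velocity growing with activation size —
testable in minutes; the full-scale geometry (40 um box, 6 um activation
disc, 400 s) is the default parameterization but is long-running.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky_banded

from . import _abm_kernels as K
from .contraction import StrainTimecourse
from .fields import (
    ActivationRegion,
    VectorFieldSeries,
    divergence,
    infill_gaps,
    region_mean,
)
from .synthetic import gen_filament_set

__all__ = [
    "ABMParams",
    "NetworkState",
    "ABMTrajectory",
    "build_network",
    "step",
    "run",
    "measure_strain",
    "boundary_speed",
    "force_map",
    "total_force",
]

KBT = 4.11e-3  # pN um at room temperature


@dataclass(frozen=True)
class ABMParams:
    """Geometry, mechanics and kinetics of the agent-based network.

    Lengths um, times s, forces pN.  Kinetic constants are standard
    non-muscle myosin II modelling values; the motor:actin ratio ``r_m``
    sets the motor count as r_m * (number of actin segments).
    """

    box_width: float = 40.0
    xi: float = 6.0
    seg_len: float = 0.28
    mean_fil_len: float = 7.1
    len_bounds: tuple[float, float] = (0.56, 25.0)
    lp: float = 20.0                  # persistence length, um
    actin_density: float = 2.5        # filament length per area, um^-1
    backbone_seg: float = 0.042
    n_backbone_seg: int = 3
    arms_per_joint: int = 2
    site_spacing: float = 0.007
    r_m: float = 0.04
    molecules_per_motor: float = 64.0  # myosins per thick filament (each arm
                                       # stands in for a small head ensemble)
    v0: float = 0.14                  # unloaded arm speed, um/s
    f_stall: float = 4.0
    k_on: float = 40.0
    capture_radius: float = 0.02
    k0_off: float = 0.35
    f0_catch: float = 4.0
    slip_force: float = 10.0    # forced unbinding load (catch-slip cutoff), pN
    k_off_out: float = 20.0
    k_seg: float = 100.0              # softened extensional stiffness, pN/um
    k_link: float = 30.0
    kappa_bb: float = 10.0            # backbone straightening stiffness, pN um^2
    gamma: float = 0.2                # bead drag, pN s/um
    k_pin: float = 50.0
    rim: float = 1.0
    dt: float = 5.0e-4
    kin_stride: int = 20
    t_total: float = 400.0
    snapshot_interval: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.xi + self.rim > self.box_width / 2 + self.xi * 0.51:
            # allow large discs, but they must at least fit in the box
            if 2 * self.xi > self.box_width:
                raise ValueError("activation disc does not fit in the box")
        for name in ("box_width", "xi", "seg_len", "mean_fil_len", "dt", "gamma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.r_m < 0:
            raise ValueError("motor:actin ratio must be non-negative")

    @classmethod
    def reduced(cls, **overrides) -> "ABMParams":
        """Reduced-scale defaults for fast qualitative runs (20 um box, 100 s)."""
        base = dict(box_width=20.0, xi=6.0, t_total=100.0)
        base.update(overrides)
        return cls(**base)

    @property
    def center(self) -> tuple[float, float]:
        return (self.box_width / 2, self.box_width / 2)

    @property
    def region(self) -> ActivationRegion:
        return ActivationRegion(self.center, self.xi)


@dataclass
class NetworkState:
    """Flat-array state: beads, chains, motors, arm attachments."""

    X: np.ndarray                 # (N, 2) bead positions
    off: np.ndarray               # (n_chain+1,) chain bead offsets
    chain_of_bead: np.ndarray     # (N,)
    chain_l0: np.ndarray          # (n_chain,) segment rest lengths
    chain_kseg: np.ndarray
    chain_kappa: np.ndarray       # bending rigidity per chain, pN um^2
    n_fil: int                    # filament chains are 0 .. n_fil-1
    n_fil_beads: int
    arm_node: np.ndarray          # (n_arms,) backbone bead index
    arm_motor: np.ndarray         # (n_arms,) motor chain index
    arm_fil: np.ndarray           # (n_arms,) bound filament chain or -1
    arm_s: np.ndarray             # (n_arms,) attachment arc position, um
    pinned: np.ndarray            # (N,) bool
    pin_pos: np.ndarray           # (N, 2)
    bend_bands: np.ndarray        # (3, N) prefactored Cholesky of I+alpha K
    has_bend: np.ndarray          # (n_chain,) bool
    time: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.X.copy(), self.off, self.chain_of_bead, self.chain_l0,
            self.chain_kseg, self.chain_kappa, self.n_fil, self.n_fil_beads,
            self.arm_node, self.arm_motor, self.arm_fil.copy(),
            self.arm_s.copy(), self.pinned, self.pin_pos, self.bend_bands,
            self.has_bend, self.time,
        )


def _implicit_factors(
    off: np.ndarray, chain_kappa: np.ndarray, chain_kseg: np.ndarray,
    chain_l0: np.ndarray, dt: float, gamma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Prefactor the per-chain IMEX matrix I + beta D1^T D1 + alpha D2^T D2.

    beta = dt k_seg / gamma handles the stiff linear part of the
    extensional springs, alpha = dt kappa / (gamma l0^3) the linearized
    curvature; both are unconditionally stable when inverted implicitly.
    """
    n_chain = off.size - 1
    N = off[-1]
    bands = np.zeros((3, N))
    has_impl = np.zeros(n_chain, dtype=np.bool_)
    for c in range(n_chain):
        nb = off[c + 1] - off[c]
        if nb < 2:
            continue
        beta = dt * chain_kseg[c] / gamma
        alpha = dt * chain_kappa[c] / (gamma * chain_l0[c] ** 3)
        D1 = np.zeros((nb - 1, nb))
        for i in range(nb - 1):
            D1[i, i] = -1.0
            D1[i, i + 1] = 1.0
        M = np.eye(nb) + beta * (D1.T @ D1)
        if nb >= 3 and chain_kappa[c] > 0:
            D2 = np.zeros((nb - 2, nb))
            for i in range(nb - 2):
                D2[i, i] = 1.0
                D2[i, i + 1] = -2.0
                D2[i, i + 2] = 1.0
            M += alpha * (D2.T @ D2)
        ab = np.zeros((3, nb))
        for d in range(3):
            for i in range(nb - d):
                ab[d, i] = M[i + d, i]
        cf = cholesky_banded(ab, lower=True)
        bands[:, off[c]: off[c + 1]] = cf
        has_impl[c] = True
    return bands, has_impl


def build_network(p: ABMParams, seed: int | None = None) -> NetworkState:
    """Generate a disordered network: filaments, motors, rim pinning.

    Filament contour lengths are truncated-exponential with the configured
    mean, positions and orientations uniform; motors are straight
    backbones dropped uniformly.  Deterministic given (params, seed).
    """
    seed = p.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    W = p.box_width
    n_fil = max(1, int(round(p.actin_density * W * W / p.mean_fil_len)))
    lengths, angles = gen_filament_set(
        n_fil, p.mean_fil_len, p.len_bounds, seed=rng.integers(2**31)
    )
    n_seg = np.maximum(2, np.round(lengths / p.seg_len).astype(int))
    n_beads_fil = int(np.sum(n_seg + 1))
    n_actin_segments = int(n_seg.sum())
    # r_m is a myosin:actin molecular ratio: ~104 monomers per 280 nm
    # segment (2.7 nm rise), ~16 myosin molecules per thick filament
    # (8 dimeric arms), so thick filaments per actin segment = 6.5 r_m
    monomers_per_seg = p.seg_len / 0.0027
    molecules_per_motor = p.molecules_per_motor
    n_mot = int(round(p.r_m * n_actin_segments * monomers_per_seg / molecules_per_motor))
    nb_bb = p.n_backbone_seg + 1
    N = n_beads_fil + n_mot * nb_bb
    if N > 500_000:
        raise ValueError(f"network of {N} beads exceeds the memory guard")

    n_chain = n_fil + n_mot
    off = np.zeros(n_chain + 1, dtype=np.int64)
    off[1: n_fil + 1] = np.cumsum(n_seg + 1)
    off[n_fil + 1:] = off[n_fil] + nb_bb * np.arange(1, n_mot + 1)
    X = np.empty((N, 2))
    kappa_f = p.lp * KBT
    chain_l0 = np.concatenate([np.full(n_fil, p.seg_len), np.full(n_mot, p.backbone_seg)])
    chain_kseg = np.full(n_chain, p.k_seg)
    chain_kappa = np.concatenate([np.full(n_fil, kappa_f), np.full(n_mot, p.kappa_bb)])
    chain_of_bead = np.empty(N, dtype=np.int64)
    for c in range(n_chain):
        chain_of_bead[off[c]: off[c + 1]] = c

    centers = rng.uniform(0.0, W, size=(n_fil, 2))
    for c in range(n_fil):
        nb = n_seg[c] + 1
        t = p.seg_len * (np.arange(nb) - (nb - 1) / 2)
        d = np.array([np.cos(angles[c]), np.sin(angles[c])])
        X[off[c]: off[c + 1]] = centers[c] + t[:, None] * d[None, :]

    mot_centers = rng.uniform(0.0, W, size=(n_mot, 2))
    mot_angles = rng.uniform(0.0, np.pi, size=n_mot)
    for m in range(n_mot):
        c = n_fil + m
        t = p.backbone_seg * (np.arange(nb_bb) - (nb_bb - 1) / 2)
        d = np.array([np.cos(mot_angles[m]), np.sin(mot_angles[m])])
        X[off[c]: off[c + 1]] = mot_centers[m] + t[:, None] * d[None, :]

    # arms: arms_per_joint at every backbone joint
    n_arms = n_mot * nb_bb * p.arms_per_joint
    arm_node = np.empty(n_arms, dtype=np.int64)
    arm_motor = np.empty(n_arms, dtype=np.int64)
    a = 0
    for m in range(n_mot):
        c = n_fil + m
        for j in range(nb_bb):
            for _ in range(p.arms_per_joint):
                arm_node[a] = off[c] + j
                arm_motor[a] = c
                a += 1
    arm_fil = np.full(n_arms, -1, dtype=np.int64)
    arm_s = np.zeros(n_arms)

    lo, hi = p.rim, W - p.rim
    pinned = (
        (X[:, 0] < lo) | (X[:, 0] > hi) | (X[:, 1] < lo) | (X[:, 1] > hi)
    )
    pin_pos = X.copy()

    bands, has_bend = _implicit_factors(off, chain_kappa, chain_kseg, chain_l0, p.dt, p.gamma)
    return NetworkState(
        X, off, chain_of_bead, chain_l0, chain_kseg, chain_kappa,
        n_fil, n_beads_fil, arm_node, arm_motor, arm_fil, arm_s,
        pinned, pin_pos, bands, has_bend,
    )


def _point_drag(state: NetworkState, p: ABMParams) -> np.ndarray:
    """Per-bead drag for the point-spring forces (arms, pinning).

    gamma_i = gamma + dt * sum(k of pin/arm springs on bead i): backward-
    Euler treatment of the diagonal part of those springs, so the step
    stays stable however many arms crowd one bead.  Beads carrying many
    bound motors genuinely drag more, so the approximation errs in a
    physical direction.
    """
    g = np.full(state.X.shape[0], p.gamma)
    g[state.pinned] += p.dt * p.k_pin
    bound = state.arm_fil >= 0
    if bound.any():
        np.add.at(g, state.arm_node[bound], p.dt * p.k_link)
        fc = state.arm_fil[bound]
        l0 = state.chain_l0[fc]
        base = state.off[fc]
        nseg = state.off[fc + 1] - base - 1
        iseg = np.minimum((state.arm_s[bound] / l0).astype(int), nseg - 1)
        frac = state.arm_s[bound] / l0 - iseg
        np.add.at(g, base + iseg, p.dt * p.k_link * (1 - frac))
        np.add.at(g, base + iseg + 1, p.dt * p.k_link * frac)
    return g


def total_force(state: NetworkState, p: ABMParams, include_pinning: bool = False) -> np.ndarray:
    """Explicit force assembly (including bending) for diagnostics.

    Without pinning every contribution is an internal pair interaction, so
    the column sum vanishes to round-off (momentum sanity).
    """
    F = np.zeros_like(state.X)
    F2 = np.zeros_like(state.X)
    K.compute_forces(
        state.X, F, F2, state.off, state.chain_l0, state.chain_kseg,
        state.chain_kappa, state.pinned, state.pin_pos,
        p.k_pin if include_pinning else 0.0,
        state.arm_node, state.arm_fil, state.arm_s, p.k_link, True, False,
    )
    return F + F2


def step(state: NetworkState, p: ABMParams, rng: np.random.Generator) -> NetworkState:
    """One kinetics block: ``kin_stride`` mechanical sub-steps + one kinetics
    update.  Mutates and returns ``state``; raises on step-size violation."""
    F = np.zeros_like(state.X)
    buf = np.empty(int(np.max(np.diff(state.off))))
    _advance(state, p, rng, F, buf, 1)
    return state


def _advance(
    state: NetworkState, p: ABMParams, rng: np.random.Generator,
    F: np.ndarray, buf: np.ndarray, n_blocks: int,
) -> None:
    F2 = np.zeros_like(F)
    dt_kin = p.dt * p.kin_stride
    W = p.box_width
    cell = max(0.3, 2 * p.capture_radius + p.seg_len / 2)
    ncx = ncy = max(1, int(W / cell))
    n_arms = state.arm_node.size
    max_l0 = float(state.chain_l0.max())
    refine = 5
    trigger = 0.5 * float(state.chain_l0[: max(state.n_fil, 1)].min())
    for _ in range(n_blocks):
        X_save = state.X.copy()
        gamma_pt = _point_drag(state, p)
        md = K.run_mech(
            state.X, F, F2, state.off, state.chain_l0, state.chain_kseg,
            state.chain_kappa, state.pinned, state.pin_pos, p.k_pin,
            state.arm_node, state.arm_fil, state.arm_s, p.k_link,
            state.bend_bands, state.has_bend, p.dt, p.gamma, gamma_pt,
            p.kin_stride, buf,
        )
        if md > trigger:
            state.n_refined = getattr(state, "n_refined", 0) + 1
            # a local configuration (e.g. a folded segment under strong
            # motor load) moved too far in one step: redo the block with a
            # finer time step and the matching implicit factors
            if not hasattr(state, "_fine_bands"):
                state._fine_bands, _ = _implicit_factors(
                    state.off, state.chain_kappa, state.chain_kseg,
                    state.chain_l0, p.dt / refine, p.gamma,
                )
            state.X[:] = X_save
            gamma_fine = p.gamma + (gamma_pt - p.gamma) / refine
            md = K.run_mech(
                state.X, F, F2, state.off, state.chain_l0, state.chain_kseg,
                state.chain_kappa, state.pinned, state.pin_pos, p.k_pin,
                state.arm_node, state.arm_fil, state.arm_s, p.k_link,
                state._fine_bands, state.has_bend, p.dt / refine, p.gamma,
                gamma_fine, p.kin_stride * refine, buf,
            )
        if md > max_l0:
            raise RuntimeError(
                f"step-size violation at t = {state.time:.2f} s: a bead moved "
                f"{md:.3g} um (> one segment length) in a single step; reduce dt"
            )
        if n_arms:
            K.kinetics(
                state.X, state.off, state.chain_of_bead, state.chain_l0,
                state.n_fil_beads, state.arm_node, state.arm_motor,
                state.arm_fil, state.arm_s,
                rng.random(n_arms), rng.random(n_arms),
                dt_kin, p.k_on, p.capture_radius, p.v0, p.f_stall,
                p.k0_off, p.f0_catch, p.slip_force, p.k_off_out, p.k_link,
                p.site_spacing,
                p.center[0], p.center[1], p.xi, cell, ncx, ncy,
            )
        state.time += dt_kin


@dataclass
class ABMTrajectory:
    """Periodic snapshots of the bead positions plus segment tensions."""

    params: ABMParams
    times: np.ndarray             # (n_snap,)
    positions: np.ndarray         # (n_snap, N, 2)
    state: NetworkState           # final state (chain topology is shared)

    @property
    def n_snapshots(self) -> int:
        return self.times.size


def run(p: ABMParams, seed: int | None = None, progress: bool = False) -> ABMTrajectory:
    """Build the network and integrate for ``t_total`` seconds."""
    state = build_network(p, seed)
    rng = np.random.default_rng(
        np.random.default_rng((p.seed if seed is None else seed) + 1).integers(2**31)
    )
    F = np.zeros_like(state.X)
    buf = np.empty(int(np.max(np.diff(state.off))))
    dt_kin = p.dt * p.kin_stride
    n_blocks_total = int(round(p.t_total / dt_kin))
    blocks_per_snap = max(1, int(round(p.snapshot_interval / dt_kin)))
    snaps = [state.X.copy()]
    times = [0.0]
    done = 0
    while done < n_blocks_total:
        nb = min(blocks_per_snap, n_blocks_total - done)
        _advance(state, p, rng, F, buf, nb)
        done += nb
        snaps.append(state.X.copy())
        times.append(state.time)
        if progress:  # pragma: no cover
            print(f"  t = {state.time:7.1f} s  bound arms: {(state.arm_fil >= 0).sum()}")
    return ABMTrajectory(p, np.asarray(times), np.asarray(snaps), state)


def measure_strain(
    traj: ABMTrajectory,
    region: ActivationRegion | None = None,
    spacing: float = 1.0,
) -> StrainTimecourse:
    """Contractile strain eps(t) from binned bead displacements.

    Filament-bead displacements since t = 0 are averaged onto a regular grid
    (by initial bead position), empty cells are median-infilled, and the
    strain follows the field-pipeline convention
    eps = -<div u>_disc (contraction-positive).
    """
    if traj.n_snapshots < 2:
        raise ValueError("need at least 2 snapshots")
    p = traj.params
    region = p.region if region is None else region
    W = p.box_width
    n = int(round(W / spacing)) + 1
    X0 = traj.positions[0, : traj.state.n_fil_beads]
    ii = np.clip(np.round(X0[:, 0] / spacing).astype(int), 0, n - 1)
    jj = np.clip(np.round(X0[:, 1] / spacing).astype(int), 0, n - 1)
    flat = ii * n + jj
    count = np.bincount(flat, minlength=n * n).reshape(n, n)
    nt = traj.n_snapshots
    ux = np.empty((nt, n, n))
    uy = np.empty((nt, n, n))
    for k in range(nt):
        dU = traj.positions[k, : traj.state.n_fil_beads] - X0
        sx = np.bincount(flat, weights=dU[:, 0], minlength=n * n).reshape(n, n)
        sy = np.bincount(flat, weights=dU[:, 1], minlength=n * n).reshape(n, n)
        with np.errstate(invalid="ignore"):
            mx = np.where(count > 0, sx / np.maximum(count, 1), np.nan)
            my = np.where(count > 0, sy / np.maximum(count, 1), np.nan)
        ux[k], _ = infill_gaps(mx)
        uy[k], _ = infill_gaps(my)
    disp = VectorFieldSeries(traj.times, ux, uy, spacing)
    eps = -region_mean(divergence(disp), region)
    return StrainTimecourse(traj.times, eps)


def boundary_speed(
    traj: ABMTrajectory, window: float = 2.0, region: ActivationRegion | None = None
) -> tuple[np.ndarray, float]:
    """Inward radial bead speed in an annulus about the activation boundary.

    Returns the per-interval speeds (um/s) and their time mean.  Bead
    membership of the annulus is re-evaluated per interval, so the measure
    tracks the material boundary as it contracts.
    """
    p = traj.params
    region = p.region if region is None else region
    cx, cy = region.center
    speeds = np.zeros(traj.n_snapshots - 1)
    nf = traj.state.n_fil_beads
    free = ~traj.state.pinned[:nf]
    for k in range(traj.n_snapshots - 1):
        P = traj.positions[k, :nf]
        dxy = P - np.array([cx, cy])
        r = np.hypot(dxy[:, 0], dxy[:, 1])
        sel = (
            (r >= region.radius - window / 2)
            & (r <= region.radius + window / 2)
            & free
        )
        if not sel.any():
            continue
        dt = traj.times[k + 1] - traj.times[k]
        dU = (traj.positions[k + 1, :nf][sel] - P[sel]) / dt
        er = dxy[sel] / r[sel, None]
        speeds[k] = float(np.mean(-(dU * er).sum(axis=1)))
    return speeds, float(speeds.mean())


def force_map(state: NetworkState, p: ABMParams | None = None) -> pd.DataFrame:
    """Axial tension of every filament segment (positive = stretched)."""
    rows = []
    for c in range(state.n_fil):
        lo, hi = state.off[c], state.off[c + 1]
        seg = state.X[lo + 1: hi] - state.X[lo: hi - 1]
        L = np.hypot(seg[:, 0], seg[:, 1])
        tension = state.chain_kseg[c] * (L - state.chain_l0[c])
        mid = 0.5 * (state.X[lo + 1: hi] + state.X[lo: hi - 1])
        for i in range(L.size):
            rows.append(
                {
                    "filament": c,
                    "segment": i,
                    "x_um": mid[i, 0],
                    "y_um": mid[i, 1],
                    "tension_pN": tension[i],
                }
            )
    df = pd.DataFrame(rows)
    if p is not None:
        cx, cy = p.center
        df["inside_activation"] = (
            np.hypot(df.x_um - cx, df.y_um - cy) <= p.xi
        )
    return df
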