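"""Numba kernels for the agent-based actomyosin simulator.

Flat-array layout: all beads (filament beads first, then motor-backbone
beads) live in one (N, 2) position array; chains are delimited by an offset
array.  Bending of semiflexible chains is integrated implicitly (linearized
curvature operator, per-chain banded Cholesky prefactored at build time),
which keeps millimetre-scale persistence lengths stable at the default time
step; extensional springs, motor linkers and rim pinning are explicit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# banded Cholesky (lower, bandwidth 2) for I + alpha * D2^T D2 per chain
# ---------------------------------------------------------------------------


@njit(cache=False)
def banded_chol_solve(cb: np.ndarray, lo: int, n: int, b: np.ndarray) -> None:
    """In-place solve of L L^T x = b for one chain.

    ``cb`` is the global (3, N) factor array; the chain occupies columns
    [lo, lo+n).  Row 0 holds the diagonal of L, rows 1-2 the sub-diagonals.
    """
    # forward substitution L z = b
    for i in range(n):
        s = b[i]
        if i >= 1:
            s -= cb[1, lo + i - 1] * b[i - 1]
        if i >= 2:
            s -= cb[2, lo + i - 2] * b[i - 2]
        b[i] = s / cb[0, lo + i]
    # backward substitution L^T x = z
    for i in range(n - 1, -1, -1):
        s = b[i]
        if i + 1 < n:
            s -= cb[1, lo + i] * b[i + 1]
        if i + 2 < n:
            s -= cb[2, lo + i] * b[i + 2]
        b[i] = s / cb[0, lo + i]


@njit(cache=False)
def compute_forces(
    X: np.ndarray,
    F: np.ndarray,
    F2: np.ndarray,
    off: np.ndarray,
    chain_l0: np.ndarray,
    chain_kseg: np.ndarray,
    chain_kappa: np.ndarray,
    pinned: np.ndarray,
    pin_pos: np.ndarray,
    k_pin: float,
    arm_node: np.ndarray,
    arm_fil: np.ndarray,
    arm_s: np.ndarray,
    k_link: float,
    include_bending: bool,
    stretch_addback: bool,
) -> None:
    """Assemble forces: chain terms into F, point springs into F2 (both zeroed).

    F2 collects the pinning and motor-linker springs, which the integrator
    treats with a per-bead backward-Euler diagonal drag; F collects the
    chain (filament/backbone) terms stepped with the uniform drag and the
    per-chain implicit solve.  With ``include_bending`` the linearized
    curvature force -kappa/l0^3 * D2^T D2 x is added explicitly (for
    diagnostics; the integrator applies bending implicitly).  With
    ``stretch_addback`` the linear chain-spring term +k D1^T D1 x is added,
    cancelling the stiff longitudinal part of the spring force against its
    implicit counterpart in the per-chain matrix (IMEX splitting); only the
    bounded nonlinear remainder is then stepped explicitly.
    """
    N = X.shape[0]
    for i in range(N):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F2[i, 0] = 0.0
        F2[i, 1] = 0.0
    n_chain = off.shape[0] - 1
    # extensional springs
    for c in range(n_chain):
        l0 = chain_l0[c]
        k = chain_kseg[c]
        for i in range(off[c], off[c + 1] - 1):
            dx = X[i + 1, 0] - X[i, 0]
            dy = X[i + 1, 1] - X[i, 1]
            L = np.sqrt(dx * dx + dy * dy)
            if L > 1e-12:
                f = k * (L - l0) / L
                F[i, 0] += f * dx
                F[i, 1] += f * dy
                F[i + 1, 0] -= f * dx
                F[i + 1, 1] -= f * dy
    if stretch_addback:
        for c in range(n_chain):
            nb = off[c + 1] - off[c]
            if nb < 2:
                continue
            k = chain_kseg[c]
            lo = off[c]
            for i in range(nb - 1):
                # +k D1^T D1 x  (minus the zero-rest-length linear spring force)
                dx = X[lo + i + 1, 0] - X[lo + i, 0]
                dy = X[lo + i + 1, 1] - X[lo + i, 1]
                F[lo + i, 0] -= k * dx
                F[lo + i, 1] -= k * dy
                F[lo + i + 1, 0] += k * dx
                F[lo + i + 1, 1] += k * dy
    if include_bending:
        for c in range(n_chain):
            nb = off[c + 1] - off[c]
            if nb < 3 or chain_kappa[c] <= 0.0:
                continue
            kb = chain_kappa[c] / chain_l0[c] ** 3
            lo = off[c]
            for i in range(1, nb - 1):
                cx = X[lo + i - 1, 0] - 2.0 * X[lo + i, 0] + X[lo + i + 1, 0]
                cy = X[lo + i - 1, 1] - 2.0 * X[lo + i, 1] + X[lo + i + 1, 1]
                F[lo + i - 1, 0] -= kb * cx
                F[lo + i - 1, 1] -= kb * cy
                F[lo + i, 0] += 2.0 * kb * cx
                F[lo + i, 1] += 2.0 * kb * cy
                F[lo + i + 1, 0] -= kb * cx
                F[lo + i + 1, 1] -= kb * cy
    # rim pinning (substrate anchoring of the quiescent surround)
    if k_pin > 0.0:
        for i in range(N):
            if pinned[i]:
                F2[i, 0] += k_pin * (pin_pos[i, 0] - X[i, 0])
                F2[i, 1] += k_pin * (pin_pos[i, 1] - X[i, 1])
    # motor arm linker springs
    for a in range(arm_node.shape[0]):
        fc = arm_fil[a]
        if fc < 0:
            continue
        l0 = chain_l0[fc]
        base = off[fc]
        nseg = off[fc + 1] - off[fc] - 1
        iseg = int(arm_s[a] / l0)
        if iseg > nseg - 1:
            iseg = nseg - 1
        frac = arm_s[a] / l0 - iseg
        ax = (1.0 - frac) * X[base + iseg, 0] + frac * X[base + iseg + 1, 0]
        ay = (1.0 - frac) * X[base + iseg, 1] + frac * X[base + iseg + 1, 1]
        node = arm_node[a]
        fx = k_link * (X[node, 0] - ax)
        fy = k_link * (X[node, 1] - ay)
        # force on the filament attachment point, lever-shared by the bead pair
        F2[base + iseg, 0] += (1.0 - frac) * fx
        F2[base + iseg, 1] += (1.0 - frac) * fy
        F2[base + iseg + 1, 0] += frac * fx
        F2[base + iseg + 1, 1] += frac * fy
        F2[node, 0] -= fx
        F2[node, 1] -= fy


@njit(cache=False)
def run_mech(
    X: np.ndarray,
    F: np.ndarray,
    F2: np.ndarray,
    off: np.ndarray,
    chain_l0: np.ndarray,
    chain_kseg: np.ndarray,
    chain_kappa: np.ndarray,
    pinned: np.ndarray,
    pin_pos: np.ndarray,
    k_pin: float,
    arm_node: np.ndarray,
    arm_fil: np.ndarray,
    arm_s: np.ndarray,
    k_link: float,
    cb: np.ndarray,
    has_bend: np.ndarray,
    dt: float,
    gamma: float,
    gamma_pt: np.ndarray,
    n_steps: int,
    buf: np.ndarray,
) -> float:
    """Advance the overdamped dynamics by ``n_steps``; returns the largest
    single-step bead displacement (for the step-size diagnostic).

    IMEX splitting: bounded chain-force remainders are explicit at the
    uniform drag ``gamma``, with the stiff linear stretch and curvature
    operators of every chain inverted implicitly through the prefactored
    banded Cholesky ``cb``; point springs (motor linkers, pinning) advance
    with the per-bead backward-Euler drag ``gamma_pt`` = gamma + dt * sum
    of attached point-spring stiffness, which keeps arbitrarily many bound
    arms per bead stable.
    """
    n_chain = off.shape[0] - 1
    max_disp = 0.0
    inv_g = dt / gamma
    for _ in range(n_steps):
        compute_forces(
            X, F, F2, off, chain_l0, chain_kseg, chain_kappa, pinned, pin_pos,
            k_pin, arm_node, arm_fil, arm_s, k_link, False, True,
        )
        for i in range(X.shape[0]):
            dx = inv_g * F[i, 0] + dt / gamma_pt[i] * F2[i, 0]
            dy = inv_g * F[i, 1] + dt / gamma_pt[i] * F2[i, 1]
            X[i, 0] += dx
            X[i, 1] += dy
            d2 = dx * dx + dy * dy
            if d2 > max_disp:
                max_disp = d2
        # implicit bending relaxation per chain
        for c in range(n_chain):
            if not has_bend[c]:
                continue
            lo = off[c]
            nb = off[c + 1] - lo
            for comp in range(2):
                for i in range(nb):
                    buf[i] = X[lo + i, comp]
                banded_chol_solve(cb, lo, nb, buf)
                for i in range(nb):
                    delta = buf[i] - X[lo + i, comp]
                    if delta * delta > max_disp:
                        max_disp = delta * delta
                    X[lo + i, comp] = buf[i]
    return np.sqrt(max_disp)


# ---------------------------------------------------------------------------
# kinetics: binding, stepping, load-dependent unbinding
# ---------------------------------------------------------------------------


@njit(cache=False)
def _cell_of(x: float, y: float, cell: float, ncx: int, ncy: int) -> tuple:
    ix = int(x / cell)
    iy = int(y / cell)
    if ix < 0:
        ix = 0
    if ix > ncx - 1:
        ix = ncx - 1
    if iy < 0:
        iy = 0
    if iy > ncy - 1:
        iy = ncy - 1
    return ix, iy


@njit(cache=False)
def build_cell_list(
    X: np.ndarray, n_fil_beads: int, cell: float, ncx: int, ncy: int
):
    """Counting-sort cell list over filament beads only."""
    counts = np.zeros(ncx * ncy + 1, dtype=np.int64)
    for b in range(n_fil_beads):
        ix, iy = _cell_of(X[b, 0], X[b, 1], cell, ncx, ncy)
        counts[ix * ncy + iy + 1] += 1
    for k in range(1, counts.shape[0]):
        counts[k] += counts[k - 1]
    order = np.empty(n_fil_beads, dtype=np.int64)
    fill = counts[:-1].copy()
    for b in range(n_fil_beads):
        ix, iy = _cell_of(X[b, 0], X[b, 1], cell, ncx, ncy)
        kcell = ix * ncy + iy
        order[fill[kcell]] = b
        fill[kcell] += 1
    return counts, order


@njit(cache=False)
def kinetics(
    X: np.ndarray,
    off: np.ndarray,
    chain_of_bead: np.ndarray,
    chain_l0: np.ndarray,
    n_fil_beads: int,
    arm_node: np.ndarray,
    arm_motor: np.ndarray,
    arm_fil: np.ndarray,
    arm_s: np.ndarray,
    r_bind: np.ndarray,
    r_unbind: np.ndarray,
    dt_kin: float,
    k_on: float,
    capture: float,
    v0: float,
    f_stall: float,
    k0_off: float,
    f0_catch: float,
    slip_force: float,
    k_off_out: float,
    k_link: float,
    site_spacing: float,
    act_cx: float,
    act_cy: float,
    act_r: float,
    cell: float,
    ncx: int,
    ncy: int,
) -> None:
    """One kinetics substep: unbind/step bound arms, bind free arms.

    Motors whose center lies inside the activation disc use slow, load-
    stabilized (catch-like) unbinding k0*exp(-F/F0); outside the disc the
    off-rate is the constant, fast non-processive rate (myosin with its
    ATPase inhibited).  Bound arms walk toward the barbed end with a linear
    force-velocity relation.
    """
    p_on = 1.0 - np.exp(-k_on * dt_kin)
    counts, order = build_cell_list(X, n_fil_beads, cell, ncx, ncy)
    n_arms = arm_node.shape[0]
    for a in range(n_arms):
        fc = arm_fil[a]
        if fc >= 0:
            # ---- bound arm: load, stepping, unbinding ----
            l0 = chain_l0[fc]
            base = off[fc]
            nseg = off[fc + 1] - base - 1
            L_fil = nseg * l0
            iseg = int(arm_s[a] / l0)
            if iseg > nseg - 1:
                iseg = nseg - 1
            frac = arm_s[a] / l0 - iseg
            ax = (1.0 - frac) * X[base + iseg, 0] + frac * X[base + iseg + 1, 0]
            ay = (1.0 - frac) * X[base + iseg, 1] + frac * X[base + iseg + 1, 1]
            # local barbed-end direction (bead order runs pointed -> barbed)
            tx = X[base + iseg + 1, 0] - X[base + iseg, 0]
            ty = X[base + iseg + 1, 1] - X[base + iseg, 1]
            tn = np.sqrt(tx * tx + ty * ty)
            if tn > 1e-12:
                tx /= tn
                ty /= tn
            node = arm_node[a]
            # load resisting barbed-ward motion
            load = k_link * ((ax - X[node, 0]) * tx + (ay - X[node, 1]) * ty)
            if load < 0.0:
                load = 0.0
            # motor center inside the activation disc?
            mb = off[arm_motor[a]]
            me = off[arm_motor[a] + 1]
            mx = 0.0
            my = 0.0
            for b in range(mb, me):
                mx += X[b, 0]
                my += X[b, 1]
            mx /= me - mb
            my /= me - mb
            inside = (mx - act_cx) ** 2 + (my - act_cy) ** 2 <= act_r * act_r
            if load > slip_force:
                # slip branch of the catch-slip bond: the head yields
                arm_fil[a] = -1
                continue
            if inside:
                k_off = k0_off * np.exp(-load / f0_catch)
            else:
                k_off = k_off_out
            if r_unbind[a] < 1.0 - np.exp(-k_off * dt_kin):
                arm_fil[a] = -1
                continue
            # no ATPase outside the activation disc: the arm holds but
            # cannot step (blebbistatin-inhibited myosin)
            if not inside:
                continue
            v = v0 * (1.0 - load / f_stall)
            if v < 0.0:
                v = 0.0
            s_new = arm_s[a] + v * dt_kin
            if s_new >= L_fil:
                # end dwell: the arm holds at the barbed end (it cannot walk
                # further) until it unbinds stochastically; end-dwelling
                # motors act as polar crosslinks and are what tips the
                # disordered network from extensile polarity sorting to net
                # contraction
                arm_s[a] = L_fil - 0.25 * site_spacing
            else:
                arm_s[a] = s_new
        else:
            # ---- free arm: binding attempt ----
            if r_bind[a] >= p_on:
                continue
            node = arm_node[a]
            px = X[node, 0]
            py = X[node, 1]
            ix, iy = _cell_of(px, py, cell, ncx, ncy)
            best_d2 = capture * capture
            best_b = -1
            best_t = 0.0
            for cx in range(max(0, ix - 1), min(ncx, ix + 2)):
                for cy in range(max(0, iy - 1), min(ncy, iy + 2)):
                    kcell = cx * ncy + cy
                    for kk in range(counts[kcell], counts[kcell + 1]):
                        b = order[kk]
                        # segment b -> b+1 within the same filament
                        if b + 1 >= n_fil_beads:
                            continue
                        if chain_of_bead[b + 1] != chain_of_bead[b]:
                            continue
                        sx = X[b + 1, 0] - X[b, 0]
                        sy = X[b + 1, 1] - X[b, 1]
                        ss = sx * sx + sy * sy
                        if ss < 1e-18:
                            continue
                        t = ((px - X[b, 0]) * sx + (py - X[b, 1]) * sy) / ss
                        if t < 0.0:
                            t = 0.0
                        if t > 1.0:
                            t = 1.0
                        qx = X[b, 0] + t * sx - px
                        qy = X[b, 1] + t * sy - py
                        d2 = qx * qx + qy * qy
                        if d2 < best_d2:
                            best_d2 = d2
                            best_b = b
                            best_t = t
            if best_b >= 0:
                fc = chain_of_bead[best_b]
                l0 = chain_l0[fc]
                s = (best_b - off[fc] + best_t) * l0
                # quantize to the discrete binding sites
                s = np.round(s / site_spacing) * site_spacing
                L_fil = (off[fc + 1] - off[fc] - 1) * l0
                if s >= L_fil:
                    s = L_fil - 0.5 * site_spacing
                if s < 0.0:
                    s = 0.0
                arm_fil[a] = fc
                arm_s[a] = s
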