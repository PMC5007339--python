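"""Shared fixtures: hand-built minimal ABM states for analytic motor tests."""

import numpy as np
import pytest

from actogel.abm import ABMParams, NetworkState, _implicit_factors


def build_two_filament_state(p: ABMParams, n_seg: int = 20, arm_offset: float = 0.0):
    """Two antiparallel filaments bridged by one motor bound at mid-span.

    Filament A runs pointed->barbed along +x at y = +12 nm, filament B
    antiparallel at y = -12 nm; a 4-bead motor backbone sits between them
    with one arm bound to the middle of each filament.  The assembly is
    centered on the activation disc (where motors step).
    """
    l0 = p.seg_len
    nb = n_seg + 1
    XA = np.stack([l0 * np.arange(nb), np.full(nb, 0.012)], axis=1)
    XB = np.stack([l0 * np.arange(nb)[::-1], np.full(nb, -0.012)], axis=1)
    nbb = p.n_backbone_seg + 1
    XM = np.stack(
        [np.full(nbb, n_seg * l0 / 2), p.backbone_seg * (np.arange(nbb) - (nbb - 1) / 2)],
        axis=1,
    )
    X = np.vstack([XA, XB, XM])
    X += np.asarray(p.center) - np.array([n_seg * l0 / 2, 0.0])
    off = np.array([0, nb, 2 * nb, 2 * nb + nbb], dtype=np.int64)
    chain_of_bead = np.repeat([0, 1, 2], [nb, nb, nbb])
    chain_l0 = np.array([l0, l0, p.backbone_seg])
    chain_kseg = np.full(3, p.k_seg)
    chain_kappa = np.array([p.lp * 4.11e-3] * 2 + [p.kappa_bb])
    arm_node = np.array([2 * nb, 2 * nb + nbb - 1], dtype=np.int64)
    arm_motor = np.array([2, 2], dtype=np.int64)
    arm_fil = np.array([0, 1], dtype=np.int64)
    arm_s = np.array([n_seg * l0 / 2 + arm_offset, n_seg * l0 / 2 + arm_offset])
    pinned = np.zeros(X.shape[0], dtype=bool)
    bands, has_impl = _implicit_factors(
        off, chain_kappa, chain_kseg, chain_l0, p.dt, p.gamma
    )
    return NetworkState(
        X.copy(), off, chain_of_bead, chain_l0, chain_kseg, chain_kappa,
        2, 2 * nb, arm_node, arm_motor, arm_fil, arm_s, pinned, X.copy(),
        bands, has_impl,
    )


@pytest.fixture
def kinetics_off_params():
    """Reduced parameters with all stochastic kinetics disabled."""
    return ABMParams.reduced(k_on=0.0, k0_off=0.0, k_off_out=0.0, k_pin=0.0)
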