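"""Agent-based simulator: motor mechanics oracles, invariants, measurement."""

import numpy as np
import pytest
from dataclasses import replace

from actogel.abm import (
    ABMParams,
    ABMTrajectory,
    _advance,
    boundary_speed,
    build_network,
    force_map,
    measure_strain,
    run,
    total_force,
)
from actogel.synthetic import nematic_order

from conftest import build_two_filament_state


def advance(state, p, seconds, seed=0):
    rng = np.random.default_rng(seed)
    F = np.zeros_like(state.X)
    buf = np.empty(int(np.max(np.diff(state.off))))
    n_blocks = int(round(seconds / (p.dt * p.kin_stride)))
    _advance(state, p, rng, F, buf, n_blocks)
    return state


class TestBuild:
    def test_seeded_rebuild_is_identical(self):
        p = ABMParams.reduced(t_total=1.0)
        a = build_network(p, 7)
        b = build_network(p, 7)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.off, b.off)
        assert np.array_equal(a.pinned, b.pinned)

    def test_generated_network_is_disordered_with_correct_lengths(self):
        # full-scale box gives enough filaments for tight statistics
        p = ABMParams(box_width=40.0)
        st = build_network(p, 3)
        n_fil = st.n_fil
        assert n_fil >= 500
        lengths = []
        angles = []
        for c in range(n_fil):
            lo, hi = st.off[c], st.off[c + 1]
            d = st.X[hi - 1] - st.X[lo]
            lengths.append(np.hypot(*d))
            angles.append(np.arctan2(d[1], d[0]) % np.pi)
        assert abs(np.mean(lengths) - 7.1) / 7.1 < 0.05
        assert nematic_order(np.array(angles)) < 3 / np.sqrt(n_fil)

    def test_infeasible_density_guarded(self):
        with pytest.raises(ValueError, match="memory guard"):
            build_network(ABMParams(box_width=40.0, actin_density=1e4), 0)


class TestMechanics:
    def test_no_motors_no_motion(self, kinetics_off_params):
        p = replace(kinetics_off_params, r_m=0.0, t_total=1.0)
        st = build_network(p, 1)
        X0 = st.X.copy()
        advance(st, p, 0.5)
        assert np.allclose(st.X, X0, atol=1e-9)

    def test_momentum_conservation(self):
        p = ABMParams.reduced()
        st = build_network(p, 4)
        rng = np.random.default_rng(0)
        st.X += 0.01 * rng.normal(size=st.X.shape)  # generic non-equilibrium
        # bind some arms so linker forces participate
        advance(st, p, 0.05, seed=1)
        F = total_force(st, p, include_pinning=False)
        assert (st.arm_fil >= 0).any()
        assert np.abs(F.sum(axis=0)).max() < 1e-9 * np.abs(F).max()

    def test_two_filament_sliding_bounded_by_twice_v0(self, kinetics_off_params):
        p = kinetics_off_params
        st = build_two_filament_state(p)
        nb = st.off[1]
        comA0, comB0 = st.X[:nb, 0].mean(), st.X[nb: 2 * nb, 0].mean()
        T = 4.0
        advance(st, p, T)
        vA = (st.X[:nb, 0].mean() - comA0) / T
        vB = (st.X[nb: 2 * nb, 0].mean() - comB0) / T
        sliding = abs(vA - vB)
        assert sliding <= 2 * p.v0 + 1e-9
        # the only load is viscous drag of the filaments themselves, so the
        # sliding speed stays within ~25% of the zero-load limit
        assert sliding > 0.7 * 2 * p.v0

    def test_step_size_violation_aborts(self, kinetics_off_params):
        p = kinetics_off_params
        st = build_two_filament_state(p)
        # yank the motor 60 um away: the linker relaxation exceeds one
        # segment length per step even after time-step refinement
        st.X[st.off[2]:, 0] += 60.0
        with pytest.raises(RuntimeError, match="step-size violation"):
            advance(st, p, 0.01)

    def test_force_map_zero_at_rest_and_tension_under_stretch(self, kinetics_off_params):
        p = kinetics_off_params
        st = build_two_filament_state(p)
        fm = force_map(st, p)
        assert np.allclose(fm.tension_pN, 0.0, atol=1e-12)
        # stretch filament A axially by moving its last bead
        delta = 0.02
        st.X[st.off[1] - 1, 0] += delta
        fm = force_map(st, p)
        assert np.isclose(fm.tension_pN.iloc[st.off[1] - 2], p.k_seg * delta)


class TestKinetics:
    def test_outside_residence_time_matches_off_rate(self):
        # motors outside the activation disc detach at the non-processive
        # rate; across replicates the mean residence time approximates the
        # geometric-waiting expectation dt_kin / (1 - exp(-k_off_out dt_kin))
        p = ABMParams.reduced(k_on=0.0, v0=0.0)
        dt_kin = p.dt * p.kin_stride
        n_rep = 60
        waits = []
        F = buf = None
        for rep in range(n_rep):
            st = build_two_filament_state(p)
            st.X[:, 0] += 8.0  # move outside the activation disc
            st.pin_pos = st.X.copy()
            rng = np.random.default_rng(1000 + rep)
            if F is None:
                F = np.zeros_like(st.X)
                buf = np.empty(int(np.max(np.diff(st.off))))
            unbound_at = np.full(2, np.nan)
            for blk in range(1, 200):
                _advance(st, p, rng, F, buf, 1)
                newly = (st.arm_fil < 0) & np.isnan(unbound_at)
                unbound_at[newly] = blk * dt_kin
                if not np.isnan(unbound_at).any():
                    break
            waits.extend(unbound_at[~np.isnan(unbound_at)])
        expected = dt_kin / (1.0 - np.exp(-p.k_off_out * dt_kin))
        got = np.mean(waits)
        se = expected / np.sqrt(len(waits))
        assert abs(got - expected) < 3 * se

    def test_bound_arm_outside_disc_detaches_fast(self):
        p = ABMParams.reduced(k_on=0.0)
        st = build_two_filament_state(p)
        # move the whole assembly outside the activation disc
        st.X[:, 0] += 8.0
        advance(st, p, 1.0, seed=5)
        assert np.all(st.arm_fil == -1)

    def test_bound_arm_inside_disc_persists_much_longer(self):
        # inside the disc the unloaded catch off-rate is 0.35/s (dwell ~3 s)
        # vs 20/s outside: over 1 s most inside arms stay bound
        p = ABMParams.reduced(k_on=0.0)
        survived = 0
        for rep in range(10):
            st = build_two_filament_state(p)
            st.pin_pos = st.X.copy()
            advance(st, p, 1.0, seed=100 + rep)
            survived += int((st.arm_fil >= 0).sum())
        assert survived >= 0.5 * 20  # expectation ~ exp(-0.35) = 70%


class TestRunAndMeasure:
    def test_short_run_deterministic(self):
        p = ABMParams.reduced(t_total=1.0, snapshot_interval=0.5)
        a = run(p, 5)
        b = run(p, 5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.state.arm_fil, b.state.arm_fil)

    def test_affine_contraction_strain(self):
        p = ABMParams.reduced(t_total=1.0)
        st = build_network(p, 2)
        a = 0.01
        c = np.array(p.center)
        X1 = st.X - a * (st.X - c)
        traj = ABMTrajectory(p, np.array([0.0, 10.0]),
                            np.stack([st.X, X1]), st)
        tc = measure_strain(traj)
        # affine shrink u = -a (x - c): div u = -2a, strain = +2a
        assert np.isclose(tc.strain[-1], 2 * a, rtol=0.05)

    def test_rigid_translation_zero_strain(self):
        p = ABMParams.reduced(t_total=1.0)
        st = build_network(p, 2)
        traj = ABMTrajectory(
            p, np.array([0.0, 10.0]), np.stack([st.X, st.X + 0.3]), st
        )
        tc = measure_strain(traj)
        assert abs(tc.strain[-1]) < 1e-6

    def test_no_motors_strain_stays_at_noise_floor(self):
        p = ABMParams.reduced(r_m=0.0, t_total=5.0)
        traj = run(p, 3)
        tc = measure_strain(traj)
        assert np.max(np.abs(tc.strain)) < 0.01

    def test_boundary_speed_of_synthetic_inflow(self):
        p = ABMParams.reduced(t_total=1.0)
        st = build_network(p, 2)
        c = np.array(p.center)
        d = st.X - c
        r = np.hypot(d[:, 0], d[:, 1])[:, None]
        X1 = st.X - 0.1 * d / np.maximum(r, 1e-9)  # uniform inward 0.1 um
        traj = ABMTrajectory(p, np.array([0.0, 10.0]), np.stack([st.X, X1]), st)
        speeds, mean_speed = boundary_speed(traj)
        assert np.isclose(mean_speed, 0.01, rtol=0.05)
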