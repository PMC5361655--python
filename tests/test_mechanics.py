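"""Musculoskeletal mechanics: scaling, Hill model, geometry, dynamics."""

import numpy as np
import pytest

from reflexwalk.anthropometry import scale_anthropometry
from reflexwalk.control import ReflexParameters
from reflexwalk.muscle import (
    MUSCLES,
    default_muscles,
    force_velocity,
    force_velocity_inverse,
    mtu_kinematics,
    mtu_length,
    mtu_moment_arm,
    muscle_force,
)
from reflexwalk.walker import ReflexWalker


# ---------------------------------------------------------------------------
# anthropometric scaling
# ---------------------------------------------------------------------------

class TestAnthropometry:
    @pytest.mark.parametrize("height,mass", [(1.8, 80.0), (1.75, 64.0),
                                             (1.8, 75.0)])
    def test_subject_scalings_satisfy_invariants(self, height, mass):
        b = scale_anthropometry(height, mass)
        total = b.segments["hat"].mass + 2 * sum(
            b.segments[s].mass for s in ("thigh", "shank", "foot"))
        assert total == pytest.approx(mass, abs=1e-9)
        for seg in b.segments.values():
            assert seg.mass > 0 and seg.length > 0 and seg.inertia > 0
        for j in b.joints.values():
            assert j.lower < j.upper

    def test_lengths_scale_with_height_masses_with_mass(self):
        a = scale_anthropometry(1.8, 80.0)
        b = scale_anthropometry(1.8, 80.0 * 1.5)  # heavier, same height
        for name in a.segments:
            assert b.segments[name].length == pytest.approx(a.segments[name].length)
            assert b.segments[name].mass == pytest.approx(1.5 * a.segments[name].mass)
        c = scale_anthropometry(1.98, 80.0)
        for name in a.segments:
            assert c.segments[name].length == pytest.approx(
                1.1 * a.segments[name].length)

    @pytest.mark.parametrize("height,mass", [(1.2, 80), (2.5, 80), (1.8, 30),
                                             (1.8, 150)])
    def test_out_of_range_rejected_with_message(self, height, mass):
        with pytest.raises(ValueError, match="range"):
            scale_anthropometry(height, mass)


# ---------------------------------------------------------------------------
# Hill-type muscle model
# ---------------------------------------------------------------------------

class TestMuscleForce:
    @pytest.mark.parametrize("mtu", default_muscles(), ids=lambda m: m.name)
    def test_isometric_maximum_is_f_max(self, mtu):
        assert muscle_force(1.0, mtu.l_opt, 0.0, mtu) == pytest.approx(mtu.f_max)

    @pytest.mark.parametrize("mtu", default_muscles(), ids=lambda m: m.name)
    def test_linear_in_activation_at_optimum(self, mtu):
        assert muscle_force(0.5, mtu.l_opt, 0.0, mtu) == pytest.approx(0.5 * mtu.f_max)

    def test_zero_activation_leaves_passive_only(self):
        mtu = default_muscles()[7]  # SOL
        assert muscle_force(0.0, mtu.l_opt, 0.0, mtu) == 0.0
        # stretched beyond optimum: passive element engages
        assert muscle_force(0.0, 1.3 * mtu.l_opt, 0.0, mtu) > 0.0

    def test_force_never_negative_and_clamps_inputs(self):
        mtu = default_muscles()[0]
        rng = np.random.default_rng(2)
        for _ in range(100):
            f = muscle_force(rng.uniform(-1, 2), rng.uniform(0, 3) * mtu.l_opt,
                             rng.uniform(-3, 3) * mtu.v_max, mtu)
            assert f >= 0.0

    def test_force_velocity_shape_and_inverse(self):
        v_max = 8.0
        assert force_velocity(v_max, v_max) == 0.0
        assert force_velocity(0.0, v_max) == pytest.approx(1.0)
        vs = np.linspace(-2 * v_max, v_max, 201)
        fv = np.array([force_velocity(v, v_max) for v in vs])
        assert np.all(np.diff(fv) <= 1e-12)  # monotone non-increasing in v
        # eccentric branch saturates near its plateau (asymptote slightly
        # above N for very fast lengthening)
        assert fv.max() <= 1.51
        # inverse round-trips through the forward relation
        for f in np.linspace(0.01, 1.49, 40):
            v = force_velocity_inverse(f, v_max)
            assert force_velocity(v, v_max) == pytest.approx(f, abs=2e-3)


class TestMtuGeometry:
    @pytest.mark.parametrize("mtu", default_muscles(), ids=lambda m: m.name)
    def test_moment_arm_matches_length_derivative(self, mtu):
        """d(l_mtu)/d(phi) equals the signed moment arm on a 100-point grid."""
        rng = np.random.default_rng(1)
        base = rng.uniform(-0.3, 0.3, 3)
        h = 1e-7
        for joint in {p.joint for p in mtu.paths}:
            for phi in np.linspace(-0.8, 0.8, 100):
                ang = base.copy()
                ang[joint] = phi
                up, dn = ang.copy(), ang.copy()
                up[joint] += h
                dn[joint] -= h
                fd = (mtu_length(mtu, up) - mtu_length(mtu, dn)) / (2 * h)
                arm = mtu_moment_arm(mtu, joint, ang)
                assert fd == pytest.approx(arm, rel=1e-6, abs=1e-12)

    def test_monoarticular_length_fixed_under_other_joints(self):
        sol = default_muscles()[MUSCLES.index("SOL")]
        l0 = mtu_length(sol, [0.1, 0.2, 0.05])
        l1 = mtu_length(sol, [-0.5, 1.0, 0.05])  # hip/knee moved, ankle fixed
        assert l1 == pytest.approx(l0)

    def test_sol_dorsiflexion_ramp_lengthens_throughout(self):
        """8 deg dorsiflexion at 250 deg/s: SOL lengthening velocity stays
        positive over the whole 32 ms ramp (finite-difference oracle)."""
        sol = default_muscles()[MUSCLES.index("SOL")]
        rate = np.deg2rad(250.0)
        ts = np.linspace(0.0, 8 / 250.0, 33)
        phis = -0.1 + rate * ts
        lens = np.array([mtu_length(sol, [0, 0, p]) for p in phis])
        assert np.all(np.diff(lens) > 0)
        for p in phis:
            _, v = mtu_kinematics(sol, [0, 0, p], [0, 0, rate])
            assert v > 0

    def test_gas_is_biarticular(self):
        gas = default_muscles()[MUSCLES.index("GAS")]
        ang = [0.0, 0.3, 0.1]
        l0 = mtu_length(gas, ang)
        assert mtu_length(gas, [0, 0.5, 0.1]) != pytest.approx(l0)
        assert mtu_length(gas, [0, 0.3, 0.3]) != pytest.approx(l0)
        assert mtu_moment_arm(gas, 1, ang) != 0.0
        assert mtu_moment_arm(gas, 2, ang) != 0.0


# ---------------------------------------------------------------------------
# rigid-body dynamics
# ---------------------------------------------------------------------------

def _sympy_accelerations(SEG, qv, qdv):
    """Independent Lagrangian derivation of the 7-link accelerations."""
    import sympy as sp

    t = sp.Symbol("t")
    funcs = [sp.Function(f"q{i}")(t) for i in range(9)]
    x, y, th = funcs[0], funcs[1], funcs[2]
    g = SEG[18]
    T = 0
    V = 0
    cx = x + SEG[2] * sp.sin(th)
    cy = y + SEG[2] * sp.cos(th)
    T += SEG[0] / 2 * (sp.diff(cx, t) ** 2 + sp.diff(cy, t) ** 2) \
        + SEG[1] / 2 * sp.diff(th, t) ** 2
    V += SEG[0] * g * cy
    for leg in range(2):
        b = 3 + 3 * leg
        a_th = funcs[b] - th
        a_sh = a_th - funcs[b + 1]
        beta = a_sh + funcs[b + 2]
        u1 = (sp.sin(a_th), -sp.cos(a_th))
        u2 = (sp.sin(a_sh), -sp.cos(a_sh))
        thx, thy = x + SEG[6] * u1[0], y + SEG[6] * u1[1]
        T += SEG[3] / 2 * (sp.diff(thx, t) ** 2 + sp.diff(thy, t) ** 2) \
            + SEG[4] / 2 * sp.diff(a_th, t) ** 2
        V += SEG[3] * g * thy
        kx, ky = x + SEG[5] * u1[0], y + SEG[5] * u1[1]
        shx, shy = kx + SEG[10] * u2[0], ky + SEG[10] * u2[1]
        T += SEG[7] / 2 * (sp.diff(shx, t) ** 2 + sp.diff(shy, t) ** 2) \
            + SEG[8] / 2 * sp.diff(a_sh, t) ** 2
        V += SEG[7] * g * shy
        ax, ay = kx + SEG[9] * u2[0], ky + SEG[9] * u2[1]
        ex = SEG[13] * sp.cos(beta) + SEG[14] * sp.sin(beta)
        ey = SEG[13] * sp.sin(beta) - SEG[14] * sp.cos(beta)
        fx, fy = ax + ex, ay + ey
        T += SEG[11] / 2 * (sp.diff(fx, t) ** 2 + sp.diff(fy, t) ** 2) \
            + SEG[12] / 2 * sp.diff(beta, t) ** 2
        V += SEG[11] * g * fy
    L = T - V
    dq = [sp.diff(f, t) for f in funcs]
    eqs = [sp.diff(sp.diff(L, dq[i]), t) - sp.diff(L, funcs[i]) for i in range(9)]
    dd = sp.symbols("dd0:9")
    subs = {sp.diff(funcs[i], t, 2): dd[i] for i in range(9)}
    subs.update({sp.diff(funcs[i], t): qdv[i] for i in range(9)})
    subs.update({funcs[i]: qv[i] for i in range(9)})
    eqs_n = [sp.expand(e).subs(subs, simultaneous=True) for e in eqs]
    A = np.zeros((9, 9))
    bb = np.zeros(9)
    for i, e in enumerate(eqs_n):
        e = sp.nsimplify(e, rational=False)
        for j in range(9):
            A[i, j] = float(sp.diff(e, dd[j]))
        bb[i] = -float(e.subs({s: 0 for s in dd}))
    return np.linalg.solve(A, bb)


class TestDynamics:
    def test_accelerations_match_sympy_lagrangian(self):
        """Hand-assembled equations of motion against an independent
        Lagrangian derivation at a random state."""
        from reflexwalk._kernel import _assemble_dynamics

        w = ReflexWalker()
        rng = np.random.default_rng(0)
        qv = rng.uniform(-0.5, 0.5, 9)
        qv[1] = 1.0
        qdv = rng.uniform(-1, 1, 9)
        Q = np.zeros(9)
        M = np.zeros((9, 9))
        _assemble_dynamics(qv, qdv, w.SEG, Q, M)
        qdd = np.linalg.solve(M, Q)
        expected = _sympy_accelerations(w.SEG, qv, qdv)
        np.testing.assert_allclose(qdd, expected, rtol=1e-9, atol=1e-9)

    def test_ballistic_energy_conservation(self):
        """Airborne passive multi-pendulum: <= 0.1% energy drift per second
        at the default step size."""
        w = ReflexWalker()
        w.MF[:, 0] = 0.0  # muscles off
        p = ReflexParameters()
        st = w.initial_state(v0=0.0)
        st.q[1] += 6.0
        st.qd[:] = 0.0
        st.q[6] = 1.0  # one leg raised: swings passively
        E0 = w.mechanical_energy(st)
        traj, st2 = w.simulate(p, 1.0, state=st)
        assert not traj.fell
        E1 = w.mechanical_energy(st2)
        assert abs(E1 - E0) / abs(E0) < 1e-3

    def test_simulation_is_bit_deterministic(self):
        w = ReflexWalker()
        p = ReflexParameters()
        t1, s1 = w.simulate(p, 0.5)
        t2, s2 = w.simulate(p, 0.5)
        np.testing.assert_array_equal(t1.rec, t2.rec)
        np.testing.assert_array_equal(s1.q, s2.q)
        np.testing.assert_array_equal(s1.lce, s2.lce)


class TestStepDynamics:
    def test_airborne_no_gravity_freezes_mechanics(self):
        """Zero stimulation, no gravity, no contact, muscles detached:
        coordinates unchanged, activations decay toward zero."""
        w = ReflexWalker()
        w.MF[:, 0] = 0.0  # no muscle forces: pure mechanics
        st = w.initial_state(v0=0.0)
        st.q[1] += 2.0
        st.qd[:] = 0.0
        st.act[:] = 0.4
        a_prev = st.act.copy()
        q0 = st.q.copy()
        for _ in range(50):
            st = w.step_dynamics(st, np.zeros((2, 9)), gravity=False)
        np.testing.assert_allclose(st.q, q0, atol=1e-12)
        np.testing.assert_array_equal(st.qd, np.zeros(9))
        assert np.all(st.act < a_prev)
        assert np.all(st.act > 0)

    def test_step_determinism(self):
        w = ReflexWalker()
        st = w.initial_state(v0=0.5)
        stim = np.full((2, 9), 0.3)
        a = w.step_dynamics(st, stim)
        b = w.step_dynamics(st, stim)
        np.testing.assert_array_equal(a.q, b.q)
        np.testing.assert_array_equal(a.qd, b.qd)
        np.testing.assert_array_equal(a.lce, b.lce)


class TestContact:
    def test_airborne_foot_zero_force(self):
        w = ReflexWalker()
        st = w.initial_state(v0=0.0)
        st.q[1] += 1.0
        assert np.all(w.contact_forces(st) == 0.0)

    def test_static_loaded_foot_no_tangential_at_zero_slip(self):
        w = ReflexWalker()
        st = w.initial_state(v0=0.0)
        st.qd[:] = 0.0
        st.q[1] -= 0.005  # press the stance foot into the ground
        F = w.contact_forces(st)
        loaded = F[:, 1] > 0
        assert loaded.any()
        # anchors at current positions, zero velocity: no friction force
        for ci in np.where(loaded)[0]:
            assert F[ci, 0] == pytest.approx(0.0, abs=1e-9)

    def test_normal_force_complementarity_during_walking(self):
        """Normal force is zero whenever a point does not penetrate."""
        from reflexwalk._kernel import REC_GRF

        w = ReflexWalker()
        p = ReflexParameters()
        traj, _ = w.simulate(p, 0.4)
        grf_y = traj.rec[:, [REC_GRF + 1, REC_GRF + 3]]
        assert np.all(grf_y >= -1e-9)
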