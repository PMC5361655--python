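"""Numba simulation kernel for the sagittal-plane reflex walker.

Everything inside this module is plain-array, loop-style code so the whole
fixed-step integration loop compiles with numba.  The public classes in
:mod:`reflexwalk.walker` pack model constants into the arrays consumed here.

Generalized coordinates (9):
    q = [x_hip, y_hip, theta_trunk, hipL, kneeL, ankleL, hipR, kneeR, ankleR]

with trunk forward lean positive, hip flexion positive, knee flexion
positive (0 = straight) and ankle dorsiflexion positive.  Absolute segment
angles: thigh ``a_th = hip - theta``, shank ``a_sh = a_th - knee``, foot
pitch ``beta = a_sh + ankle``; a segment's "down" unit vector is
``(sin a, -cos a)``.

The equations of motion are assembled per step from per-segment
center-of-mass Jacobians: ``M = sum m J^T J + I w^T w`` and the right-hand
side collects gravity, contact, joint torques and the velocity-product
(bias) terms; a 9x9 solve yields the accelerations, integrated
semi-implicitly (symplectic Euler).  During an imposed ankle-rotation
disturbance the ankle coordinate is servo-prescribed by solving the
constrained system exactly.

Muscle order (per leg): HFL GLU HAM RF VAS BFSH GAS SOL TA; muscle arrays
are length 18 with the left leg first.
"""

import numpy as np
from numba import njit

from .muscle import (
    force_length,
    force_velocity_inverse,
    parallel_force,
    tendon_force,
)

# muscle indices
HFL, GLU, HAM, RF, VAS, BFSH, GAS, SOL, TA = range(9)
NM = 9

# controller parameter indices (see control.PARAM_NAMES)
P_G_SOL, P_G_TA, P_LOFF_TA, P_GS_TA, P_G_GAS, P_G_VAS, P_LOFF_KNEE, \
    P_KKNEE, P_S0_VAS, P_KP_TRUNK, P_KD_TRUNK, P_THETA_REF, P_KHAM_TR, \
    P_KHFL_TR, P_DS_HFL, P_DS_GLU, P_S0_HFL_SW, P_G_HFL, P_LOFF_HFL, \
    P_GHAM_HFL, P_LOFF_HAM, P_KLEAN, P_GHAM_SW, P_KGLU_HAM, P_G_BFSH, \
    P_LOFF_BFSH, P_GVAS_LSW, P_LOFF_VAS_LSW, P_GGAS_LSW, P_S0_GLU, \
    P_S0_HAM, P_KDS_VAS = range(32)
NPARAM = 32

# disturbance protocol codes
D_NONE, D_MMR, D_TR, D_SR, D_TRIP, D_SLIP = 0, 1, 2, 3, 4, 5

# recording layout
REC_T = 0
REC_Q = 1          # 9
REC_QD = 10        # 9
REC_STIM = 19      # 18
REC_ACT = 37       # 18
REC_LCE = 55       # 18 (l_ce / l_opt)
REC_VCE = 73       # 18 (v_ce / v_max, shortening positive)
REC_F = 91         # 18 (F / F_max)
REC_GRF = 109      # 4 (legL x,y, legR x,y)
REC_LOAD = 113     # 2
REC_GATE = 115     # 2
REC_NCOL = 117

S_MIN = 0.01       # baseline stimulation tone
TAU_ACT = 0.010    # excitation-activation time constant [s]

# metabolic constants: activation/maintenance rate per muscle mass, and
# shortening-heat fraction on top of positive CE work
H_AM = 128.0       # W / kg of active muscle
SHORT_HEAT = 0.25


@njit(cache=True)
def _clip(x, lo, hi):
    if x < lo:
        return lo
    if x > hi:
        return hi
    return x


@njit(cache=True)
def _mtu_geometry(q, qd, b, MF, MI, lmtu, vmtu, arms):
    """MTU lengths, velocities and joint moment arms for one leg.

    ``b`` is the first joint index of the leg in q (3 or 6).  ``arms`` is
    (NM, 3): d(l_mtu)/d(phi) per joint.
    """
    for m in range(NM):
        l = MF[m, 1] + MF[m, 3]  # l_opt + l_slack
        v = 0.0
        for j in range(3):
            arms[m, j] = 0.0
        for pth in range(MI[m, 0]):
            jl = MI[m, 2 + pth]          # 0 hip, 1 knee, 2 ankle
            atype = MI[m, 4 + pth]
            r0 = MF[m, 5 + 6 * pth]
            phimax = MF[m, 6 + 6 * pth]
            phiref = MF[m, 7 + 6 * pth]
            rho = MF[m, 8 + 6 * pth]
            sgn = MF[m, 9 + 6 * pth]
            phi = q[b + jl]
            phid = qd[b + jl]
            # the CE length excursion is attenuated by the pennation factor
            # rho, while the torque-producing arm is the full geometric r(phi)
            if atype == 0:
                dl = sgn * rho * r0 * (phi - phiref)
                arm_l = sgn * rho * r0
                arm_t = sgn * r0
            else:
                dl = sgn * rho * r0 * (np.sin(phi - phimax) - np.sin(phiref - phimax))
                c = np.cos(phi - phimax)
                arm_l = sgn * rho * r0 * c
                arm_t = sgn * r0 * c
            l += dl
            v += arm_l * phid
            arms[m, jl] += arm_t
        lmtu[m] = l
        vmtu[m] = v


@njit(cache=True)
def _leg_point(q, qd, SEG, b, ox, oy):
    """Position and velocity of a foot-frame point (ox, oy) offset from the
    ankle, plus the chain data needed for J^T F accumulation.

    Returns (px, py, vx, vy, uthx, uthy, ushx, ushy, perpx, perpy)
    where (uth, ush) are l * u'(alpha) for thigh/shank and perp is the
    derivative of the rotated foot offset w.r.t. beta.
    """
    th = q[2]
    a_th = q[b] - th
    a_sh = a_th - q[b + 1]
    beta = a_sh + q[b + 2]
    a_th_d = qd[b] - qd[2]
    a_sh_d = a_th_d - qd[b + 1]
    beta_d = a_sh_d + qd[b + 2]
    l_th = SEG[5]
    l_sh = SEG[9]
    s1, c1 = np.sin(a_th), np.cos(a_th)
    s2, c2 = np.sin(a_sh), np.cos(a_sh)
    sb, cb = np.sin(beta), np.cos(beta)
    # rotated offset e = R(beta) (ox, oy)
    ex = ox * cb - oy * sb
    ey = ox * sb + oy * cb
    px = q[0] + l_th * s1 + l_sh * s2 + ex
    py = q[1] - l_th * c1 - l_sh * c2 + ey
    uthx, uthy = l_th * c1, l_th * s1     # d/d(a_th)
    ushx, ushy = l_sh * c2, l_sh * s2     # d/d(a_sh)
    perpx, perpy = -ey, ex                # d/d(beta)
    vx = qd[0] + a_th_d * uthx + a_sh_d * ushx + beta_d * perpx
    vy = qd[1] + a_th_d * uthy + a_sh_d * ushy + beta_d * perpy
    return px, py, vx, vy, uthx, uthy, ushx, ushy, perpx, perpy


@njit(cache=True)
def _apply_point_force(Q, b, Fx, Fy, uthx, uthy, ushx, ushy, perpx, perpy):
    """Accumulate generalized force J^T F for a foot point of leg at b."""
    Q[0] += Fx
    Q[1] += Fy
    # column dot products; angle derivative maps:
    # a_th: theta -1, hip +1 ; a_sh: theta -1, hip +1, knee -1
    # beta: theta -1, hip +1, knee -1, ankle +1
    d_ath = uthx * Fx + uthy * Fy
    d_ash = ushx * Fx + ushy * Fy
    d_beta = perpx * Fx + perpy * Fy
    Q[2] += -(d_ath + d_ash + d_beta)
    Q[b] += d_ath + d_ash + d_beta
    Q[b + 1] += -(d_ash + d_beta)
    Q[b + 2] += d_beta


@njit(cache=True)
def _assemble_dynamics(q, qd, SEG, Q, M):
    """Mass matrix and velocity-product/gravity contributions.

    On return M holds the 9x9 mass matrix and Q has been incremented by
    gravity and bias terms (Q may already contain joint/contact forces).
    """
    g = SEG[18]
    for i in range(9):
        for j in range(9):
            M[i, j] = 0.0

    # --- trunk (HAT): com = hip + c_hat * (sin th, cos th), ccw angle -th
    th = q[2]
    c_hat = SEG[2]
    m_hat = SEG[0]
    st, ct = np.sin(th), np.cos(th)
    jx = c_hat * ct    # d(com_x)/d th
    jy = -c_hat * st   # d(com_y)/d th
    # bias accel (qdd = 0): -thd^2 * c_hat * (sin th, cos th)
    bx = -qd[2] * qd[2] * c_hat * st
    by = -qd[2] * qd[2] * c_hat * ct
    Fx = 0.0 - m_hat * bx
    Fy = -m_hat * g - m_hat * by
    Q[0] += Fx
    Q[1] += Fy
    Q[2] += jx * Fx + jy * Fy
    M[0, 0] += m_hat
    M[1, 1] += m_hat
    M[0, 2] += m_hat * jx
    M[2, 0] += m_hat * jx
    M[1, 2] += m_hat * jy
    M[2, 1] += m_hat * jy
    M[2, 2] += m_hat * (jx * jx + jy * jy) + SEG[1]

    # --- legs
    for leg in range(2):
        b = 3 + 3 * leg
        a_th = q[b] - th
        a_sh = a_th - q[b + 1]
        beta = a_sh + q[b + 2]
        a_th_d = qd[b] - qd[2]
        a_sh_d = a_th_d - qd[b + 1]
        beta_d = a_sh_d + qd[b + 2]
        l_th, c_th = SEG[5], SEG[6]
        l_sh, c_sh = SEG[9], SEG[10]
        s1, c1 = np.sin(a_th), np.cos(a_th)
        s2, c2 = np.sin(a_sh), np.cos(a_sh)
        sb, cb = np.sin(beta), np.cos(beta)

        # chain derivative vectors
        # thigh com
        t_x, t_y = c_th * c1, c_th * s1
        # shank com pieces
        k_x, k_y = l_th * c1, l_th * s1
        s_x, s_y = c_sh * c2, c_sh * s2
        # foot com rotated offset e = R(beta) (c_fx, -c_fy)
        c_fx, c_fy = SEG[13], SEG[14]
        ex = c_fx * cb + c_fy * sb
        ey = c_fx * sb - c_fy * cb
        f_sx, f_sy = l_sh * c2, l_sh * s2
        p_x, p_y = -ey, ex

        # angle-to-q maps: columns (theta=2, hip=b, knee=b+1, ankle=b+2)
        # body jacobians as 2 x 6 over cols [0, 1, 2, b, b+1, b+2]
        # thigh: J = [x, y; d(a_th) * t]
        # d a_th/d th = -1, /d hip = +1
        # shank: d a_sh/d th=-1,/hip=+1,/knee=-1
        # foot: d beta/d th=-1,/hip=+1,/knee=-1,/ankle=+1
        m_th_m, I_th = SEG[3], SEG[4]
        m_sh_m, I_sh = SEG[7], SEG[8]
        m_f_m, I_f = SEG[11], SEG[12]

        # pack compact jacobians: rows x/y, cols th,hip,knee,ankle
        Jx = np.zeros((3, 4))
        Jy = np.zeros((3, 4))
        # thigh (body 0)
        Jx[0, 0] = -t_x
        Jy[0, 0] = -t_y
        Jx[0, 1] = t_x
        Jy[0, 1] = t_y
        # shank (body 1)
        Jx[1, 0] = -(k_x + s_x)
        Jy[1, 0] = -(k_y + s_y)
        Jx[1, 1] = k_x + s_x
        Jy[1, 1] = k_y + s_y
        Jx[1, 2] = -s_x
        Jy[1, 2] = -s_y
        # foot (body 2)
        Jx[2, 0] = -(k_x + f_sx + p_x)
        Jy[2, 0] = -(k_y + f_sy + p_y)
        Jx[2, 1] = k_x + f_sx + p_x
        Jy[2, 1] = k_y + f_sy + p_y
        Jx[2, 2] = -(f_sx + p_x)
        Jy[2, 2] = -(f_sy + p_y)
        Jx[2, 3] = p_x
        Jy[2, 3] = p_y

        # bias accelerations (qdd = 0)
        biasx = np.empty(3)
        biasy = np.empty(3)
        biasx[0] = -a_th_d * a_th_d * c_th * s1
        biasy[0] = a_th_d * a_th_d * c_th * c1
        biasx[1] = -a_th_d * a_th_d * l_th * s1 - a_sh_d * a_sh_d * c_sh * s2
        biasy[1] = a_th_d * a_th_d * l_th * c1 + a_sh_d * a_sh_d * c_sh * c2
        biasx[2] = -a_th_d * a_th_d * l_th * s1 - a_sh_d * a_sh_d * l_sh * s2 \
            - beta_d * beta_d * ex
        biasy[2] = a_th_d * a_th_d * l_th * c1 + a_sh_d * a_sh_d * l_sh * c2 \
            - beta_d * beta_d * ey
        masses = np.empty(3)
        masses[0] = m_th_m
        masses[1] = m_sh_m
        masses[2] = m_f_m
        inertias = np.empty(3)
        inertias[0] = I_th
        inertias[1] = I_sh
        inertias[2] = I_f
        cols = np.empty(4, dtype=np.int64)
        cols[0] = 2
        cols[1] = b
        cols[2] = b + 1
        cols[3] = b + 2
        # angular jacobian entries per body over cols th,hip,knee,ankle
        wrow = np.zeros((3, 4))
        wrow[0, 0] = -1.0
        wrow[0, 1] = 1.0
        wrow[1, 0] = -1.0
        wrow[1, 1] = 1.0
        wrow[1, 2] = -1.0
        wrow[2, 0] = -1.0
        wrow[2, 1] = 1.0
        wrow[2, 2] = -1.0
        wrow[2, 3] = 1.0

        for bd in range(3):
            mb = masses[bd]
            Ib = inertias[bd]
            Fx = -mb * biasx[bd]
            Fy = -mb * (g + biasy[bd])
            # translational part
            Q[0] += Fx
            Q[1] += Fy
            M[0, 0] += mb
            M[1, 1] += mb
            for ci in range(4):
                jxi = Jx[bd, ci]
                jyi = Jy[bd, ci]
                col = cols[ci]
                Q[col] += jxi * Fx + jyi * Fy
                M[0, col] += mb * jxi
                M[col, 0] += mb * jxi
                M[1, col] += mb * jyi
                M[col, 1] += mb * jyi
                for cj in range(4):
                    M[col, cols[cj]] += mb * (jxi * Jx[bd, cj] + jyi * Jy[bd, cj]) \
                        + Ib * wrow[bd, ci] * wrow[bd, cj]


@njit(cache=True)
def _solve_free(M, Q):
    return np.linalg.solve(M, Q)


@njit(cache=True)
def _solve_prescribed(M, Q, idx, acc):
    """Solve M qdd = Q with qdd[idx] prescribed; returns (qdd, torque)."""
    n = 9
    qdd = np.zeros(n)
    Mr = np.zeros((n - 1, n - 1))
    Qr = np.zeros(n - 1)
    ii = 0
    for i in range(n):
        if i == idx:
            continue
        jj = 0
        Qr[ii] = Q[i] - M[i, idx] * acc
        for j in range(n):
            if j == idx:
                continue
            Mr[ii, jj] = M[i, j]
            jj += 1
        ii += 1
    sol = np.linalg.solve(Mr, Qr)
    ii = 0
    for i in range(n):
        if i == idx:
            qdd[i] = acc
        else:
            qdd[i] = sol[ii]
            ii += 1
    # implied actuation torque on the prescribed DOF
    lam = -Q[idx]
    for j in range(n):
        lam += M[idx, j] * qdd[j]
    return qdd, lam


@njit(cache=True)
def _stimulations(p, leg, gate, fd, ld, vd, knee_ld, knee_vd,
                  theta_d, thetad_d, load_own, load_con, S_out):
    """Reflex stimulation law for one leg (fd/ld/vd: delayed afferents of
    this leg's 9 muscles; knee_* are the delayed VAS length/velocity used as
    the knee-extension proxy).

    The stance soleus pathway uses only the force afferent (no velocity
    term); gating blends the stance and swing law with weight ``gate``.
    """
    u = p[P_KP_TRUNK] * (theta_d - p[P_THETA_REF]) + p[P_KD_TRUNK] * thetad_d
    up = u if u > 0.0 else 0.0
    un = -u if u < 0.0 else 0.0
    rho = _clip(load_own, 0.0, 1.0)
    rhoc = _clip(load_con, 0.0, 1.0)

    # stance law
    st = np.empty(NM)
    st[SOL] = S_MIN + p[P_G_SOL] * fd[SOL]
    ta_stretch = ld[TA] - p[P_LOFF_TA]
    st[TA] = S_MIN + p[P_G_TA] * (ta_stretch if ta_stretch > 0.0 else 0.0) \
        - p[P_GS_TA] * fd[SOL]
    st[GAS] = S_MIN + p[P_G_GAS] * fd[GAS]
    ext = p[P_LOFF_KNEE] - knee_ld
    inhib = 0.0
    if ext > 0.0 and knee_vd > 0.0:  # knee extending (VAS shortening)
        inhib = p[P_KKNEE] * ext
    st[VAS] = p[P_S0_VAS] + p[P_G_VAS] * fd[VAS] - inhib - p[P_KDS_VAS] * rhoc
    st[HFL] = S_MIN + p[P_KHFL_TR] * rho * un + p[P_DS_HFL] * rhoc
    st[GLU] = p[P_S0_GLU] + rho * up - p[P_DS_GLU] * rhoc
    st[HAM] = p[P_S0_HAM] + p[P_KHAM_TR] * rho * up
    st[RF] = S_MIN
    st[BFSH] = S_MIN

    # swing law
    sw = np.empty(NM)
    hfl_stretch = ld[HFL] - p[P_LOFF_HFL]
    ham_stretch = ld[HAM] - p[P_LOFF_HAM]
    sw[HFL] = p[P_S0_HFL_SW] \
        + p[P_G_HFL] * (hfl_stretch if hfl_stretch > 0.0 else 0.0) \
        - p[P_GHAM_HFL] * (ham_stretch if ham_stretch > 0.0 else 0.0) \
        + p[P_KLEAN] * (theta_d - p[P_THETA_REF])
    sw[HAM] = S_MIN + p[P_GHAM_SW] * fd[HAM]
    sw[GLU] = S_MIN + p[P_KGLU_HAM] * fd[HAM]
    sw[TA] = S_MIN + p[P_G_TA] * (ta_stretch if ta_stretch > 0.0 else 0.0)
    sw[SOL] = S_MIN
    sw[GAS] = S_MIN + p[P_GGAS_LSW] * fd[GAS]
    vas_stretch = ld[VAS] - p[P_LOFF_VAS_LSW]
    sw[VAS] = S_MIN + p[P_GVAS_LSW] * (vas_stretch if vas_stretch > 0.0 else 0.0)
    bfsh_stretch = ld[BFSH] - p[P_LOFF_BFSH]
    sw[BFSH] = S_MIN + p[P_G_BFSH] * (bfsh_stretch if bfsh_stretch > 0.0 else 0.0)
    sw[RF] = S_MIN

    for m in range(NM):
        S_out[m] = _clip(gate * st[m] + (1.0 - gate) * sw[m], S_MIN, 1.0)


@njit(cache=True)
def simulate(
    n_steps, dt, rec_every, step0, t0,
    SEG, JL, MF, MI, CON, P, CTRLI,
    q, qd, act, lce, gate, canchor, cflag, phst,
    BUF, TBUF, LBUF, blk, DIST,
    REC, hs_t, to_t, evn, misc,
):
    """Advance the walker ``n_steps`` and record the trajectory.

    All state arrays are mutated in place so a run can be resumed (this is
    how limit-cycle snapshots and disturbance trials work).  Returns the
    number of steps actually simulated (less than ``n_steps`` on a fall).

    misc out: [0] E_met, [1] distance start x, [2] fall flag, [3] fall time,
    [4] servo torque peak, [5] imposed ankle angle achieved,
    [6] trip onset time, [7] slip onset time.
    """
    NB = BUF.shape[2]
    nrec = REC.shape[0]
    maxev = hs_t.shape[1]
    g_std = SEG[20]
    weight = SEG[19] * SEG[18]

    lmtu = np.zeros((2, NM))
    vmtu = np.zeros((2, NM))
    arms = np.zeros((2, NM, 3))
    fse = np.zeros((2, NM))
    stim = np.zeros((2, NM))
    load = np.zeros(2)
    grf = np.zeros((2, 2))
    Q = np.zeros(9)
    M = np.zeros((9, 9))
    S_leg = np.zeros(NM)
    fdel = np.zeros(NM)
    ldel = np.zeros(NM)
    vdel = np.zeros(NM)

    proto = int(DIST[0])
    dist_t0 = DIST[1]
    dist_leg = int(DIST[2])
    tr_dl = -1.0  # computed at onset for tendon tap
    sr_phi0 = 0.0
    sr_qd0 = 0.0
    sr_started = False
    slip_hs_time = -1.0

    d_trunk = CTRLI[0]
    d_load = CTRLI[1]
    fade_steps = CTRLI[2]
    min_dwell = CTRLI[3]
    d_knee = CTRLI[4]

    fall = False
    step_done = 0

    for it in range(n_steps):
        step = step0 + it
        t = t0 + it * dt
        slot = step % NB

        # ---------------- stage A: muscle geometry and forces --------------
        for leg in range(2):
            b = 3 + 3 * leg
            _mtu_geometry(q, qd, b, MF, MI, lmtu[leg], vmtu[leg], arms[leg])

        # tendon-tap imposed MTU stretch (triangular ramp on one muscle)
        if proto == D_TR and t >= dist_t0:
            ramp = DIST[4]
            if t < dist_t0 + ramp:
                mtr = int(DIST[5])
                if tr_dl < 0.0:
                    # first step of the tap: stretch set by current tension
                    lse0 = lmtu[dist_leg, mtr] - lce[dist_leg, mtr]
                    F_now = tendon_force(lse0, MF[mtr, 3], MF[mtr, 0])
                    cap = DIST[6] * MF[mtr, 1]
                    if DIST[3] <= 0.0:
                        tr_dl = 0.0  # zero-energy tap: exactly null
                    elif F_now > 1e-6:
                        tr_dl = DIST[3] / F_now
                        if tr_dl > cap:
                            tr_dl = cap
                    else:
                        tr_dl = cap  # near-zero tension: capped, flagged
                    misc[5] = tr_dl
                half = 0.5 * ramp
                tau = t - dist_t0
                if tau < half:
                    frac = tau / half
                    slope = tr_dl / half
                else:
                    frac = (ramp - tau) / half
                    slope = -tr_dl / half
                mtr = int(DIST[5])
                lmtu[dist_leg, mtr] += tr_dl * frac
                vmtu[dist_leg, mtr] += slope

        for leg in range(2):
            for m in range(NM):
                lse = lmtu[leg, m] - lce[leg, m]
                fse[leg, m] = tendon_force(lse, MF[m, 3], MF[m, 0])

        # ---------------- contact forces -----------------------------------
        for i in range(9):
            Q[i] = 0.0
        trip_on = proto == D_TRIP and blk[4] > 0.5 and t >= DIST[12]
        for leg in range(2):
            b = 3 + 3 * leg
            grf[leg, 0] = 0.0
            grf[leg, 1] = 0.0
            vg = 0.0
            if proto == D_SLIP and leg == dist_leg and slip_hs_time > 0.0:
                t_on = slip_hs_time + DIST[4]
                if t >= t_on:
                    w = (t - t_on) / DIST[13]
                    if w > 1.0:
                        w = 1.0
                    vg = DIST[3] * DIST[14] * w
                    if t_on >= 0.0 and misc[7] < 0.0:
                        misc[7] = t_on
            for pt in range(2):
                ox = -SEG[15] if pt == 0 else SEG[16]
                oy = -SEG[17]
                px, py, vx, vy, uthx, uthy, ushx, ushy, perpx, perpy = \
                    _leg_point(q, qd, SEG, b, ox, oy)
                ci = 2 * leg + pt
                # ground height (trip block top acts as raised ground)
                gh = 0.0
                on_block = False
                if trip_on:
                    bx0 = blk[0]  # front-face x of the block
                    if px >= bx0 and px <= bx0 + DIST[8]:
                        pen_x = px - bx0
                        pen_y = DIST[7] - py
                        if pen_y > 0.0:
                            if pen_y < pen_x:
                                gh = DIST[7]
                                on_block = True
                            else:
                                # front-face horizontal contact
                                kb = DIST[9]
                                db = DIST[10]
                                vrelx = vx - blk[2]
                                Fxb = -(kb * pen_x + db * (vrelx if vrelx > 0.0 else 0.0))
                                if Fxb > 0.0:
                                    Fxb = 0.0
                                _apply_point_force(Q, b, Fxb, 0.0, uthx, uthy,
                                                   ushx, ushy, perpx, perpy)
                                blk[3] -= Fxb  # reaction on block (+x)
                                grf[leg, 0] += Fxb
                pen = gh - py
                if pen > 0.0:
                    pend = -vy
                    Fn = CON[0] * pen * (1.0 + CON[1] * pend)
                    if Fn < 0.0:
                        Fn = 0.0
                    vsurf = vg
                    if on_block:
                        vsurf = blk[2]
                    if cflag[ci] == 0:
                        canchor[ci] = px
                        cflag[ci] = 1
                    canchor[ci] += vsurf * dt
                    vrel = vx - vsurf
                    Ft = -CON[2] * (px - canchor[ci]) - CON[3] * vrel
                    fmax_t = CON[4] * Fn
                    if Ft > fmax_t:
                        Ft = fmax_t
                        canchor[ci] = px + (Ft + CON[3] * vrel) / CON[2]
                    elif Ft < -fmax_t:
                        Ft = -fmax_t
                        canchor[ci] = px + (Ft + CON[3] * vrel) / CON[2]
                    _apply_point_force(Q, b, Ft, Fn, uthx, uthy, ushx, ushy,
                                       perpx, perpy)
                    grf[leg, 0] += Ft
                    grf[leg, 1] += Fn
                    if on_block:
                        blk[3] -= Ft  # friction reaction accelerates block
                else:
                    cflag[ci] = 0
            load[leg] = grf[leg, 1] / weight

        # ---------------- stage B: afferent recording ----------------------
        pulse_f = 0.0
        pulse_l = 0.0
        pulse_v = 0.0
        if proto == D_MMR and t >= dist_t0 and t < dist_t0 + DIST[4]:
            pulse_f = DIST[3]
            pulse_l = DIST[3]
            pulse_v = DIST[3]
        for leg in range(2):
            for m in range(NM):
                fm = MF[m, 0] if MF[m, 0] > 0.0 else 1.0
                BUF[leg, m, slot, 0] = fse[leg, m] / fm + pulse_f
                BUF[leg, m, slot, 1] = lce[leg, m] / MF[m, 1] + pulse_l
                # shortening-positive CE velocity is stored after the muscle
                # update below; afferent uses MTU-based proxy recorded here
                BUF[leg, m, slot, 2] = -vmtu[leg, m] / (MF[m, 2] * MF[m, 1]) + pulse_v
        TBUF[0, slot] = q[2]
        TBUF[1, slot] = qd[2]
        LBUF[0, slot] = load[0]
        LBUF[1, slot] = load[1]

        # ---------------- stage C: gait events and gating ------------------
        for leg in range(2):
            loaded = load[leg] * weight > CON[5]
            was = phst[leg, 3] > 0.5
            # loading (heel strike) is detected immediately; unloading (toe
            # off) must persist for the debounce span, so brief unloading
            # during a disturbance does not flip the stance/swing gate
            if loaded == was:
                phst[leg, 4] = 0.0
            else:
                phst[leg, 4] += dt
            if (loaded and not was) or \
                    ((not loaded) and was and phst[leg, 4] >= min_dwell * dt):
                phst[leg, 3] = 1.0 if loaded else 0.0
                phst[leg, 4] = 0.0
                if loaded:
                    phst[leg, 1] = phst[leg, 0]
                    phst[leg, 0] = t
                    if evn[leg] < maxev:
                        hs_t[leg, evn[leg]] = t
                        evn[leg] += 1
                    if proto == D_SLIP and leg == dist_leg \
                            and slip_hs_time < 0.0 and t >= dist_t0:
                        slip_hs_time = t
                else:
                    phst[leg, 2] = t
                    if evn[2 + leg] < maxev:
                        to_t[leg, evn[2 + leg]] = t
                        evn[2 + leg] += 1
            tgt = 1.0 if phst[leg, 3] > 0.5 else 0.0
            if gate[leg] < tgt:
                gate[leg] = min(tgt, gate[leg] + 1.0 / fade_steps)
            elif gate[leg] > tgt:
                gate[leg] = max(tgt, gate[leg] - 1.0 / fade_steps)

        # ---------------- stage D: reflex stimulations ---------------------
        for leg in range(2):
            for m in range(NM):
                d = int(MI[m, 1])
                rd = (step - d) % NB
                fdel[m] = BUF[leg, m, rd, 0]
                ldel[m] = BUF[leg, m, rd, 1]
                vdel[m] = BUF[leg, m, rd, 2]
            rd_t = (step - d_trunk) % NB
            rd_l = (step - d_load) % NB
            rd_k = (step - d_knee) % NB
            knee_ld = BUF[leg, VAS, rd_k, 1]
            knee_vd = BUF[leg, VAS, rd_k, 2]
            # double-support modulation only acts on the trailing leg (the
            # one whose contralateral partner struck the ground more recently)
            trailing = phst[1 - leg, 0] > phst[leg, 0]
            load_con = LBUF[1 - leg, rd_l] if trailing else 0.0
            _stimulations(P, leg, gate[leg], fdel, ldel, vdel, knee_ld,
                          knee_vd, TBUF[0, rd_t], TBUF[1, rd_t],
                          LBUF[leg, rd_l], load_con, S_leg)
            for m in range(NM):
                stim[leg, m] = S_leg[m]

        # ---------------- stage E: muscle dynamics -------------------------
        E_rate = 0.0
        for leg in range(2):
            for m in range(NM):
                a = act[leg, m]
                a += (stim[leg, m] - a) * dt / TAU_ACT
                act[leg, m] = a
                l_opt = MF[m, 1]
                fl = force_length(lce[leg, m], l_opt)
                fpe = parallel_force(lce[leg, m], l_opt, MF[m, 0])
                denom = a * MF[m, 0] * fl
                if denom < 0.01 * MF[m, 0]:
                    denom = 0.01 * MF[m, 0]
                if denom < 1e-9:  # disabled muscle (F_max = 0)
                    denom = 1e-9
                fv_req = (fse[leg, m] - fpe) / denom
                if fv_req < 0.0:
                    fv_req = 0.0
                v_sh = force_velocity_inverse(fv_req, MF[m, 2])  # l_opt/s
                l_old = lce[leg, m]
                lnew = l_old - v_sh * l_opt * dt
                lo = 0.2 * l_opt
                hi = 1.9 * l_opt
                if lnew < lo:
                    lnew = lo
                elif lnew > hi:
                    lnew = hi
                lce[leg, m] = lnew
                # realized CE velocity (zero while pinned at a length clamp):
                # this is what the spindle afferent reports and what does work
                v_real = (l_old - lnew) / (l_opt * dt)
                BUF[leg, m, slot, 2] = v_real / MF[m, 2] + pulse_v
                # metabolic rate: activation/maintenance + shortening work
                f_ce = fse[leg, m] - fpe
                if f_ce < 0.0:
                    f_ce = 0.0
                vms = v_real * l_opt
                if vms > 0.0:
                    E_rate += (1.0 + SHORT_HEAT) * f_ce * vms
                E_rate += MF[m, 4] * H_AM * a
        misc[0] += E_rate * dt

        # ---------------- stage F: joint torques ---------------------------
        for leg in range(2):
            b = 3 + 3 * leg
            for m in range(NM):
                F = fse[leg, m]
                for j in range(3):
                    if arms[leg, m, j] != 0.0:
                        Q[b + j] += -F * arms[leg, m, j]
            for j in range(3):
                phi = q[b + j]
                phid = qd[b + j]
                if phi > JL[j, 1]:
                    Q[b + j] += -JL[j, 2] * (phi - JL[j, 1]) - JL[j, 3] * phid
                elif phi < JL[j, 0]:
                    Q[b + j] += JL[j, 2] * (JL[j, 0] - phi) - JL[j, 3] * phid

        # ---------------- stage G: dynamics and integration ----------------
        _assemble_dynamics(q, qd, SEG, Q, M)

        servo = False
        if proto == D_SR and DIST[3] != 0.0 and t >= dist_t0:
            T_ramp = DIST[3] / DIST[4]  # angle / rate
            if t < dist_t0 + T_ramp + DIST[5]:
                if not sr_started:
                    sr_phi0 = q[3 + 3 * dist_leg + 2]
                    sr_qd0 = qd[3 + 3 * dist_leg + 2]
                    sr_started = True
                tau_sr = t - dist_t0
                if tau_sr < T_ramp:
                    phi_t = sr_phi0 + DIST[4] * tau_sr
                    phid_t = DIST[4]
                else:
                    phi_t = sr_phi0 + DIST[3]
                    phid_t = 0.0
                aidx = 3 + 3 * dist_leg + 2
                acc = 1.0e6 * (phi_t - q[aidx]) + 2.0e3 * (phid_t - qd[aidx])
                qdd, lam = _solve_prescribed(M, Q, aidx, acc)
                if abs(lam) > misc[4]:
                    misc[4] = abs(lam)
                misc[5] = q[aidx] - sr_phi0
                servo = True
        if not servo:
            qdd = _solve_free(M, Q)

        for i in range(9):
            qd[i] += qdd[i] * dt
            q[i] += qd[i] * dt

        # trip block dynamics (horizontal; rests on ground)
        if trip_on:
            N_b = DIST[11] * SEG[18]  # m_b * g (foot vertical load ignored)
            fric = DIST[15] * N_b * np.tanh(blk[2] / 0.005)
            ax = (blk[3] - fric) / DIST[11]
            blk[2] += ax * dt
            blk[0] += blk[2] * dt
            blk[3] = 0.0

        # ---------------- stage H: recording -------------------------------
        if it % rec_every == 0:
            r = it // rec_every
            if r < nrec:
                REC[r, REC_T] = t
                for i in range(9):
                    REC[r, REC_Q + i] = q[i]
                    REC[r, REC_QD + i] = qd[i]
                for leg in range(2):
                    for m in range(NM):
                        k = leg * NM + m
                        REC[r, REC_STIM + k] = stim[leg, m]
                        REC[r, REC_ACT + k] = act[leg, m]
                        REC[r, REC_LCE + k] = lce[leg, m] / MF[m, 1]
                        REC[r, REC_VCE + k] = BUF[leg, m, slot, 2] - pulse_v
                        REC[r, REC_F + k] = fse[leg, m] / (MF[m, 0] if MF[m, 0] > 0.0 else 1.0)
                    REC[r, REC_GRF + 2 * leg] = grf[leg, 0]
                    REC[r, REC_GRF + 2 * leg + 1] = grf[leg, 1]
                    REC[r, REC_LOAD + leg] = load[leg]
                    REC[r, REC_GATE + leg] = gate[leg]

        step_done = it + 1

        # ---------------- stage I: fall detection --------------------------
        ok = True
        for i in range(9):
            if not np.isfinite(q[i]) or not np.isfinite(qd[i]):
                ok = False
        if q[1] < 0.7 * g_std or abs(q[2]) > 1.2 or not ok:
            fall = True
            misc[2] = 1.0
            misc[3] = t
            break

    return step_done
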