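"""Model front end: the sagittal reflex walker and its trajectories.

:class:`ReflexWalker` owns the scaled musculoskeletal model (segments,
muscles, ground) and exposes ``simulate`` for forward integration from a
:class:`WalkerState`, plus snapshot handling so disturbance trials can be
launched repeatedly from the same limit-cycle state.  ``fit`` (gait
optimization) lives in :mod:`reflexwalk.optimize` and is attached here for
the statsmodels-style ``model.fit() -> results`` workflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from ._kernel import (
    REC_ACT, REC_F, REC_GATE, REC_GRF, REC_LCE, REC_LOAD, REC_NCOL, REC_Q,
    REC_QD, REC_STIM, REC_T, REC_VCE, TAU_ACT, simulate as _simulate,
)
from .anthropometry import BodyModel, scale_anthropometry
from .muscle import MUSCLES, default_muscles, muscle_table

__all__ = ["ReflexWalker", "WalkerState", "GaitTrajectory", "MechState"]

# density and specific tension used to convert F_max * l_opt to muscle mass
MUSCLE_DENSITY = 1059.7   # kg / m^3
SPECIFIC_TENSION = 0.25e6  # N / m^2

_STATE_FIELDS = ("q", "qd", "act", "lce", "gate", "canchor", "cflag", "phst",
                 "buf", "tbuf", "lbuf", "blk")


@dataclass
class WalkerState:
    """Complete mechanical + neural state (MechState of the model).

    Includes the afferent delay-line buffers so that restarting from a
    saved state is bit-exact.
    """

    q: np.ndarray
    qd: np.ndarray
    act: np.ndarray       # (2, 9)
    lce: np.ndarray       # (2, 9)
    gate: np.ndarray      # (2,)
    canchor: np.ndarray   # (4,) contact anchor x per foot point
    cflag: np.ndarray     # (4,) int
    phst: np.ndarray      # (2, 5) phase bookkeeping
    buf: np.ndarray       # (2, 9, NB, 3) afferent ring buffer
    tbuf: np.ndarray      # (2, NB) trunk lean / lean velocity
    lbuf: np.ndarray      # (2, NB) leg load
    blk: np.ndarray       # (6,) trip-block state
    step: int = 0
    t: float = 0.0

    def copy(self) -> "WalkerState":
        return WalkerState(
            *[getattr(self, f).copy() for f in _STATE_FIELDS],
            step=self.step, t=self.t,
        )

    def to_dict(self) -> dict:
        d = {f: getattr(self, f).tolist() for f in _STATE_FIELDS}
        d["step"] = self.step
        d["t"] = self.t
        return d

    @classmethod
    def from_dict(cls, d) -> "WalkerState":
        arrays = {}
        for f in _STATE_FIELDS:
            a = np.asarray(d[f])
            if f == "cflag":
                a = a.astype(np.int64)
            else:
                a = a.astype(float)
            arrays[f] = a
        return cls(**arrays, step=int(d["step"]), t=float(d["t"]))

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "WalkerState":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


MechState = WalkerState  # domain alias


class GaitTrajectory:
    """Recorded walking trajectory with gait metrics and tabular export."""

    def __init__(self, rec: np.ndarray, heel_strikes, toe_offs, misc,
                 dt_rec: float, fell: bool):
        self.rec = rec
        self.heel_strikes = heel_strikes    # list of arrays per leg
        self.toe_offs = toe_offs
        self.misc = misc
        self.dt_rec = dt_rec
        self.fell = fell

    # -- basic accessors ---------------------------------------------------
    @property
    def t(self):
        return self.rec[:, REC_T]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def q(self, i):
        return self.rec[:, REC_Q + i]

    def qd(self, i):
        return self.rec[:, REC_QD + i]

    def _mcol(self, base, leg, muscle):
        m = MUSCLES.index(muscle) if isinstance(muscle, str) else muscle
        return self.rec[:, base + 9 * leg + m]

    def activation(self, leg, muscle):
        return self._mcol(REC_ACT, leg, muscle)

    def stimulation(self, leg, muscle):
        return self._mcol(REC_STIM, leg, muscle)

    def force_afferent(self, leg, muscle):
        return self._mcol(REC_F, leg, muscle)

    def length_afferent(self, leg, muscle):
        return self._mcol(REC_LCE, leg, muscle)

    def velocity_afferent(self, leg, muscle):
        return self._mcol(REC_VCE, leg, muscle)

    def leg_load(self, leg):
        return self.rec[:, REC_LOAD + leg]

    def grf(self, leg):
        return self.rec[:, REC_GRF + 2 * leg:REC_GRF + 2 * leg + 2]

    @property
    def metabolic_energy(self) -> float:
        return float(self.misc[0])

    # -- gait metrics ------------------------------------------------------
    def average_speed(self, discard: float = 0.0) -> float:
        """Mean forward hip velocity after discarding an initial transient."""
        sel = self.t >= self.t[0] + discard
        if sel.sum() < 2:
            return np.nan
        x = self.rec[sel, REC_Q + 0]
        tt = self.t[sel]
        return float((x[-1] - x[0]) / (tt[-1] - tt[0]))

    def stride_periods(self, leg=0) -> np.ndarray:
        return np.diff(self.heel_strikes[leg])

    def ankle_angle(self, leg):
        return self.q(5 + 3 * leg)

    def ankle_velocity(self, leg):
        return self.qd(5 + 3 * leg)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.t}
        for i, n in enumerate(("x", "y", "theta", "hip_l", "knee_l", "ankle_l",
                               "hip_r", "knee_r", "ankle_r")):
            cols[n] = self.q(i)
            cols[n + "_vel"] = self.qd(i)
        for leg, tag in ((0, "l"), (1, "r")):
            cols[f"grf_x_{tag}"] = self.grf(leg)[:, 0]
            cols[f"grf_y_{tag}"] = self.grf(leg)[:, 1]
            for m in MUSCLES:
                cols[f"act_{m.lower()}_{tag}"] = self.activation(leg, m)
                cols[f"stim_{m.lower()}_{tag}"] = self.stimulation(leg, m)
                cols[f"lce_{m.lower()}_{tag}"] = self.length_afferent(leg, m)
                cols[f"vce_{m.lower()}_{tag}"] = self.velocity_afferent(leg, m)
                cols[f"f_{m.lower()}_{tag}"] = self.force_afferent(leg, m)
        return pd.DataFrame(cols)

    def save_table(self, path, sep="\t"):
        self.to_frame().to_csv(path, sep=sep, index=False)

    def plot(self, leg=0, muscles=("SOL", "GAS", "TA", "VAS"), axes=None):
        """Quick-look figure: joint angles, vertical GRF, activations."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 7))
        b = 3 + 3 * leg
        for i, n in zip(range(b, b + 3), ("hip", "knee", "ankle")):
            axes[0].plot(self.t, np.rad2deg(self.q(i)), label=n)
        axes[0].set_ylabel("angle [deg]")
        axes[0].legend(loc="upper right", fontsize=8)
        axes[1].plot(self.t, self.grf(leg)[:, 1], label="vertical GRF")
        axes[1].set_ylabel("GRF [N]")
        for m in muscles:
            axes[2].plot(self.t, self.activation(leg, m), label=m)
        axes[2].set_ylabel("activation")
        axes[2].set_xlabel("time [s]")
        axes[2].legend(loc="upper right", fontsize=8)
        return axes

    def save_hdf(self, path):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("rec", data=self.rec, compression="gzip")
            fh.attrs["dt_rec"] = self.dt_rec
            fh.attrs["fell"] = self.fell


class ReflexWalker:
    """Sagittal-plane neuromuscular walking model.

    Parameters
    ----------
    height, mass : float
        Subject anthropometry; segment and muscle properties scale from the
        1.80 m / 80 kg template.
    dt : float
        Fixed integrator step [s] (0.1–0.5 ms supported).
    """

    def __init__(self, height: float = 1.8, mass: float = 80.0,
                 dt: float = 5e-4, contact: dict | None = None):
        if not 1e-4 <= dt <= 5e-4:
            raise ValueError("dt must be within [0.1, 0.5] ms")
        self.body: BodyModel = scale_anthropometry(height, mass)
        self.height = height
        self.mass = mass
        self.dt = dt
        self.muscles = default_muscles(height / 1.8, mass / 80.0)
        self._pack(contact or {})

    @classmethod
    def from_config(cls, path=None) -> "ReflexWalker":
        """Build a walker from a structured (YAML) configuration file.

        ``path=None`` loads the shipped defaults; a user file only needs
        the fields it overrides (same nesting as the default file).
        """
        import yaml
        from importlib import resources

        ref = resources.files("reflexwalk.data").joinpath("default_model.yaml")
        with resources.as_file(ref) as p:
            with open(p) as fh:
                cfg = yaml.safe_load(fh)
        if path is not None:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
            for section, vals in user.items():
                cfg.setdefault(section, {}).update(vals or {})
        ground = dict(cfg.get("ground", {}))
        mass = float(cfg["subject"]["mass"])
        contact = {}
        scale = mass / 80.0
        for key, col in (("k_n", "k_n"), ("d_n", "d_n"), ("k_t", "k_t"),
                         ("d_t", "d_t"), ("mu", "mu")):
            if key in ground:
                v = float(ground[key])
                if key in ("k_n", "k_t", "d_t"):
                    v *= scale
                contact[col] = v
        if "load_threshold_bw" in ground:
            contact["load_threshold"] = (
                float(ground["load_threshold_bw"]) * mass * 9.81)
        return cls(height=float(cfg["subject"]["height"]), mass=mass,
                   dt=float(cfg["simulation"]["dt"]), contact=contact)

    # -- model packing -----------------------------------------------------
    def _pack(self, contact):
        b = self.body
        seg = np.zeros(21)
        hat, th, sh, ft = (b.segments[k] for k in ("hat", "thigh", "shank", "foot"))
        seg[0], seg[1], seg[2] = hat.mass, hat.inertia, hat.com_offset
        seg[3], seg[4], seg[5], seg[6] = th.mass, th.inertia, th.length, th.com_offset
        seg[7], seg[8], seg[9], seg[10] = sh.mass, sh.inertia, sh.length, sh.com_offset
        seg[11], seg[12] = ft.mass, ft.inertia
        seg[13] = 0.5 * ft.length - b.foot_heel   # foot CoM ahead of ankle
        seg[14] = 0.7 * b.foot_height             # foot CoM below ankle
        seg[15], seg[16], seg[17] = b.foot_heel, b.foot_ball, b.foot_height
        seg[18] = 9.81
        seg[19] = b.mass
        seg[20] = b.standing_hip_height
        self.SEG = seg

        jl = np.zeros((3, 4))
        for j, name in enumerate(("hip", "knee", "ankle")):
            jj = b.joints[name]
            jl[j] = (jj.lower, jj.upper, jj.stiffness, jj.damping)
        self.JL = jl

        tab = muscle_table(self.muscles)
        MF = np.zeros((9, 17))
        MF[:, 0] = tab["f_max"]
        MF[:, 1] = tab["l_opt"]
        MF[:, 2] = tab["v_max"]
        MF[:, 3] = tab["l_slack"]
        MF[:, 4] = tab["f_max"] * tab["l_opt"] * MUSCLE_DENSITY / SPECIFIC_TENSION
        for j in range(2):
            MF[:, 5 + 6 * j] = tab["r0"][:, j]
            MF[:, 6 + 6 * j] = tab["phi_max"][:, j]
            MF[:, 7 + 6 * j] = tab["phi_ref"][:, j]
            MF[:, 8 + 6 * j] = tab["rho"][:, j]
            MF[:, 9 + 6 * j] = tab["sign"][:, j]
        self.MF = MF
        MI = np.zeros((9, 6), dtype=np.int64)
        MI[:, 0] = tab["n_paths"]
        MI[:, 1] = np.round(tab["delay"] / self.dt).astype(np.int64)
        MI[:, 2:4] = tab["joint"]
        MI[:, 4:6] = tab["arm_type"]
        self.MI = MI

        mscale = self.mass / 80.0
        defaults = dict(k_n=1.2e5 * mscale, d_n=1.0, k_t=8.0e4 * mscale,
                        d_t=600.0 * mscale, mu=0.9,
                        load_threshold=0.03 * b.weight)
        defaults.update(contact)
        self.CON = np.array([defaults["k_n"], defaults["d_n"], defaults["k_t"],
                             defaults["d_t"], defaults["mu"],
                             defaults["load_threshold"]])
        self.CTRLI = np.array([
            round(0.005 / self.dt),   # trunk afferent delay
            round(0.010 / self.dt),   # load afferent delay
            round(0.010 / self.dt),   # stance/swing cross-fade
            round(0.030 / self.dt),   # unloading-persistence debounce
            round(0.010 / self.dt),   # knee-proxy delay
        ], dtype=np.int64)
        self.NB = int(np.max(MI[:, 1])) + int(self.CTRLI[1]) + 4

    # -- state construction ------------------------------------------------
    def initial_state(self, v0: float = 1.2, pose: dict | None = None
                      ) -> WalkerState:
        """Standing-start state: stance leg near vertical, swing leg flexed,
        hip moving forward at ``v0``; the lowest foot point is placed on the
        ground."""
        pose = pose or {}
        q = np.zeros(9)
        q[2] = pose.get("theta", 0.105)
        q[3] = pose.get("hip_l", 0.12)
        q[4] = pose.get("knee_l", 0.03)
        q[5] = pose.get("ankle_l", 0.0)
        q[6] = pose.get("hip_r", 0.4)
        q[7] = pose.get("knee_r", 0.55)
        q[8] = pose.get("ankle_r", 0.0)
        q[1] = self.body.standing_hip_height + 0.05
        # drop the model so the lowest foot point just touches the ground
        low = self._lowest_point(q)
        q[1] -= low
        qd = np.zeros(9)
        qd[0] = v0

        lce = np.zeros((2, 9))
        for leg in range(2):
            phis = q[3 + 3 * leg:6 + 3 * leg]
            for m, mtu in enumerate(self.muscles):
                from .muscle import mtu_length

                l = mtu_length(mtu, phis) - mtu.l_slack
                lce[leg, m] = np.clip(l, 0.6 * mtu.l_opt, 1.3 * mtu.l_opt)
        act = np.full((2, 9), 0.02)
        # pre-activate the stance leg's anti-gravity muscles so the first
        # weight acceptance does not collapse before the reflex loops engage
        for name, a0 in (("SOL", 0.20), ("VAS", 0.20), ("GLU", 0.12),
                         ("HAM", 0.10), ("GAS", 0.08)):
            act[0, MUSCLES.index(name)] = a0
        NB = self.NB
        buf = np.zeros((2, 9, NB, 3))
        for leg in range(2):
            for m, mtu in enumerate(self.muscles):
                buf[leg, m, :, 1] = lce[leg, m] / mtu.l_opt
        tbuf = np.zeros((2, NB))
        tbuf[0, :] = q[2]
        lbuf = np.zeros((2, NB))
        phst = np.zeros((2, 5))
        phst[:, 4] = 1.0  # long-ago last switch: events may fire immediately
        return WalkerState(
            q=q, qd=qd, act=act, lce=lce, gate=np.array([1.0, 0.0]),
            canchor=np.zeros(4), cflag=np.zeros(4, dtype=np.int64),
            phst=phst, buf=buf, tbuf=tbuf, lbuf=lbuf, blk=np.zeros(6),
        )

    def _lowest_point(self, q):
        from ._kernel import _leg_point

        low = np.inf
        for leg in range(2):
            b = 3 + 3 * leg
            for ox in (-self.SEG[15], self.SEG[16]):
                py = _leg_point(q, np.zeros(9), self.SEG, b, ox, -self.SEG[17])[1]
                low = min(low, py)
        return low

    # -- simulation --------------------------------------------------------
    def simulate(self, params, duration: float, state: WalkerState | None = None,
                 disturbance=None, rec_dt: float = 1e-3,
                 max_events: int = 512) -> tuple:
        """Integrate for ``duration`` seconds; returns (trajectory, state).

        ``params`` is a :class:`~reflexwalk.control.ReflexParameters` or a
        flat vector; ``state`` (mutated copy) defaults to
        :meth:`initial_state`; ``disturbance`` is a
        :class:`~reflexwalk.disturbances.DisturbanceSpec` or packed array.
        """
        from .control import ReflexParameters

        if isinstance(params, ReflexParameters):
            P = params.vector()
        else:
            P = np.asarray(params, dtype=float)
        st = (state or self.initial_state()).copy()
        if st.buf.shape[2] != self.NB:
            raise ValueError("state delay buffers do not match this model's dt")

        n_steps = int(round(duration / self.dt))
        rec_every = max(1, int(round(rec_dt / self.dt)))
        n_rec = n_steps // rec_every + 1
        REC = np.zeros((n_rec, REC_NCOL))
        hs_t = np.full((2, max_events), np.nan)
        to_t = np.full((2, max_events), np.nan)
        evn = np.zeros(4, dtype=np.int64)
        misc = np.zeros(8)
        misc[7] = -1.0

        if disturbance is None:
            DIST = np.zeros(16)
        elif hasattr(disturbance, "to_array"):
            DIST = disturbance.to_array()
        else:
            DIST = np.asarray(disturbance, dtype=float)
        if DIST[0] == _kernel.D_TRIP and DIST[11] > 0.0:
            # place the obstacle: front face at DIST[6], initially at rest
            st.blk[:] = 0.0
            st.blk[0] = DIST[6]
            st.blk[4] = 1.0

        done = _simulate(
            n_steps, self.dt, rec_every, st.step, st.t,
            self.SEG, self.JL, self.MF, self.MI, self.CON, P, self.CTRLI,
            st.q, st.qd, st.act, st.lce, st.gate, st.canchor, st.cflag,
            st.phst, st.buf, st.tbuf, st.lbuf, st.blk, DIST,
            REC, hs_t, to_t, evn, misc,
        )
        st.step += done
        st.t += done * self.dt
        n_kept = min(n_rec, (done + rec_every - 1) // rec_every)
        hs = [hs_t[leg, :evn[leg]] for leg in range(2)]
        to = [to_t[leg, :evn[2 + leg]] for leg in range(2)]
        traj = GaitTrajectory(REC[:n_kept], hs, to, misc, rec_every * self.dt,
                              fell=bool(misc[2]))
        return traj, st

    # -- energies ----------------------------------------------------------
    def mechanical_energy(self, state: WalkerState) -> float:
        """Kinetic + gravitational potential energy of the rigid bodies."""
        q, qd = state.q, state.qd
        seg = self.SEG
        g = seg[18]
        th = q[2]
        # trunk
        cx = q[0] + seg[2] * np.sin(th)
        cy = q[1] + seg[2] * np.cos(th)
        # trunk com velocity: d/dt (hip + c*(sin th, cos th))
        vx = qd[0] + seg[2] * np.cos(th) * qd[2]
        vy = qd[1] - seg[2] * np.sin(th) * qd[2]
        E = 0.5 * seg[0] * (vx ** 2 + vy ** 2) + 0.5 * seg[1] * qd[2] ** 2 \
            + seg[0] * g * cy
        for leg in range(2):
            b = 3 + 3 * leg
            a_th = q[b] - th
            a_sh = a_th - q[b + 1]
            beta = a_sh + q[b + 2]
            a_th_d = qd[b] - qd[2]
            a_sh_d = a_th_d - qd[b + 1]
            beta_d = a_sh_d + qd[b + 2]
            u1 = np.array([np.sin(a_th), -np.cos(a_th)])
            du1 = np.array([np.cos(a_th), np.sin(a_th)])
            u2 = np.array([np.sin(a_sh), -np.cos(a_sh)])
            du2 = np.array([np.cos(a_sh), np.sin(a_sh)])
            hip_v = np.array([qd[0], qd[1]])
            # thigh
            c = seg[6]
            pos = np.array([q[0], q[1]]) + c * u1
            vel = hip_v + c * a_th_d * du1
            E += 0.5 * seg[3] * vel @ vel + 0.5 * seg[4] * a_th_d ** 2 \
                + seg[3] * g * pos[1]
            # shank
            knee = np.array([q[0], q[1]]) + seg[5] * u1
            knee_v = hip_v + seg[5] * a_th_d * du1
            pos = knee + seg[10] * u2
            vel = knee_v + seg[10] * a_sh_d * du2
            E += 0.5 * seg[7] * vel @ vel + 0.5 * seg[8] * a_sh_d ** 2 \
                + seg[7] * g * pos[1]
            # foot
            ankle = knee + seg[9] * u2
            ankle_v = knee_v + seg[9] * a_sh_d * du2
            cb, sb = np.cos(beta), np.sin(beta)
            e = np.array([seg[13] * cb + seg[14] * sb,
                          seg[13] * sb - seg[14] * cb])
            pos = ankle + e
            vel = ankle_v + beta_d * np.array([-e[1], e[0]])
            E += 0.5 * seg[11] * vel @ vel + 0.5 * seg[12] * beta_d ** 2 \
                + seg[11] * g * pos[1]
        return float(E)

    # -- low-level mechanics operations --------------------------------------
    def contact_forces(self, state: WalkerState) -> np.ndarray:
        """Per-contact-point ground forces [N] at the given state.

        Returns (4, 2): rows heelL, ballL, heelR, ballR; columns (Fx, Fy).
        Pure function of the state (anchor bookkeeping is not advanced).
        """
        from ._kernel import _leg_point

        out = np.zeros((4, 2))
        for leg in range(2):
            b = 3 + 3 * leg
            for pt in range(2):
                ox = -self.SEG[15] if pt == 0 else self.SEG[16]
                px, py, vx, vy = _leg_point(state.q, state.qd, self.SEG, b,
                                            ox, -self.SEG[17])[:4]
                ci = 2 * leg + pt
                pen = -py
                if pen <= 0.0:
                    continue
                Fn = max(self.CON[0] * pen * (1.0 + self.CON[1] * (-vy)), 0.0)
                anchor = state.canchor[ci] if state.cflag[ci] else px
                Ft = -self.CON[2] * (px - anchor) - self.CON[3] * vx
                Ft = np.clip(Ft, -self.CON[4] * Fn, self.CON[4] * Fn)
                out[ci] = (Ft, Fn)
        return out

    def step_dynamics(self, state: WalkerState, stimulations,
                      gravity: bool = True, contact: bool = True
                      ) -> WalkerState:
        """Advance the mechanics one fixed step with *given* stimulations.

        Bypasses the reflex controller (stimulations is (2, 9) or flat 18
        in [0, 1]); otherwise identical staging to the simulation kernel:
        activation dynamics, CE force balance, contact, joint-limit
        torques, EOM solve, symplectic Euler.  Deterministic.
        """
        from ._kernel import (_apply_point_force, _assemble_dynamics,
                              _leg_point, _mtu_geometry)
        from .muscle import (force_length, force_velocity_inverse,
                             parallel_force, tendon_force)

        stim = np.asarray(stimulations, dtype=float).reshape(2, 9)
        st = state.copy()
        dt = self.dt
        SEG = self.SEG.copy()
        if not gravity:
            SEG[18] = 0.0
        Q = np.zeros(9)
        M = np.zeros((9, 9))
        lmtu = np.zeros((2, 9))
        vmtu = np.zeros((2, 9))
        arms = np.zeros((2, 9, 3))
        for leg in range(2):
            b = 3 + 3 * leg
            _mtu_geometry(st.q, st.qd, b, self.MF, self.MI, lmtu[leg],
                          vmtu[leg], arms[leg])
        fse = np.zeros((2, 9))
        for leg in range(2):
            for m in range(9):
                fse[leg, m] = tendon_force(lmtu[leg, m] - st.lce[leg, m],
                                           self.MF[m, 3], self.MF[m, 0])
        if contact:
            for leg in range(2):
                b = 3 + 3 * leg
                for pt in range(2):
                    ox = -SEG[15] if pt == 0 else SEG[16]
                    px, py, vx, vy, uthx, uthy, ushx, ushy, perpx, perpy = \
                        _leg_point(st.q, st.qd, SEG, b, ox, -SEG[17])
                    ci = 2 * leg + pt
                    pen = -py
                    if pen <= 0.0:
                        st.cflag[ci] = 0
                        continue
                    Fn = max(self.CON[0] * pen * (1.0 + self.CON[1] * (-vy)), 0.0)
                    if not st.cflag[ci]:
                        st.canchor[ci] = px
                        st.cflag[ci] = 1
                    Ft = -self.CON[2] * (px - st.canchor[ci]) - self.CON[3] * vx
                    fmax_t = self.CON[4] * Fn
                    if abs(Ft) > fmax_t:
                        Ft = np.sign(Ft) * fmax_t
                        st.canchor[ci] = px + (Ft + self.CON[3] * vx) / self.CON[2]
                    _apply_point_force(Q, b, Ft, Fn, uthx, uthy, ushx, ushy,
                                       perpx, perpy)
        for leg in range(2):
            for m in range(9):
                a = st.act[leg, m] + (stim[leg, m] - st.act[leg, m]) * dt / TAU_ACT
                st.act[leg, m] = a
                l_opt = self.MF[m, 1]
                fl = force_length(st.lce[leg, m], l_opt)
                fpe = parallel_force(st.lce[leg, m], l_opt, self.MF[m, 0])
                denom = max(a * self.MF[m, 0] * fl, 0.01 * self.MF[m, 0], 1e-9)
                fv_req = max((fse[leg, m] - fpe) / denom, 0.0)
                v_sh = force_velocity_inverse(fv_req, self.MF[m, 2])
                st.lce[leg, m] = np.clip(st.lce[leg, m] - v_sh * l_opt * dt,
                                         0.2 * l_opt, 1.9 * l_opt)
            b = 3 + 3 * leg
            for m in range(9):
                for j in range(3):
                    if arms[leg, m, j] != 0.0:
                        Q[b + j] += -fse[leg, m] * arms[leg, m, j]
            for j in range(3):
                phi, phid = st.q[b + j], st.qd[b + j]
                if phi > self.JL[j, 1]:
                    Q[b + j] += -self.JL[j, 2] * (phi - self.JL[j, 1]) \
                        - self.JL[j, 3] * phid
                elif phi < self.JL[j, 0]:
                    Q[b + j] += self.JL[j, 2] * (self.JL[j, 0] - phi) \
                        - self.JL[j, 3] * phid
        _assemble_dynamics(st.q, st.qd, SEG, Q, M)
        qdd = np.linalg.solve(M, Q)
        if not np.all(np.isfinite(qdd)):
            raise FloatingPointError("non-finite accelerations: simulation "
                                     "aborted, flagged as fall")
        st.qd += qdd * dt
        st.q += st.qd * dt
        st.t += dt
        st.step += 1
        return st

    # -- statsmodels-style fit ----------------------------------------------
    def fit(self, v_tgt: float, budget: int = 2000, seed: int = 0, **kw):
        """Optimize the reflex parameters for stable walking at ``v_tgt``.

        Thin wrapper around :func:`reflexwalk.optimize.optimize_gait`;
        returns a :class:`reflexwalk.optimize.GaitFitResults`.
        """
        from .optimize import optimize_gait

        return optimize_gait(self, v_tgt, budget=budget, seed=seed, **kw)
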