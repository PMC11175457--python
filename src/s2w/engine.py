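"""Forward simulation engine: packing, integration loop, trajectories.

Integration is fixed-step semi-implicit Euler at ``DT = 2e-4`` s with
trajectory sampling at 100 Hz; the hot loop lives in :mod:`s2w._kernel`.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel as K
from .model import (ANGULAR_COORDS, COORDINATES, MUSCLE_ORDER,
                    ModelDefinition, hertz_stiffness)

DT = 2.0e-4                 # s, integration step
SAMPLE_RATE = 100.0         # Hz, trajectory sampling
MAX_TIME = 12.0             # s, simulation cap
FALL_RATIO = 0.6            # COM-height fraction that defines a fall
STEP_FORCE_THRESHOLD = 30.0  # N, heel force rising edge for step detection
STEP_UNLOADED_TIME = 0.05   # s, minimum unloaded interval before a step

MUSCLES_RL = tuple(f"{m}_r" for m in MUSCLE_ORDER) + \
    tuple(f"{m}_l" for m in MUSCLE_ORDER)

TRAJ_COLUMNS = (
    ["time"]
    + [f"q_{c}" for c in COORDINATES]
    + [f"qd_{c}" for c in COORDINATES]
    + [f"a_{m}" for m in MUSCLES_RL]
    + [f"u_{m}" for m in MUSCLES_RL]
    + [f"f_{m}" for m in MUSCLES_RL]
    + [f"lce_{m}" for m in MUSCLES_RL]
    + [f"vce_{m}" for m in MUSCLES_RL]
    + ["grf_r_x", "grf_r_y", "grf_l_x", "grf_l_y", "seat_x", "seat_y",
       "pelvis_com_x", "pelvis_com_y", "head_x", "head_y",
       "tau_lumbar", "tau_thoracic", "phase", "state_r", "state_l",
       "heel_r_y", "heel_l_y", "com_x", "com_y",
       "fext_x", "fext_y", "m_acom_x", "m_acom_y"]
)
assert len(TRAJ_COLUMNS) == K.NCOLS

PHASE_NAMES = {0: "P1", 1: "P2", 2: "GAIT"}


def detect_fall(com_height: float, initial_com_height: float,
                ratio: float = FALL_RATIO) -> bool:
    """True iff the COM height has dropped strictly below ratio * initial."""
    if initial_com_height <= 0:
        raise ValueError("initial COM height must be > 0")
    return com_height < ratio * initial_com_height


# ---------------------------------------------------------------------------
# delayed signals (public contract; the kernel keeps its own ring buffer)


class DelayBuffer:
    """Per-channel history with linearly interpolated delayed reads."""

    def __init__(self):
        self._t: dict[str, list] = {}
        self._v: dict[str, list] = {}

    def append(self, channel: str, t: float, value: float):
        ts = self._t.setdefault(channel, [])
        if ts and t < ts[-1]:
            raise ValueError("samples must be appended in time order")
        ts.append(t)
        self._v.setdefault(channel, []).append(value)

    def channels(self):
        return list(self._t)

    def delayed_value(self, channel: str, t: float, delay: float) -> float:
        if channel not in self._t:
            raise KeyError(f"unknown channel {channel!r}")
        ts = self._t[channel]
        vs = self._v[channel]
        tq = t - delay
        if tq <= ts[0]:
            return vs[0]
        i = bisect.bisect_right(ts, tq)
        if i >= len(ts):
            return vs[-1]
        t0, t1 = ts[i - 1], ts[i]
        w = (tq - t0) / (t1 - t0) if t1 > t0 else 0.0
        return vs[i - 1] * (1 - w) + vs[i] * w


def delayed_value(buffer: DelayBuffer, channel: str, t: float, delay: float):
    return buffer.delayed_value(channel, t, delay)


# ---------------------------------------------------------------------------
# trajectory


class Trajectory:
    """Uniformly sampled rollout record (SI units internally)."""

    def __init__(self, data: np.ndarray, dt_sample: float, fell: bool,
                 status: int = 0):
        self.data = np.asarray(data, dtype=float)
        self.dt_sample = dt_sample
        self.fell = bool(fell)
        self.status = int(status)
        if self.data.ndim != 2 or self.data.shape[1] != K.NCOLS:
            raise ValueError("bad trajectory shape")
        if len(self.data) == 0:
            raise ValueError("empty trajectory")

    def __len__(self):
        return len(self.data)

    @property
    def time(self):
        return self.data[:, K.COL_T]

    @property
    def end_time(self):
        return float(self.data[-1, K.COL_T])

    def col(self, name: str) -> np.ndarray:
        return self.data[:, TRAJ_COLUMNS.index(name)]

    def coordinate(self, name: str) -> np.ndarray:
        return self.col(f"q_{name}")

    @property
    def phase(self):
        return self.data[:, K.COL_PHASE].astype(int)

    def phase_mask(self, name: str):
        code = {v: k for k, v in PHASE_NAMES.items()}[name]
        return self.phase == code

    @property
    def activations(self):
        return self.data[:, K.COL_A:K.COL_A + K.NM]

    @property
    def excitations(self):
        return self.data[:, K.COL_U:K.COL_U + K.NM]

    @property
    def muscle_forces(self):
        return self.data[:, K.COL_FM:K.COL_FM + K.NM]

    @property
    def pelvis_com(self):
        return self.data[:, K.COL_PELVIS:K.COL_PELVIS + 2]

    @property
    def seat_force(self):
        return self.data[:, K.COL_SEAT:K.COL_SEAT + 2]

    def grf(self, leg: str):
        c = K.COL_GRF_R if leg == "r" else K.COL_GRF_L
        return self.data[:, c:c + 2]

    @property
    def head_acceleration(self) -> np.ndarray:
        """|a| of the head point, finite-differenced at the sampling rate."""
        pos = self.data[:, K.COL_HEAD:K.COL_HEAD + 2]
        if len(pos) < 3:
            return np.zeros(len(pos))
        acc = np.gradient(np.gradient(pos, self.dt_sample, axis=0),
                          self.dt_sample, axis=0)
        return np.hypot(acc[:, 0], acc[:, 1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=TRAJ_COLUMNS)
        for c in COORDINATES:
            if c in ANGULAR_COORDS:
                df[f"q_{c}"] = np.degrees(df[f"q_{c}"])
                df[f"qd_{c}"] = np.degrees(df[f"qd_{c}"])
        df["phase"] = [PHASE_NAMES[int(p)] for p in self.phase]
        return df

    def write_csv(self, path):
        df = self.to_frame()
        df.insert(0, "fell", "")
        df.loc[df.index[0], "fell"] = int(self.fell)
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        fell = bool(int(df["fell"].iloc[0]))
        df = df.drop(columns=["fell"])
        for c in COORDINATES:
            if c in ANGULAR_COORDS:
                df[f"q_{c}"] = np.radians(df[f"q_{c}"])
                df[f"qd_{c}"] = np.radians(df[f"qd_{c}"])
        code = {v: k for k, v in PHASE_NAMES.items()}
        df["phase"] = [code[p] for p in df["phase"]]
        data = df[list(TRAJ_COLUMNS)].to_numpy(dtype=float)
        dt = float(np.median(np.diff(data[:, 0]))) if len(data) > 1 else 1.0 / SAMPLE_RATE
        return cls(data, dt, fell)


def detect_steps(traj: Trajectory,
                 threshold: float = STEP_FORCE_THRESHOLD,
                 unloaded_time: float = STEP_UNLOADED_TIME):
    """Step events: heel vertical force rising through ``threshold`` after an
    unloaded interval of at least ``unloaded_time``.  Returns [(t, leg), ...].
    """
    events = []
    for leg, colname in (("r", "heel_r_y"), ("l", "heel_l_y")):
        f = traj.col(colname)
        t = traj.time
        unloaded_since = None
        loaded = f[0] >= threshold
        for i in range(1, len(f)):
            if f[i] < threshold:
                if loaded or unloaded_since is None:
                    unloaded_since = t[i]
                loaded = False
            else:
                if not loaded and unloaded_since is not None \
                        and t[i] - unloaded_since >= unloaded_time:
                    events.append((float(t[i]), leg))
                loaded = True
    return sorted(events)


# ---------------------------------------------------------------------------
# model packing


@dataclass
class PackedModel:
    parent: np.ndarray
    jtype: np.ndarray
    jsign: np.ndarray
    jpos: np.ndarray
    jcoord: np.ndarray
    mass: np.ndarray
    inertia: np.ndarray
    com: np.ndarray
    rev_coord: np.ndarray
    rev_sign: np.ndarray
    coord_body: np.ndarray
    desc: np.ndarray
    qlo: np.ndarray
    qhi: np.ndarray
    klim: np.ndarray
    dlim: np.ndarray
    pdamp: np.ndarray
    has_limit: np.ndarray
    fmax: np.ndarray
    lopt: np.ndarray
    lslack: np.ndarray
    vmax: np.ndarray
    vp_body: np.ndarray
    vp_loc: np.ndarray
    vp_off: np.ndarray
    span: np.ndarray
    sph_body: np.ndarray
    sph_loc: np.ndarray
    sph_r: np.ndarray
    sph_k: np.ndarray
    sph_c: np.ndarray
    sph_mus: np.ndarray
    sph_mud: np.ndarray
    sph_is_butt: np.ndarray
    box_k: float
    box_c: float
    box_mus: float
    box_mud: float
    box_h: np.ndarray
    head_body: int
    head_loc: np.ndarray
    body_index: dict


def pack_model(model: ModelDefinition) -> PackedModel:
    names = list(model.body_order)           # segment names, tree order
    nb = len(names) + 2                      # + two prismatic phantoms
    body_index = {n: i + 2 for i, n in enumerate(names)}

    parent = np.full(nb, -1, dtype=np.int64)
    jtype = np.zeros(nb, dtype=np.int64)
    jsign = np.ones(nb)
    jpos = np.zeros((nb, 2))
    jcoord = np.zeros(nb, dtype=np.int64)
    mass = np.zeros(nb)
    inertia = np.zeros(nb)
    com = np.zeros((nb, 2))

    # phantoms: ground-x, ground-y
    parent[0], jtype[0], jcoord[0] = -1, 0, 0
    parent[1], jtype[1], jcoord[1] = 0, 1, 1
    # root revolute (pelvis tilt)
    root = model.root_joint
    b_pelvis = body_index[root.child]
    parent[b_pelvis], jtype[b_pelvis] = 1, 2
    jsign[b_pelvis] = root.axis_sign
    jcoord[b_pelvis] = 2

    ncoord = model.dof_count
    coord_body = np.zeros(ncoord, dtype=np.int64)
    coord_body[0], coord_body[1], coord_body[2] = 0, 1, b_pelvis
    rev_coord = np.zeros(ncoord, dtype=np.bool_)
    rev_coord[2] = True
    rev_sign = np.zeros(ncoord)
    rev_sign[2] = root.axis_sign

    qlo = np.full(ncoord, -np.inf)
    qhi = np.full(ncoord, np.inf)
    klim = np.zeros(ncoord)
    dlim = np.zeros(ncoord)
    pdamp = np.zeros(ncoord)
    has_limit = np.zeros(ncoord, dtype=np.bool_)

    for seg in names:
        b = body_index[seg]
        s = model.segments[seg]
        mass[b] = s.mass
        inertia[b] = s.inertia_zz
        com[b] = s.com_offset
        if seg in model.pin_joints:
            j = model.pin_joints[seg]
            ci = model.coordinate_index(j.name)
            parent[b] = body_index[j.parent]
            jtype[b] = 2
            jsign[b] = j.axis_sign
            jpos[b] = j.pos_in_parent
            jcoord[b] = ci
            coord_body[ci] = b
            rev_coord[ci] = True
            rev_sign[ci] = j.axis_sign
            qlo[ci], qhi[ci] = j.q_min, j.q_max
            klim[ci], dlim[ci] = j.limit_stiffness, j.limit_damping
            pdamp[ci] = j.passive_damping
            has_limit[ci] = j.limit_stiffness > 0

    # descendant masks: body b moves with coordinate ci
    desc = np.zeros((nb, ncoord), dtype=np.bool_)
    for b in range(nb):
        chain = b
        while chain >= 0:
            desc[b, jcoord[chain]] = True
            chain = parent[chain]

    # muscles in controller order (10 right then 10 left)
    fmax = np.zeros(K.NM)
    lopt = np.zeros(K.NM)
    lslack = np.zeros(K.NM)
    vmax = np.zeros(K.NM)
    vp_body_l, vp_loc_l, vp_off = [], [], [0]
    span = np.zeros((K.NM, ncoord), dtype=np.bool_)
    for mi, mname in enumerate(MUSCLES_RL):
        mp = model.muscles[mname]
        fmax[mi], lopt[mi] = mp.f_max, mp.l_opt
        lslack[mi], vmax[mi] = mp.l_slack, mp.v_max
        for seg, loc in mp.path:
            vp_body_l.append(body_index[seg])
            vp_loc_l.append(loc)
        vp_off.append(len(vp_body_l))
        for j in model.joints:
            if j.kind == "pin" and model.muscle_spans(mname, j.name):
                span[mi, model.coordinate_index(j.name)] = True

    # contact spheres: heel_r, toe_r, heel_l, toe_l, buttock
    def foot_spheres(side):
        feet = [s for s in model.spheres if s.parent == f"foot_{side}"]
        return sorted(feet, key=lambda s: s.center[0])

    ordered = foot_spheres("r") + foot_spheres("l") + \
        [s for s in model.spheres if s.parent == "pelvis"]
    ns = len(ordered)
    sph_body = np.array([body_index[s.parent] for s in ordered], dtype=np.int64)
    sph_loc = np.array([s.center for s in ordered])
    sph_r = np.array([s.radius for s in ordered])
    sph_k = np.array([s.stiffness for s in ordered])
    sph_c = np.array([s.dissipation for s in ordered])
    sph_mus = np.array([s.mu_static for s in ordered])
    sph_mud = np.array([s.mu_dynamic for s in ordered])
    sph_is_butt = np.array([s.parent == "pelvis" for s in ordered],
                           dtype=np.bool_)

    butt_r = float(sph_r[sph_is_butt][0]) if sph_is_butt.any() else 0.1
    box = model.box
    torso = model.segments["torso"]

    return PackedModel(
        parent=parent, jtype=jtype, jsign=jsign, jpos=jpos, jcoord=jcoord,
        mass=mass, inertia=inertia, com=com,
        rev_coord=rev_coord, rev_sign=rev_sign, coord_body=coord_body,
        desc=desc, qlo=qlo, qhi=qhi, klim=klim, dlim=dlim, pdamp=pdamp,
        has_limit=has_limit,
        fmax=fmax, lopt=lopt, lslack=lslack, vmax=vmax,
        vp_body=np.array(vp_body_l, dtype=np.int64),
        vp_loc=np.array(vp_loc_l, dtype=float),
        vp_off=np.array(vp_off, dtype=np.int64),
        span=span,
        sph_body=sph_body, sph_loc=sph_loc, sph_r=sph_r, sph_k=sph_k,
        sph_c=sph_c, sph_mus=sph_mus, sph_mud=sph_mud,
        sph_is_butt=sph_is_butt,
        box_k=hertz_stiffness(box.plane_strain_modulus, butt_r),
        box_c=box.dissipation, box_mus=box.mu_static, box_mud=box.mu_dynamic,
        box_h=np.asarray(box.half_extents, dtype=float),
        head_body=body_index["torso"],
        head_loc=np.array([0.0, torso.length]),
        body_index=body_index,
    )


_NULL_PW = dict(
    pw_target=np.zeros(0, dtype=np.int64),
    pw_phase=np.zeros(0, dtype=np.int64),
    pw_statemask=np.zeros(0, dtype=np.int64),
    pw_type=np.zeros(0, dtype=np.int64),
    pw_source=np.zeros(0, dtype=np.int64),
    pw_sign=np.zeros(0),
    pw_delay_steps=np.zeros(0, dtype=np.int64),
    pw_gain_idx=np.zeros(0, dtype=np.int64),
    pw_ofs_idx=np.zeros(0, dtype=np.int64),
    pw_ofs_const=np.zeros(0),
    pw_leg=np.zeros(0, dtype=np.int64),
)


class SimulationEngine:
    """Rollout driver around the compiled kernel for one model."""

    def __init__(self, model: ModelDefinition, dt: float = DT,
                 sample_rate: float = SAMPLE_RATE):
        self.model = model
        self.packed = pack_model(model)
        self.dt = dt
        self.sample_every = max(int(round(1.0 / (sample_rate * dt))), 1)

    # -- low-level ---------------------------------------------------------

    def rollout(self, q0, qd0=None, *, controller=None, u_const=None,
                tau_const=None, t_max: float = MAX_TIME,
                gravity: float = 9.81, enable_contact: bool = True,
                enable_muscles: bool = True, box_pos=None, locked=None,
                fall_ratio: float = FALL_RATIO) -> Trajectory:
        p = self.packed
        q0 = np.asarray(q0, dtype=float)
        qd0 = np.zeros_like(q0) if qd0 is None else np.asarray(qd0, dtype=float)
        locked_arr = np.zeros(len(q0), dtype=np.bool_)
        if locked is not None:
            for c in locked:
                locked_arr[self.model.coordinate_index(c)] = True

        if controller is not None:
            pw = controller.pathway_arrays(self.dt)
            x = controller.values()
            t1, t2, thr = controller.t1, controller.t2, controller.load_threshold
            u_mode = 0
            uc = np.zeros(K.NM)
            tc = np.zeros(2)
        else:
            pw = _NULL_PW
            x = np.zeros(1)
            t1, t2, thr = 1e9, 1e9, 0.1
            u_mode = 1
            uc = np.zeros(K.NM) if u_const is None else \
                np.asarray(u_const, dtype=float)
            tc = np.zeros(2) if tau_const is None else \
                np.asarray(tau_const, dtype=float)

        if box_pos is None:
            box_on, bx, by = False, 0.0, 0.0
        else:
            box_on, bx, by = True, float(box_pos[0]), float(box_pos[1])

        nsteps = int(math.floor(t_max / self.dt + 0.5))
        out = np.zeros((nsteps // self.sample_every + 2, K.NCOLS))

        status, nsamp, t_end, fell = K.rollout(
            p.parent, p.jtype, p.jsign, p.jpos, p.jcoord,
            p.mass, p.inertia, p.com,
            p.rev_coord, p.rev_sign, p.coord_body, p.desc,
            p.qlo, p.qhi, p.klim, p.dlim, p.pdamp, p.has_limit, locked_arr,
            p.fmax, p.lopt, p.lslack, p.vmax,
            p.vp_body, p.vp_loc, p.vp_off, p.span,
            0.010, 0.040, enable_muscles,
            p.sph_body, p.sph_loc, p.sph_r, p.sph_k, p.sph_c,
            p.sph_mus, p.sph_mud, p.sph_is_butt,
            box_on, bx, by, float(p.box_h[0]), float(p.box_h[1]),
            p.box_k, p.box_c, p.box_mus, p.box_mud,
            pw["pw_target"], pw["pw_phase"], pw["pw_statemask"],
            pw["pw_type"], pw["pw_source"], pw["pw_sign"],
            pw["pw_delay_steps"], pw["pw_gain_idx"], pw["pw_ofs_idx"],
            pw["pw_ofs_const"], pw["pw_leg"], np.asarray(x, dtype=float),
            float(t1), float(t2), float(thr),
            u_mode, uc, tc,
            q0, qd0, gravity, enable_contact, self.dt, t_max, fall_ratio,
            self.sample_every, p.head_body, p.head_loc, p.head_body,
            out,
        )
        if status == 1:
            raise RuntimeError(f"integration diverged (non-finite state) at t={t_end:.4f} s")
        if status == 2:
            raise RuntimeError(f"muscle equilibrium failure at t={t_end:.4f} s")
        return Trajectory(out[:nsamp], self.sample_every * self.dt, fell)

    # -- energy / diagnostics ---------------------------------------------

    def mass_matrix(self, q) -> np.ndarray:
        """Joint-space mass matrix assembled from body Jacobians (Python side)."""
        model, p = self.model, self.packed
        poses = model.body_transforms(q)
        n = model.dof_count
        M = np.zeros((n, n))
        centers = self._coord_centers(poses)
        for seg in model.body_order:
            b = p.body_index[seg]
            s = model.segments[seg]
            cw = model.point_in_world(poses, seg, s.com_offset)
            J = np.zeros((3, n))
            for ci in range(n):
                if not p.desc[b, ci]:
                    continue
                if p.rev_coord[ci]:
                    sg = p.rev_sign[ci]
                    r = cw - centers[ci]
                    J[:, ci] = [sg, -sg * r[1], sg * r[0]]
                else:
                    J[1 + ci, ci] = 1.0   # coords 0,1 are x,y prismatic
            M += J.T @ np.diag([s.inertia_zz, s.mass, s.mass]) @ J
        return M

    def _coord_centers(self, poses):
        model, p = self.model, self.packed
        centers = {}
        for ci in range(model.dof_count):
            if not p.rev_coord[ci]:
                continue
            if ci == 2:
                centers[ci] = poses[model.root_joint.child][1]
            else:
                jname = model.coordinates[ci]
                j = next(jj for jj in model.joints if jj.name == jname)
                centers[ci] = model._joint_world_center(poses, j)
        return centers

    def total_energy(self, q, qd, gravity: float = 9.81) -> float:
        M = self.mass_matrix(q)
        ke = 0.5 * float(np.asarray(qd) @ M @ np.asarray(qd))
        poses = self.model.body_transforms(q)
        pe = 0.0
        for seg in self.model.body_order:
            s = self.model.segments[seg]
            cw = self.model.point_in_world(poses, seg, s.com_offset)
            pe += s.mass * gravity * cw[1]
        return ke + pe

    def com_height(self, q) -> float:
        poses = self.model.body_transforms(q)
        m, cy = 0.0, 0.0
        for seg in self.model.body_order:
            s = self.model.segments[seg]
            cw = self.model.point_in_world(poses, seg, s.com_offset)
            m += s.mass
            cy += s.mass * cw[1]
        return cy / m
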