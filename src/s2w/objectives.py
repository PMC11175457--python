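"""Rollout scoring: mimic, gait-velocity, range, head-acceleration and
energy measures aggregated into one scalar objective.

Every measure is non-negative and exactly zero on its satisfying set.  When
all task measures are satisfied the weighted energy term
``J_total = w_mb*J_mb + w_act*J_act + w_T*J_T`` is the only non-zero
contribution.  Falls add a large penalty proportional to the missing
simulation time so that any falling rollout scores worse than any non-falling
one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .engine import Trajectory, detect_steps
from .model import MUSCLE_ORDER

# energy weights
W_MB = 0.01
W_ACT = 0.1
W_T = 0.0003

V_MIN = 0.8               # m/s minimum gait velocity
HEAD_ACC_THRESHOLD = 1.0  # m/s^2
FALL_PENALTY_RATE = 1000.0 / 12.0   # per missing second

#: coordinate range bounds [deg] for the range measures
RANGE_BOUNDS = {
    "lumbar": (-50.0, 0.0),
    "thoracic": (-15.0, 15.0),
    "pelvis_tilt": (-50.0, 30.0),
    "ankle_r": (-60.0, 60.0),
    "ankle_l": (-60.0, 60.0),
}
KNEE_LIMIT_STIFFNESS = 500.0   # N*m/rad beyond the knee range
KNEE_TORQUE_THRESHOLD = 0.0    # integrate any limit-torque magnitude

# metabolic model coefficients (documented fixture; activation/maintenance +
# shortening heat + positive mechanical work, 50% slow-twitch)
MB_SPECIFIC_TENSION = 2.5e5    # N/m^2
MB_MUSCLE_DENSITY = 1059.7     # kg/m^3
MB_AM_RATE = 50.0              # W/kg at full activation
MB_SHORT_RATE = 25.0           # W/kg per v_max at full activation
MB_BASAL_RATE = 1.2            # W/kg whole-body


@dataclass
class Corridor:
    """Pelvis-COM reference band over the stand-up interval."""
    times: np.ndarray          # s
    centers: np.ndarray        # (n, 2) m
    half_width: float = 0.10   # m

    def center_at(self, t):
        t = np.clip(t, self.times[0], self.times[-1])
        cx = np.interp(t, self.times, self.centers[:, 0])
        cy = np.interp(t, self.times, self.centers[:, 1])
        return np.stack([cx, cy], axis=-1)


def standup_corridor(start_com, target_com, duration: float = 2.0,
                     half_width: float = 0.10, n: int = 50) -> Corridor:
    """Quintic seated-to-standing pelvis-COM blend with a +/- half-width band.

    Stands in for the measured reference band: a rough stand-up trajectory
    without dictating a specific motion pattern.
    """
    s = np.linspace(0.0, 1.0, n)
    blend = 10 * s**3 - 15 * s**4 + 6 * s**5
    start = np.asarray(start_com, dtype=float)
    target = np.asarray(target_com, dtype=float)
    centers = start[None, :] + blend[:, None] * (target - start)[None, :]
    return Corridor(times=s * duration, centers=centers, half_width=half_width)


@dataclass
class MeasureConfig:
    corridor: Corridor | None = None
    v_min: float = V_MIN
    range_bounds: dict = field(default_factory=lambda: dict(RANGE_BOUNDS))
    head_acc_threshold: float = HEAD_ACC_THRESHOLD
    w_mb: float = W_MB
    w_act: float = W_ACT
    w_t: float = W_T
    t_max: float = 12.0


@dataclass
class ObjectiveReport:
    mimic: float = 0.0
    velocity: float = 0.0
    range_penalties: dict = field(default_factory=dict)
    head_acc: float = 0.0
    j_mb: float = 0.0
    j_act: float = 0.0
    j_t: float = 0.0
    j_total: float = 0.0
    fall: bool = False
    end_time: float = 0.0
    total: float = 0.0

    def as_dict(self):
        d = dict(mimic=self.mimic, velocity=self.velocity,
                 head_acc=self.head_acc, j_mb=self.j_mb, j_act=self.j_act,
                 j_t=self.j_t, j_total=self.j_total, fall=int(self.fall),
                 end_time=self.end_time, total=self.total)
        for k, v in self.range_penalties.items():
            d[f"range_{k}"] = v
        return d

    def write(self, path):
        with open(path, "w") as fh:
            for k, v in self.as_dict().items():
                fh.write(f"{k}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# individual measures


def mimic_measure(traj: Trajectory, corridor: Corridor | None) -> float:
    """Mean squared exceedance of the pelvis COM outside the corridor band."""
    if corridor is None or not math.isfinite(corridor.half_width):
        return 0.0
    t_end = min(traj.end_time, corridor.times[-1])
    mask = traj.time <= t_end + 1e-9
    if not mask.any():
        return 0.0
    com = traj.pelvis_com[mask]
    ref = corridor.center_at(traj.time[mask])
    dist = np.hypot(com[:, 0] - ref[:, 0], com[:, 1] - ref[:, 1])
    exceed = np.maximum(dist - corridor.half_width, 0.0)
    return float(np.mean(exceed ** 2))


def gait_velocity_measure(traj: Trajectory, v_min: float = V_MIN,
                          step_events=None) -> float:
    """Shortfall of the average forward pelvis velocity below ``v_min``.

    Averaged from the end of the third step to the end of the trajectory;
    with fewer than four steps the full post-stand-up (GAIT) interval is
    used.
    """
    if step_events is None:
        step_events = detect_steps(traj)
    t = traj.time
    x = traj.pelvis_com[:, 0]
    if len(step_events) >= 4:
        t_start = step_events[2][0]
    else:
        gait = traj.phase_mask("GAIT")
        t_start = t[gait][0] if gait.any() else t[0]
    i0 = int(np.searchsorted(t, t_start))
    i0 = min(i0, len(t) - 2)
    dt_span = t[-1] - t[i0]
    if dt_span <= 1e-9:
        return v_min
    v_avg = (x[-1] - x[i0]) / dt_span
    return float(max(0.0, v_min - v_avg))


def range_measure(traj: Trajectory, coordinate: str, bounds) -> float:
    """Time-integrated absolute exceedance beyond bounds [deg*s]."""
    lo, hi = bounds
    q = np.degrees(traj.coordinate(coordinate))
    exceed = np.maximum(q - hi, 0.0) + np.maximum(lo - q, 0.0)
    return float(np.trapezoid(exceed, traj.time))


def knee_limit_measure(traj: Trajectory, model,
                       threshold: float = KNEE_TORQUE_THRESHOLD) -> float:
    """Integrated knee limit-torque magnitude above threshold [N*m*s]."""
    total = 0.0
    for joint in ("knee_r", "knee_l"):
        q = traj.coordinate(joint)
        qd = traj.col(f"qd_{joint}")
        tau = np.array([abs(model.joint_limit_torque(joint, qi, qdi))
                        for qi, qdi in zip(q, qd)])
        total += float(np.trapezoid(np.maximum(tau - threshold, 0.0),
                                    traj.time))
    return total


def head_acceleration_measure(traj: Trajectory,
                              threshold: float = HEAD_ACC_THRESHOLD) -> float:
    """Time-integrated exceedance of |a_head| above the threshold."""
    acc = traj.head_acceleration
    return float(np.trapezoid(np.maximum(acc - threshold, 0.0), traj.time))


# ---------------------------------------------------------------------------
# energy


def metabolic_rate(traj: Trajectory, model) -> np.ndarray:
    """Whole-body metabolic rate [W] per sample (documented Hill-energetics
    fixture: activation/maintenance + shortening heat + positive CE work +
    basal rate)."""
    from .engine import MUSCLES_RL
    rate = np.full(len(traj), MB_BASAL_RATE * model.total_mass)
    for mi, name in enumerate(MUSCLES_RL):
        p = model.muscles[name]
        m_mass = p.f_max / MB_SPECIFIC_TENSION * p.l_opt * MB_MUSCLE_DENSITY
        a = traj.data[:, K.COL_A + mi]
        v = traj.data[:, K.COL_V + mi]            # l_opt/s, + lengthening
        f = traj.data[:, K.COL_FM + mi]
        h_am = m_mass * MB_AM_RATE * a ** 1.5
        h_s = m_mass * MB_SHORT_RATE * a * np.maximum(-v, 0.0) / p.v_max
        w_pos = np.maximum(-f * v * p.l_opt, 0.0)  # positive CE work rate
        rate += h_am + h_s + w_pos
    return rate


def energy_objective(traj: Trajectory, model,
                     w_mb: float = W_MB, w_act: float = W_ACT,
                     w_t: float = W_T):
    """(J_mb, J_act, J_T, J_total).

    J_act: sum over muscles of the time-average cubed activation.
    J_T: sum over the trunk joints of the time-average squared torque.
    J_mb: average metabolic rate during stand-up plus metabolic cost of
    transport (energy / distance) during gait.
    """
    t = traj.time
    dur = max(t[-1] - t[0], 1e-9)
    a3 = traj.activations ** 3
    j_act = float(np.trapezoid(a3.sum(axis=1), t) / dur)
    tau = traj.data[:, K.COL_TAU:K.COL_TAU + 2]
    j_t = float(np.trapezoid((tau ** 2).sum(axis=1), t) / dur)

    rate = metabolic_rate(traj, model)
    gait = traj.phase_mask("GAIT")
    standup = ~gait
    j_mb = 0.0
    if standup.sum() >= 2:
        ts = t[standup]
        j_mb += float(np.trapezoid(rate[standup], ts) / max(ts[-1] - ts[0], 1e-9))
    if gait.sum() >= 2:
        tg = t[gait]
        x = traj.pelvis_com[:, 0]
        dist = abs(x[-1] - x[np.argmax(gait)])
        energy = float(np.trapezoid(rate[gait], tg))
        j_mb += energy / max(dist, 0.1)
    j_total = w_mb * j_mb + w_act * j_act + w_t * j_t
    return j_mb, j_act, j_t, j_total


# ---------------------------------------------------------------------------
# aggregation


#: weights of the task measures in the total objective
W_MIMIC = 1000.0
W_VEL = 100.0
W_RANGE = 0.1
W_HEAD = 1.0


def evaluate(traj: Trajectory, model, config: MeasureConfig) -> ObjectiveReport:
    rep = ObjectiveReport(end_time=traj.end_time, fall=traj.fell)
    rep.mimic = mimic_measure(traj, config.corridor)
    rep.velocity = gait_velocity_measure(traj, config.v_min)
    for coord, bounds in config.range_bounds.items():
        rep.range_penalties[coord] = range_measure(traj, coord, bounds)
    rep.range_penalties["knee_limit"] = knee_limit_measure(traj, model)
    rep.head_acc = head_acceleration_measure(traj, config.head_acc_threshold)
    rep.j_mb, rep.j_act, rep.j_t, rep.j_total = energy_objective(
        traj, model, config.w_mb, config.w_act, config.w_t)
    rep.total = total_objective(rep, config)
    return rep


def total_objective(rep: ObjectiveReport, config: MeasureConfig) -> float:
    """Weighted sum of all measures plus the fall penalty."""
    total = rep.j_total
    total += W_MIMIC * rep.mimic
    total += W_VEL * rep.velocity
    total += W_RANGE * sum(rep.range_penalties.values())
    total += W_HEAD * rep.head_acc
    if rep.fall:
        total += FALL_PENALTY_RATE * (config.t_max - rep.end_time) + 1000.0
    return float(total)
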