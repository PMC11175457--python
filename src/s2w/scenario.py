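"""Scenario configuration, seated-posture construction, result bundles and
post-processing (trunk angle, joint loading, condition comparison).

A scenario fixes the seat height, the initial seated posture (solved from
the chair geometry with ~90 deg knee flexion and optional per-foot
anterior-posterior offsets), the simulation cap and the measure
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import _kernel as K
from .engine import SimulationEngine, Trajectory, detect_steps
from .model import COORDINATES, ModelDefinition, Posture, build_model
from .objectives import (Corridor, MeasureConfig, ObjectiveReport, evaluate,
                         standup_corridor)

GRAV = 9.81

_SCENARIO_KEYS = {
    "name", "seat_height", "foot_offset_r", "foot_offset_l", "max_time",
    "v_min", "corridor_duration", "corridor_half_width", "posture",
    "chair_weight_share", "corridor_enabled",
}


@dataclass
class ScenarioConfig:
    name: str = "normal_seat"
    seat_height: float = 0.44          # m, top surface of the chair box
    foot_offset_r: float = 0.0         # m, anterior(+)/posterior(-) shift
    foot_offset_l: float = 0.0
    max_time: float = 12.0
    v_min: float = 0.8
    corridor_duration: float = 2.0
    corridor_half_width: float = 0.10
    corridor_enabled: bool = True
    chair_weight_share: float = 0.75   # initial fraction of BW on the chair
    posture: Posture | None = None     # explicit override

    def __post_init__(self):
        if self.seat_height <= 0:
            raise ValueError("seat height must be > 0")


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a scenario file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    posture = raw.pop("posture", None)
    sc = ScenarioConfig(**raw)
    if posture is not None:
        sc.posture = Posture(posture).validate()
    return sc


def default_scenario_dir() -> Path:
    return Path(__file__).parent / "data" / "scenarios"


# ---------------------------------------------------------------------------
# seated posture construction


def seated_posture(model: ModelDefinition, scenario: ScenarioConfig) -> Posture:
    """Seated start: trunk upright, ~90 deg knees, feet flat, buttocks on
    the chair with ``chair_weight_share`` of body weight carried by the seat.
    """
    if scenario.posture is not None:
        return scenario.posture

    butt = next(s for s in model.spheres if s.parent == "pelvis")
    eng_k = _box_stiffness(model, butt.radius)
    w_chair = scenario.chair_weight_share * model.total_mass * GRAV
    pen = (w_chair / eng_k) ** (2.0 / 3.0)
    pelvis_y = scenario.seat_height + butt.radius - pen - butt.center[1]

    l_f = abs(model.pin_joints["tibia_r"].pos_in_parent[1])   # femur length
    l_t = abs(model.pin_joints["foot_r"].pos_in_parent[1])    # tibia length
    ankle_y = _standing_ankle_height(model)

    # default forward foot placement: shank vertical under the knee
    knee_y = ankle_y + l_t
    cos_a = np.clip((pelvis_y - knee_y) / l_f, -1.0, 1.0)
    alpha = math.acos(cos_a)
    ankle_x0 = l_f * math.sin(alpha)

    p = Posture({c: 0.0 for c in COORDINATES})
    p["pelvis_tx"] = 0.0
    p["pelvis_ty"] = pelvis_y
    for side, off in (("r", scenario.foot_offset_r),
                      ("l", scenario.foot_offset_l)):
        ax, ay = ankle_x0 + off, ankle_y
        dx, dy = ax - 0.0, ay - pelvis_y
        d = math.hypot(dx, dy)
        d = min(d, l_f + l_t - 1e-6)
        knee_inner = math.acos(
            np.clip((l_f**2 + l_t**2 - d**2) / (2 * l_f * l_t), -1.0, 1.0))
        knee_flex = math.pi - knee_inner
        phi = math.atan2(dx, -dy)
        psi = math.acos(np.clip((l_f**2 + d**2 - l_t**2) / (2 * l_f * d),
                                -1.0, 1.0))
        hip_flex = phi + psi
        ankle = knee_flex - hip_flex       # foot flat on the ground
        p[f"hip_{side}"] = math.degrees(hip_flex)
        p[f"knee_{side}"] = math.degrees(knee_flex)
        p[f"ankle_{side}"] = math.degrees(ankle)
    return p


def _standing_ankle_height(model: ModelDefinition) -> float:
    """Ankle height with foot spheres touching the ground."""
    sph = [s for s in model.spheres if s.parent == "foot_r"]
    return max(s.radius - s.center[1] for s in sph)


def _box_stiffness(model, radius):
    from .model import hertz_stiffness
    return hertz_stiffness(model.box.plane_strain_modulus, radius)


def chair_position(model: ModelDefinition, scenario: ScenarioConfig,
                   posture: Posture) -> tuple:
    """Chair box centre in world frame: under the buttock sphere, top surface
    at the scenario seat height."""
    butt = next(s for s in model.spheres if s.parent == "pelvis")
    cx = posture["pelvis_tx"] + butt.center[0]
    cy = scenario.seat_height - model.box.half_extents[1]
    return (cx, cy)


def build_corridor(model: ModelDefinition, scenario: ScenarioConfig,
                   posture: Posture) -> Corridor | None:
    if not scenario.corridor_enabled:
        return None
    q0 = posture.to_q()
    poses = model.body_transforms(q0)
    pel = model.segments[model.root_joint.child]
    start = model.point_in_world(poses, pel.name, pel.com_offset)
    ankle_x = []
    for side in ("r", "l"):
        j = model.pin_joints[f"foot_{side}"]
        ankle_x.append(model._joint_world_center(poses, j)[0])
    stand_y = model.meta.get("standing_pelvis_height", 0.95) + pel.com_offset[1]
    target = np.array([np.mean(ankle_x) + pel.com_offset[0], stand_y])
    return standup_corridor(start, target, scenario.corridor_duration,
                            scenario.corridor_half_width)


def measure_config(model, scenario: ScenarioConfig,
                   posture: Posture) -> MeasureConfig:
    return MeasureConfig(
        corridor=build_corridor(model, scenario, posture),
        v_min=scenario.v_min, t_max=scenario.max_time)


def simulate_scenario(engine: SimulationEngine, scenario: ScenarioConfig,
                      controller=None, **kw) -> Trajectory:
    posture = seated_posture(engine.model, scenario)
    return engine.rollout(
        posture.to_q(), controller=controller,
        box_pos=chair_position(engine.model, scenario, posture),
        t_max=scenario.max_time, **kw)


# ---------------------------------------------------------------------------
# post-processing


def trunk_angle(traj: Trajectory) -> np.ndarray:
    """Forward inclination of the torso long axis from vertical [deg]."""
    theta = (-traj.coordinate("pelvis_tilt")
             + traj.coordinate("lumbar") + traj.coordinate("thoracic"))
    return -np.degrees(theta)


def peak_trunk_angle(traj: Trajectory, phase: str | None = None) -> float:
    ang = trunk_angle(traj)
    if phase is not None:
        mask = traj.phase_mask(phase)
        if not mask.any():
            raise ValueError(f"phase {phase!r} not present in trajectory")
        ang = ang[mask]
    return float(ang.max())


def seat_off_time(traj: Trajectory, threshold: float = 1.0) -> float | None:
    """First time the seat force drops to ~zero and stays off >= 100 ms."""
    fy = traj.seat_force[:, 1]
    t = traj.time
    hold = max(int(0.1 / traj.dt_sample), 1)
    for i in range(len(fy)):
        if fy[i] < threshold and np.all(fy[i:i + hold] < threshold):
            return float(t[i])
    return None


_JOINT_CROSSING_CACHE: dict = {}


def joint_reaction_load(traj: Trajectory, model: ModelDefinition,
                        joint: str, gravity: float = GRAV) -> np.ndarray:
    """|resultant force| [N] transmitted through a pin joint, including the
    reaction to muscle forces crossing it.

    Newton balance of the distal subsystem per sample:
    ``R = sum m (a - g) - F_contact - F_muscles_on_distal``.
    """
    j = model._get_pin_joint(joint)
    below = model._descendants(j.child)
    t = traj.time
    n = len(t)

    # body COM positions of the distal subsystem
    segs = [model.segments[s] for s in model.body_order if s in below]
    com = np.zeros((n, 2))
    msum = sum(s.mass for s in segs)
    qcols = np.array([traj.coordinate(c) for c in model.coordinates]).T
    poses_all = [model.body_transforms(q) for q in qcols]
    for s in segs:
        pts = np.array([model.point_in_world(poses, s.name, s.com_offset)
                        for poses in poses_all])
        com += s.mass * pts
    com /= msum
    dt = traj.dt_sample
    acc = np.gradient(np.gradient(com, dt, axis=0), dt, axis=0) \
        if n >= 3 else np.zeros_like(com)

    # contact force on the distal subsystem
    contact = np.zeros((n, 2))
    side = "_r" if joint.endswith("_r") else "_l" if joint.endswith("_l") else None
    if side and any(f"foot{side}" == s.name for s in segs):
        contact = traj.grf(side[1])
    if model.root_joint.child in below:
        contact = contact + traj.seat_force

    # muscle forces pulling the distal subsystem toward the proximal side
    from .engine import MUSCLES_RL
    fmus = np.zeros((n, 2))
    for mi, name in enumerate(MUSCLES_RL):
        mp = model.muscles[name]
        crossing = None
        for (sa, la), (sb, lb) in zip(mp.path, mp.path[1:]):
            if (sa in below) != (sb in below):
                crossing = ((sa, la), (sb, lb))
                break
        if crossing is None:
            continue
        (sa, la), (sb, lb) = crossing
        if sa in below:      # ensure b = distal attachment
            (sa, la), (sb, lb) = (sb, lb), (sa, la)
        f = traj.data[:, K.COL_FM + mi]
        for i, poses in enumerate(poses_all):
            pa = model.point_in_world(poses, sa, la)
            pb = model.point_in_world(poses, sb, lb)
            u = pa - pb
            nrm = np.hypot(u[0], u[1])
            if nrm > 1e-9:
                fmus[i] += f[i] * u / nrm

    g = np.array([0.0, -gravity])
    r = msum * acc - msum * g[None, :] - contact - fmus
    return np.hypot(r[:, 0], r[:, 1])


def stepping_leg(traj: Trajectory) -> str:
    """Leg in swing during the initial step (first step event leg)."""
    events = detect_steps(traj)
    if events:
        return events[0][1]
    # fallback: leg with lower average load after stand-up
    gait = traj.phase_mask("GAIT")
    if gait.any():
        r = traj.grf("r")[gait, 1].mean()
        l = traj.grf("l")[gait, 1].mean()
        return "r" if r < l else "l"
    return "r"


def summarize(traj: Trajectory, model: ModelDefinition) -> dict:
    """Derived summary, a pure function of the trajectory."""
    bw = model.total_mass * GRAV
    step_leg = stepping_leg(traj)
    stance_leg = "l" if step_leg == "r" else "r"
    out = {
        "end_time": traj.end_time,
        "fell": int(traj.fell),
        "seat_off_time": seat_off_time(traj),
        "peak_trunk_angle_P1": (peak_trunk_angle(traj, "P1")
                                if traj.phase_mask("P1").any() else None),
        "peak_trunk_angle_standup": float(
            trunk_angle(traj)[~traj.phase_mask("GAIT")].max())
        if (~traj.phase_mask("GAIT")).any() else None,
        "stepping_leg": step_leg,
        "forward_displacement": float(traj.pelvis_com[-1, 0]
                                      - traj.pelvis_com[0, 0]),
        "n_steps": len(detect_steps(traj)),
    }
    for jname in ("hip", "knee", "ankle"):
        for role, leg in (("step", step_leg), ("stance", stance_leg)):
            load = joint_reaction_load(traj, model, f"{jname}_{leg}")
            out[f"peak_{jname}_load_{role}"] = float(load.max())
            out[f"peak_{jname}_load_{role}_bw"] = float(load.max() / bw)
    tau_l = traj.col("tau_lumbar")
    tau_t = traj.col("tau_thoracic")
    so = out["seat_off_time"]
    if so is not None:
        after = traj.time >= so
        out["peak_lumbar_torque_post_seatoff"] = float(
            np.abs(tau_l[after]).max())
        out["peak_thoracic_torque_post_seatoff"] = float(
            np.abs(tau_t[after]).max())
    return out


def compare_conditions(baseline: dict, alternative: dict) -> dict:
    """Percent change (alt - base)/base * 100 for each shared numeric metric."""
    out = {}
    for k, b in baseline.items():
        a = alternative.get(k)
        if isinstance(b, (int, float)) and isinstance(a, (int, float)) \
                and not isinstance(b, bool) and b not in (0, None):
            out[k] = (a - b) / b * 100.0
    return out


# ---------------------------------------------------------------------------
# result bundle I/O


@dataclass
class ResultBundle:
    trajectory: Trajectory
    report: ObjectiveReport
    summary: dict
    controller: object = None


def write_results(bundle, out_dir) -> list:
    """Write trajectory CSV, objective report, parameters and summary."""
    out_dir = Path(out_dir)
    if len(bundle.trajectory) < 2:
        raise ValueError("refusing to write an empty trajectory")
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    p = out_dir / "trajectory.csv"
    bundle.trajectory.write_csv(p)
    written.append(p)
    p = out_dir / "objective.txt"
    bundle.report.write(p)
    written.append(p)
    p = out_dir / "summary.txt"
    with open(p, "w") as fh:
        for k, v in bundle.summary.items():
            fh.write(f"{k}\t{v}\n")
    written.append(p)
    if bundle.controller is not None:
        p = out_dir / "best.par"
        bundle.controller.save(p)
        written.append(p)
    return written
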