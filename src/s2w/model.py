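"""Planar musculoskeletal model: segments, joints, muscle paths, contact geometry.

The model is a sagittal-plane kinematic tree rooted at the pelvis, which is
connected to the ground through a 3-DOF planar-free joint (x, y, tilt).  All
other joints are pins.  Muscle paths are ordered via-point polylines; muscle
moment arms follow the tendon-excursion convention (``r = -dL/dq``), so a
positive moment arm produces a positive joint torque for a positive (tensile)
muscle force.

Coordinate conventions: x forward, y up, angles CCW-positive internally.
Generalized coordinates use clinical signs (hip/knee flexion positive, ankle
dorsiflexion positive, pelvis anterior tilt positive, lumbar/thoracic
extension positive); each joint carries an ``axis sign`` mapping the clinical
angle onto the tree rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

GRAVITY = 9.81

#: generalized-coordinate order; tree joints are laid out in the same order.
COORDINATES = (
    "pelvis_tx", "pelvis_ty", "pelvis_tilt",
    "lumbar", "thoracic",
    "hip_r", "knee_r", "ankle_r",
    "hip_l", "knee_l", "ankle_l",
)

ANGULAR_COORDS = frozenset(COORDINATES[2:])

MUSCLE_ORDER = ("HAM", "BFSH", "GMAX", "ILIAC", "PSOAS",
                "RFEM", "VAS", "GAS", "SOL", "TA")

#: dimensionless unit-scale applied to the plane-strain moduli stored in the
#: model file before the Hertz stiffness derivation.  The stored moduli are
#: kept verbatim from the source description; interpreted SI-verbatim they
#: yield decimetre-scale static penetrations (the model would wade through
#: the floor), so they are rescaled to give millimetre-scale penetration
#: under body weight, preserving the printed feet:chair stiffness ratio.
MODULUS_UNIT_SCALE = 1.0e2


class ModelError(ValueError):
    """Raised for schema violations or construction-rule failures."""


@dataclass(frozen=True)
class BodySegment:
    name: str
    mass: float
    inertia_zz: float
    com_offset: np.ndarray      # COM in segment frame [m]
    length: float

    def __post_init__(self):
        if self.mass < 0:
            raise ModelError(f"segment {self.name}: mass must be >= 0")
        if self.inertia_zz < 0:
            raise ModelError(f"segment {self.name}: inertia must be >= 0")


@dataclass(frozen=True)
class Joint:
    name: str
    parent: str
    child: str
    kind: str                   # "pin" | "planar-free"
    pos_in_parent: np.ndarray   # joint centre in parent frame [m]
    axis_sign: float = 1.0      # clinical angle -> CCW tree rotation
    q_min: float = -math.inf    # rad (pin joints)
    q_max: float = math.inf
    limit_stiffness: float = 0.0  # N*m/rad outside the range
    limit_damping: float = 0.0    # N*m*s/rad, ramped in over LIMIT_RAMP
    passive_damping: float = 0.0  # N*m*s/rad viscous damping, always active


@dataclass(frozen=True)
class MTUParams:
    name: str
    f_max: float        # N
    l_opt: float        # m
    l_slack: float      # m
    v_max: float        # l_opt/s
    path: tuple         # ((segment, np.ndarray(2)), ...)

    def __post_init__(self):
        if min(self.f_max, self.l_opt, self.l_slack) <= 0:
            raise ModelError(f"muscle {self.name}: f_max/l_opt/l_slack must be > 0")
        if len(self.path) < 2:
            raise ModelError(f"muscle {self.name}: path needs >= 2 via-points")


@dataclass(frozen=True)
class ContactSphere:
    parent: str
    center: np.ndarray
    radius: float
    plane_strain_modulus: float   # as stored in the model file
    dissipation: float            # s/m
    mu_static: float
    mu_dynamic: float

    @property
    def stiffness(self) -> float:
        return hertz_stiffness(self.plane_strain_modulus, self.radius)


@dataclass(frozen=True)
class ContactBox:
    half_extents: np.ndarray      # (hx, hy) [m]
    plane_strain_modulus: float
    dissipation: float
    mu_static: float
    mu_dynamic: float


def hertz_stiffness(plane_strain_modulus: float, radius: float) -> float:
    """Hertzian sphere-plane stiffness ``k`` such that ``F = k * x**1.5``.

    ``k = 4/3 * E* * sqrt(R)`` with the stored modulus rescaled by
    :data:`MODULUS_UNIT_SCALE` (see module docstring).
    """
    return (4.0 / 3.0) * plane_strain_modulus * MODULUS_UNIT_SCALE * math.sqrt(radius)


class Posture(dict):
    """Mapping coordinate name -> angle (deg) or position (m); velocities zero."""

    def validate(self):
        missing = [c for c in COORDINATES if c not in self]
        if missing:
            raise ModelError(f"posture missing coordinates: {missing}")
        extra = [c for c in self if c not in COORDINATES]
        if extra:
            raise ModelError(f"posture has unknown coordinates: {extra}")
        return self

    def to_q(self) -> np.ndarray:
        self.validate()
        q = np.empty(len(COORDINATES))
        for i, c in enumerate(COORDINATES):
            v = float(self[c])
            q[i] = math.radians(v) if c in ANGULAR_COORDS else v
        return q

    @classmethod
    def from_q(cls, q: Sequence[float]) -> "Posture":
        p = cls()
        for i, c in enumerate(COORDINATES):
            p[c] = math.degrees(q[i]) if c in ANGULAR_COORDS else float(q[i])
        return p


# ---------------------------------------------------------------------------
# model definition


LIMIT_RAMP = 0.01  # rad over which limit damping fades in (keeps torque C0)


class ModelDefinition:
    """Constructed planar model: kinematic tree + muscles + contact geometry."""

    def __init__(self, segments, joints, muscles, spheres, box, meta):
        self.segments: dict[str, BodySegment] = {s.name: s for s in segments}
        self.joints: list[Joint] = list(joints)
        self.muscles: dict[str, MTUParams] = {m.name: m for m in muscles}
        self.spheres: list[ContactSphere] = list(spheres)
        self.box: ContactBox = box
        self.meta = dict(meta)
        self._build_tree()
        self._validate()

    # -- construction ------------------------------------------------------

    def _build_tree(self):
        free = [j for j in self.joints if j.kind == "planar-free"]
        pins = [j for j in self.joints if j.kind == "pin"]
        if len(free) != 1:
            raise ModelError(f"expected exactly 1 planar-free joint, got {len(free)}")
        root = free[0]
        if root.parent != "ground":
            raise ModelError("planar-free joint must attach to ground")

        order = [root.child]
        child_of = {}
        for j in pins:
            child_of.setdefault(j.parent, []).append(j)
        seen = set(order)
        i = 0
        while i < len(order):
            for j in child_of.get(order[i], []):
                if j.child in seen:
                    raise ModelError(f"segment {j.child} has two parent joints")
                order.append(j.child)
                seen.add(j.child)
            i += 1
        if seen != set(self.segments):
            raise ModelError(f"disconnected segments: {set(self.segments) - seen}")

        self.root_joint = root
        self.body_order = order                      # segment names, tree order
        self.pin_joints = {j.child: j for j in pins}
        # coordinate list: 3 root coords then one per pin joint, in the order
        # the joints appear in the model file (the file order is canonical)
        self.coordinates = ["pelvis_tx", "pelvis_ty", "pelvis_tilt"]
        self.coordinates += [j.name for j in pins]

    def _validate(self):
        n_expect = self.meta.get("expected_dof")
        if n_expect is not None and self.dof_count != n_expect:
            raise ModelError(
                f"construction error: DOF = {self.dof_count}, expected {n_expect}")
        m_expect = self.meta.get("expected_muscles")
        if m_expect is not None and self.muscle_count != m_expect:
            raise ModelError(
                f"construction error: muscles = {self.muscle_count}, expected {m_expect}")
        mass_expect = self.meta.get("total_mass")
        if mass_expect is not None and abs(self.total_mass - mass_expect) > 1e-6:
            raise ModelError(
                f"total mass {self.total_mass:.6f} kg != {mass_expect} kg")
        for m in self.muscles.values():
            for seg, _ in m.path:
                if seg not in self.segments:
                    raise ModelError(f"muscle {m.name}: unknown segment {seg!r}")

    # -- basic queries -----------------------------------------------------

    @property
    def dof_count(self) -> int:
        return len(self.coordinates)

    @property
    def muscle_count(self) -> int:
        return len(self.muscles)

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    def coordinate_index(self, name: str) -> int:
        return self.coordinates.index(name)

    # -- kinematics --------------------------------------------------------

    def body_transforms(self, q: np.ndarray):
        """World pose (theta, origin xy) of every segment at coordinates q.

        Returns dict name -> (theta, np.ndarray origin).
        """
        q = np.asarray(q, dtype=float)
        poses = {}
        root = self.root_joint
        th = root.axis_sign * q[2]
        poses[root.child] = (th, np.array([q[0], q[1]]))
        for name in self.body_order[1:]:
            j = self.pin_joints[name]
            pth, porg = poses[j.parent]
            qi = q[self.coordinate_index(j.name)]
            c, s = math.cos(pth), math.sin(pth)
            org = porg + np.array([c * j.pos_in_parent[0] - s * j.pos_in_parent[1],
                                   s * j.pos_in_parent[0] + c * j.pos_in_parent[1]])
            poses[name] = (pth + j.axis_sign * qi, org)
        return poses

    def point_in_world(self, poses, segment: str, local: np.ndarray) -> np.ndarray:
        th, org = poses[segment]
        c, s = math.cos(th), math.sin(th)
        return org + np.array([c * local[0] - s * local[1],
                               s * local[0] + c * local[1]])

    def _joint_world_center(self, poses, joint: Joint) -> np.ndarray:
        if joint.kind == "planar-free":
            return poses[joint.child][1].copy()
        th, org = poses[joint.parent]
        c, s = math.cos(th), math.sin(th)
        p = joint.pos_in_parent
        return org + np.array([c * p[0] - s * p[1], s * p[0] + c * p[1]])

    def _descendants(self, segment: str) -> set:
        out, stack = set(), [segment]
        while stack:
            s = stack.pop()
            out.add(s)
            stack.extend(j.child for j in self.joints
                         if j.kind == "pin" and j.parent == s)
        return out

    # -- muscle geometry ---------------------------------------------------

    def muscle_points_world(self, poses, muscle: str):
        m = self._get_muscle(muscle)
        return [self.point_in_world(poses, seg, loc) for seg, loc in m.path]

    def muscle_tendon_length(self, q: np.ndarray, muscle: str) -> float:
        poses = self.body_transforms(q)
        pts = self.muscle_points_world(poses, muscle)
        return float(sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])))

    def muscle_spans(self, muscle: str, joint_name: str) -> bool:
        m = self._get_muscle(muscle)
        j = self._get_pin_joint(joint_name)
        below = self._descendants(j.child)
        segs = {seg for seg, _ in m.path}
        return bool(segs & below) and bool(segs - below)

    def moment_arm(self, q: np.ndarray, muscle: str, joint_name: str) -> float:
        """Tendon-excursion moment arm ``-dL/dq`` about a pin joint [m]."""
        m = self._get_muscle(muscle)
        j = self._get_pin_joint(joint_name)
        if not self.muscle_spans(muscle, joint_name):
            import warnings
            warnings.warn(f"muscle {muscle} does not span joint {joint_name}")
            return 0.0
        poses = self.body_transforms(q)
        pts = self.muscle_points_world(poses, muscle)
        cj = self._joint_world_center(poses, j)
        below = self._descendants(j.child)
        sign = j.axis_sign
        dL = 0.0
        for (sa, _), (sb, _), pa, pb in zip(m.path, m.path[1:], pts, pts[1:]):
            seg_vec = pb - pa
            norm = np.linalg.norm(seg_vec)
            if norm < 1e-12:
                continue
            e = seg_vec / norm
            dpa = self._point_partial(pa, cj, sign) if sa in below else np.zeros(2)
            dpb = self._point_partial(pb, cj, sign) if sb in below else np.zeros(2)
            dL += float(e @ (dpb - dpa))
        return -dL

    @staticmethod
    def _point_partial(p, center, sign):
        r = p - center
        return sign * np.array([-r[1], r[0]])

    def _get_muscle(self, name: str) -> MTUParams:
        try:
            return self.muscles[name]
        except KeyError:
            raise ModelError(f"unknown muscle {name!r}") from None

    def _get_pin_joint(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name and j.kind == "pin":
                return j
        raise ModelError(f"unknown pin joint {name!r}")

    # -- joint limits ------------------------------------------------------

    def joint_limit_torque(self, joint_name: str, q: float, qdot: float) -> float:
        j = self._get_pin_joint(joint_name)
        return joint_limit_torque(q, qdot, j.q_min, j.q_max,
                                  j.limit_stiffness, j.limit_damping)

    # -- reference posture / height ---------------------------------------

    def standing_posture(self) -> Posture:
        p = Posture({c: 0.0 for c in COORDINATES})
        p["pelvis_ty"] = self.meta.get("standing_pelvis_height", 0.0)
        return p

    def standing_height(self) -> float:
        """Top of the torso above the ground at the reference standing posture."""
        q = self.standing_posture().to_q()
        poses = self.body_transforms(q)
        torso = self.segments[self.body_order[-1] if "torso" not in self.segments
                              else "torso"]
        top = self.point_in_world(poses, torso.name, np.array([0.0, torso.length]))
        return float(top[1])


def joint_limit_torque(q, qdot, q_min, q_max, stiffness, damping):
    """Restoring torque outside [q_min, q_max]; zero inside; C0 at the bounds.

    Outside the range the torque is ``-k*excess`` plus a damping term that
    ramps in linearly over LIMIT_RAMP rad so the total is continuous.
    """
    if q > q_max:
        excess = q - q_max
    elif q < q_min:
        excess = q - q_min
    else:
        return 0.0
    ramp = min(abs(excess) / LIMIT_RAMP, 1.0)
    return -stiffness * excess - damping * qdot * ramp


# ---------------------------------------------------------------------------
# parsing


def default_model_file() -> Path:
    return Path(__file__).parent / "data" / "h1120_planar.yaml"


def build_model(source=None) -> ModelDefinition:
    """Build a model from a YAML definition file (or an equivalent mapping)."""
    if source is None:
        source = default_model_file()
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    return _from_raw(raw)


def _req(record, key, where):
    try:
        return record[key]
    except (KeyError, TypeError):
        raise ModelError(f"{where}: missing field {key!r}") from None


def _from_raw(raw) -> ModelDefinition:
    segments = []
    for rec in _req(raw, "segments", "model"):
        name = _req(rec, "name", "segment")
        segments.append(BodySegment(
            name=name,
            mass=float(_req(rec, "mass", f"segment {name}")),
            inertia_zz=float(_req(rec, "inertia", f"segment {name}")),
            com_offset=np.array(_req(rec, "com", f"segment {name}"), dtype=float),
            length=float(_req(rec, "length", f"segment {name}")),
        ))

    joints = []
    for rec in _req(raw, "joints", "model"):
        name = _req(rec, "name", "joint")
        kind = _req(rec, "type", f"joint {name}")
        if kind not in ("pin", "planar-free"):
            raise ModelError(f"joint {name}: unknown type {kind!r}")
        rng = rec.get("range_deg", [-180.0, 180.0])
        joints.append(Joint(
            name=name,
            parent=_req(rec, "parent", f"joint {name}"),
            child=_req(rec, "child", f"joint {name}"),
            kind=kind,
            pos_in_parent=np.array(rec.get("pos_in_parent", [0.0, 0.0]), dtype=float),
            axis_sign=float(rec.get("axis_sign", 1.0)),
            q_min=math.radians(float(rng[0])),
            q_max=math.radians(float(rng[1])),
            limit_stiffness=float(rec.get("limit_stiffness", 0.0)),
            limit_damping=float(rec.get("limit_damping", 0.0)),
            passive_damping=float(rec.get("passive_damping", 0.0)),
        ))

    muscles = []
    for rec in _req(raw, "muscles", "model"):
        name = _req(rec, "name", "muscle")
        sides = ("_r", "_l") if rec.get("symmetric", True) else ("",)
        for suffix in sides:
            path = []
            for seg, xy in _req(rec, "path", f"muscle {name}"):
                seg_name = seg + suffix if seg + suffix in {s.name for s in segments} \
                    else seg
                path.append((seg_name, np.array(xy, dtype=float)))
            muscles.append(MTUParams(
                name=name + suffix,
                f_max=float(_req(rec, "f_max", f"muscle {name}")),
                l_opt=float(_req(rec, "l_opt", f"muscle {name}")),
                l_slack=float(_req(rec, "l_slack", f"muscle {name}")),
                v_max=float(rec.get("v_max", 10.0)),
                path=tuple(path),
            ))

    spheres = []
    for rec in _req(raw, "contact_spheres", "model"):
        sides = ("_r", "_l") if rec.get("symmetric", False) else ("",)
        for suffix in sides:
            parent = _req(rec, "parent", "contact sphere") + suffix
            if suffix and parent not in {s.name for s in segments}:
                raise ModelError(f"contact sphere: unknown parent {parent!r}")
            spheres.append(ContactSphere(
                parent=parent if suffix else _req(rec, "parent", "contact sphere"),
                center=np.array(_req(rec, "center", "contact sphere"), dtype=float),
                radius=float(_req(rec, "radius", "contact sphere")),
                plane_strain_modulus=float(_req(rec, "plane_strain_modulus",
                                                "contact sphere")),
                dissipation=float(rec.get("dissipation", 1.0)),
                mu_static=float(rec.get("mu_static", 0.9)),
                mu_dynamic=float(rec.get("mu_dynamic", 0.6)),
            ))

    b = _req(raw, "chair_box", "model")
    box = ContactBox(
        half_extents=np.array(_req(b, "half_extents", "chair_box"), dtype=float),
        plane_strain_modulus=float(_req(b, "plane_strain_modulus", "chair_box")),
        dissipation=float(b.get("dissipation", 1.0)),
        mu_static=float(b.get("mu_static", 0.9)),
        mu_dynamic=float(b.get("mu_dynamic", 0.6)),
    )

    return ModelDefinition(segments, joints, muscles, spheres, box,
                           raw.get("meta", {}))
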