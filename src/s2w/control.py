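"""Sit-to-walk control policy.

Three sequential phases: two stand-up reflex phases (P1, P2) switching at T1,
then a gait controller from T2 on.  Stand-up excitation per muscle follows

    U = C0 + K_L (L(t-dt) - L0) + K_F F(t-dt) + K_V V(t-dt)

summed over a monosynaptic pathway (excitatory), antagonistic pathways
(inhibitory, same structure driven by the opposing muscle's sensors) and a
vestibular PD on pelvis tilt routed to every muscle with an
extensor-positive/flexor-negative sign.  The torque-driven lumbar and
thoracic joints run delayed PD servos limited to +/-1000 N*m.  The gait
controller is a reflex state machine (Stance / Lift-off / Swing per leg,
gated by a stance load threshold on the leg's ground force) with
force-feedback plantarflexors, TA length feedback with SOL-force inhibition,
per-state BFSH/RFEM length+force gains, a VAS knee-angle suppression term
and stance-only vestibular balance on the hip-crossing muscles.

All neural delays are fixed on a 5 ms grid (see the ``derive_*`` functions);
gains, constants, offsets, transition times and the stance threshold are the
optimizer's free parameters — 551 of them in the default per-leg layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from . import _kernel as K
from .model import MUSCLE_ORDER

# ---------------------------------------------------------------------------
# neural latency derivation


@dataclass(frozen=True)
class LatencyConstants:
    h_reflex_sol: float = 30.2        # ms
    distal_motor: float = 3.3         # ms
    patellar_reflex: float = 21.0     # ms
    conduction_velocity: float = 50.0  # m/s
    gmax_sol_distance: float = 0.55   # m (0.50-0.60 printed range)
    sol_vestibular: float = 55.0      # ms
    thoracic_vestibular: float = 30.0  # ms


DEFAULT_CONSTANTS = LatencyConstants()

#: antagonist wiring per muscle (both sides)
ANTAGONISTS = {
    "HAM": ("RFEM", "VAS"),
    "BFSH": ("RFEM", "VAS"),
    "GMAX": ("ILIAC", "PSOAS"),
    "ILIAC": ("GMAX",),
    "PSOAS": ("GMAX",),
    "RFEM": ("HAM", "BFSH"),
    "VAS": ("HAM", "BFSH"),
    "GAS": ("TA",),
    "SOL": ("TA",),
    "TA": ("GAS", "SOL"),
}

#: vestibular routing sign: anterior-tilt error excites extensors (+),
#: inhibits flexors (-)
VESTIBULAR_SIGN = {
    "HAM": +1, "GMAX": +1, "VAS": +1, "GAS": +1, "SOL": +1,
    "BFSH": -1, "ILIAC": -1, "PSOAS": -1, "RFEM": -1, "TA": -1,
}

HIP_MUSCLES = ("HAM", "GMAX", "ILIAC", "PSOAS", "RFEM")


def _round5_half_up(x: float) -> int:
    return int(5 * math.floor(x / 5.0 + 0.5))


def _floor5(x: float) -> int:
    return int(5 * math.floor(x / 5.0 + 1e-9))


def derive_monosynaptic_latency(muscle: str,
                                constants: LatencyConstants = DEFAULT_CONSTANTS) -> int:
    """Monosynaptic reflex-loop latency [ms] on the 5 ms grid."""
    c = constants
    sol = _round5_half_up(c.h_reflex_sol + c.distal_motor)
    if muscle in ("SOL", "GAS", "TA"):
        return sol
    if muscle in ("GMAX", "ILIAC", "PSOAS"):
        dt_ms = 2.0 * c.gmax_sol_distance / c.conduction_velocity * 1000.0
        return _floor5(sol - dt_ms)
    if muscle == "RFEM":
        return _round5_half_up(c.patellar_reflex)
    if muscle in ("VAS", "BFSH"):
        return _round5_half_up(c.patellar_reflex)
    if muscle == "HAM":
        return 15
    raise KeyError(f"unknown muscle {muscle!r}")


def derive_antagonistic_latency(muscle: str, antagonist: str,
                                constants: LatencyConstants = DEFAULT_CONSTANTS) -> int:
    """Mean of the two monosynaptic delays, rounded half-up to 5 ms."""
    a = derive_monosynaptic_latency(muscle, constants)
    b = derive_monosynaptic_latency(antagonist, constants)
    return _round5_half_up(0.5 * (a + b))


def derive_vestibular_latency(muscle_or_joint: str,
                              constants: LatencyConstants = DEFAULT_CONSTANTS) -> int:
    """Vestibular latency [ms], floored to the 5 ms grid."""
    c = constants
    sol_mono = derive_monosynaptic_latency("SOL", constants)
    if muscle_or_joint == "lumbar":
        return _floor5(c.sol_vestibular - sol_mono / 2.0)
    if muscle_or_joint == "thoracic":
        return int(c.thoracic_vestibular)
    mono = derive_monosynaptic_latency(muscle_or_joint, constants)
    return _floor5(c.sol_vestibular - sol_mono / 2.0 + mono / 2.0)


def latency_table(constants: LatencyConstants = DEFAULT_CONSTANTS) -> dict:
    """Full latency table: muscle -> (mono, antagonistic, vestibular) [ms]
    plus 'lumbar' and 'thoracic' vestibular entries."""
    out = {}
    for m in MUSCLE_ORDER:
        out[m] = (
            derive_monosynaptic_latency(m, constants),
            derive_antagonistic_latency(m, ANTAGONISTS[m][0], constants),
            derive_vestibular_latency(m, constants),
        )
    out["lumbar"] = derive_vestibular_latency("lumbar", constants)
    out["thoracic"] = derive_vestibular_latency("thoracic", constants)
    return out


#: the stored reference table (mono, antagonistic, vestibular) in ms
REFERENCE_LATENCIES = {
    "HAM": (15, 20, 45), "BFSH": (20, 20, 45), "GMAX": (10, 10, 40),
    "ILIAC": (10, 10, 40), "PSOAS": (10, 10, 40), "RFEM": (20, 20, 45),
    "VAS": (20, 20, 45), "GAS": (35, 35, 55), "SOL": (35, 35, 55),
    "TA": (35, 35, 55), "lumbar": 35, "thoracic": 30,
}


# ---------------------------------------------------------------------------
# pathway primitives (reference implementations used by tests and docs;
# the rollout kernel evaluates the same packed records)


@dataclass(frozen=True)
class ReflexPathway:
    target: str
    source: str                    # muscle label or "vestibular"
    k_l: float = 0.0
    k_f: float = 0.0
    k_v: float = 0.0
    l0: float = 1.0
    c0: float = 0.0
    delay: float = 0.0             # s
    inhibitory: bool = False


def reflex_excitation(p: ReflexPathway, L_d: float, F_d: float, V_d: float) -> float:
    """Delayed proprioceptive contribution of one pathway (before clamping)."""
    u = p.c0 + p.k_l * (L_d - p.l0) + p.k_f * F_d + p.k_v * V_d
    return -u if p.inhibitory else u


@dataclass(frozen=True)
class VestibularPathway:
    target: str
    k_p: float = 0.0
    k_v: float = 0.0
    theta0: float = 0.0            # rad
    delay: float = 0.0
    sign: int = 1


def vestibular_excitation(p: VestibularPathway, theta_d: float,
                          thetad_d: float) -> float:
    return p.sign * (p.k_p * (theta_d - p.theta0) + p.k_v * thetad_d)


def gait_state_update(state: int, load: float, contra_load: float,
                      threshold: float, dwell_ok: bool = True) -> int:
    """One gait-state-machine transition step for a leg.

    load is the leg's ground force normalized by body weight.  Stance while
    loaded; Lift-off when unloading with the other leg loaded; Swing once the
    load reaches ~0; back to Stance on re-loading.
    """
    if not dwell_ok:
        return state
    if state == K.ST_STANCE:
        if load < threshold and contra_load >= threshold:
            return K.ST_LIFTOFF
    elif state == K.ST_LIFTOFF:
        if load <= K.SWING_LOAD:
            return K.ST_SWING
        if load >= threshold:
            return K.ST_STANCE
    else:
        if load >= threshold:
            return K.ST_STANCE
    return state


# ---------------------------------------------------------------------------
# full controller configuration


@dataclass
class Param:
    name: str
    value: float
    std: float
    lo: float
    hi: float


@dataclass
class _PwRec:
    target: int
    phase: int
    statemask: int
    ptype: int
    source: int
    sign: float
    delay_ms: int
    gain: str
    ofs: Optional[str] = None       # parameter name, or None -> constant
    ofs_const: float = 0.0
    leg: int = -1


def muscle_index(muscle: str, side: str) -> int:
    i = MUSCLE_ORDER.index(muscle)
    return i if side == "r" else i + len(MUSCLE_ORDER)


KA_THRESHOLD = 0.17    # rad knee flexion below which VAS is suppressed


class ControllerConfig:
    """Free-parameter registry plus the packed pathway table.

    ``sharing='per-leg'`` keeps independent left/right gains (the default;
    asymmetric strategies need it); ``sharing='symmetric'`` maps both sides
    onto one parameter set.
    """

    def __init__(self, sharing: str = "per-leg",
                 constants: LatencyConstants = DEFAULT_CONSTANTS):
        if sharing not in ("per-leg", "symmetric"):
            raise ValueError(f"unknown sharing mode {sharing!r}")
        self.sharing = sharing
        self.constants = constants
        self.params: list[Param] = []
        self._index: dict[str, int] = {}
        self.pathways: list[_PwRec] = []
        self._build()
        self._packed_cache = None

    # -- parameter registry ------------------------------------------------

    def _add(self, name: str, value: float, lo: float, hi: float) -> str:
        if name in self._index:
            raise ValueError(f"duplicate parameter {name}")
        std = 0.1 * (hi - lo)
        self._index[name] = len(self.params)
        self.params.append(Param(name, value, std, lo, hi))
        return name

    def _share(self, name: str, value: float, lo: float, hi: float) -> str:
        """Register once under the canonical (right-side) name when symmetric."""
        if self.sharing == "symmetric":
            name = name.replace(".l.", ".r.")
        if name in self._index:
            return name
        return self._add(name, value, lo, hi)

    def _canon(self, name: str) -> str:
        if self.sharing == "symmetric":
            return name.replace(".l.", ".r.")
        return name

    def __contains__(self, name):
        return self._canon(name) in self._index

    def __getitem__(self, name):
        return self.params[self._index[self._canon(name)]].value

    def __setitem__(self, name, value):
        p = self.params[self._index[self._canon(name)]]
        p.value = float(np.clip(value, p.lo, p.hi))
        self._packed_cache = None

    def names(self):
        return [p.name for p in self.params]

    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.params])

    def set_values(self, x: Iterable[float]):
        x = np.asarray(list(x), dtype=float)
        if len(x) != len(self.params):
            raise ValueError(f"expected {len(self.params)} values, got {len(x)}")
        for p, v in zip(self.params, x):
            p.value = float(np.clip(v, p.lo, p.hi))
        self._packed_cache = None

    def bounds(self):
        return (np.array([p.lo for p in self.params]),
                np.array([p.hi for p in self.params]))

    def stds(self) -> np.ndarray:
        return np.array([p.std for p in self.params])

    # convenience accessors for the phase schedule
    @property
    def t1(self) -> float:
        return self["T1"]

    @property
    def t2(self) -> float:
        t2 = self["T2"]
        return max(t2, self["T1"] + 0.05)   # keep 0 < T1 < T2

    @property
    def load_threshold(self) -> float:
        return self["load_threshold"]

    # -- construction ------------------------------------------------------

    def _build(self):
        mono = {m: derive_monosynaptic_latency(m, self.constants)
                for m in MUSCLE_ORDER}
        anta = {m: derive_antagonistic_latency(m, ANTAGONISTS[m][0],
                                               self.constants)
                for m in MUSCLE_ORDER}
        vest = {m: derive_vestibular_latency(m, self.constants)
                for m in MUSCLE_ORDER}
        lum_d = derive_vestibular_latency("lumbar", self.constants)
        thor_d = derive_vestibular_latency("thoracic", self.constants)

        # ---- stand-up phases
        for pi, ph in enumerate(("p1", "p2")):
            th0 = self._add(f"{ph}.theta0", 0.0, -0.8, 0.8)
            for side in ("r", "l"):
                for m in MUSCLE_ORDER:
                    mi = muscle_index(m, side)
                    base = f"{ph}.{side}.{m}"
                    c0 = self._share(f"{base}.C0", 0.05, 0.0, 1.0)
                    self.pathways.append(_PwRec(mi, pi, 7, K.PW_C, 0, 1.0,
                                                0, c0))
                    kl = self._share(f"{base}.mono.KL", 0.0, 0.0, 10.0)
                    kf = self._share(f"{base}.mono.KF", 0.0, 0.0, 5.0)
                    kv = self._share(f"{base}.mono.KV", 0.0, 0.0, 0.5)
                    d = mono[m]
                    self.pathways += [
                        _PwRec(mi, pi, 7, K.PW_L, mi, 1.0, d, kl,
                               ofs_const=1.0),
                        _PwRec(mi, pi, 7, K.PW_F, mi, 1.0, d, kf),
                        _PwRec(mi, pi, 7, K.PW_V, mi, 1.0, d, kv),
                    ]
                    for a in ANTAGONISTS[m]:
                        ai = muscle_index(a, side)
                        da = anta[m]
                        akl = self._share(f"{base}.anta_{a}.KL", 0.0, 0.0, 10.0)
                        akf = self._share(f"{base}.anta_{a}.KF", 0.0, 0.0, 5.0)
                        akv = self._share(f"{base}.anta_{a}.KV", 0.0, 0.0, 0.5)
                        self.pathways += [
                            _PwRec(mi, pi, 7, K.PW_L, ai, -1.0, da, akl,
                                   ofs_const=1.0),
                            _PwRec(mi, pi, 7, K.PW_F, ai, -1.0, da, akf),
                            _PwRec(mi, pi, 7, K.PW_V, ai, -1.0, da, akv),
                        ]
                    vp = self._share(f"{base}.vest.KP", 0.0, 0.0, 10.0)
                    vv = self._share(f"{base}.vest.KV", 0.0, 0.0, 2.0)
                    sgn = float(VESTIBULAR_SIGN[m])
                    self.pathways += [
                        _PwRec(mi, pi, 7, K.PW_VESTP, 0, sgn, vest[m], vp,
                               ofs=th0),
                        _PwRec(mi, pi, 7, K.PW_VESTD, 0, sgn, vest[m], vv),
                    ]
            for jn, (tgt, ch, dly) in (("lumbar", (20, K.CH_LUM, lum_d)),
                                       ("thoracic", (21, K.CH_THOR, thor_d))):
                kp = self._add(f"{ph}.{jn}.KP", 400.0, 0.0, 2000.0)
                kv = self._add(f"{ph}.{jn}.KV", 8.0, 0.0, 500.0)
                q0 = self._add(f"{ph}.{jn}.Q0", 0.0, -1.0, 0.5)
                self.pathways += [
                    _PwRec(tgt, pi, 7, K.PW_TRUNKP, ch, -1.0, dly, kp, ofs=q0),
                    _PwRec(tgt, pi, 7, K.PW_TRUNKD, ch + 1, -1.0, dly, kv),
                ]

        # ---- gait controller (phase 2)
        ST, LO, SW = 1, 2, 4
        for li, side in enumerate(("r", "l")):
            for m in MUSCLE_ORDER:
                mi = muscle_index(m, side)
                base = f"gait.{side}.{m}"
                c0 = self._share(f"{base}.C0", 0.02, 0.0, 1.0)
                self.pathways.append(_PwRec(mi, 2, 7, K.PW_C, 0, 1.0, 0, c0,
                                            leg=li))
                if m in HIP_MUSCLES:
                    vp = self._share(f"{base}.vest.KP", 0.0, 0.0, 10.0)
                    vv = self._share(f"{base}.vest.KV", 0.0, 0.0, 2.0)
                    sgn = float(VESTIBULAR_SIGN[m])
                    self.pathways += [
                        _PwRec(mi, 2, ST, K.PW_VESTP, 0, sgn, vest[m], vp,
                               leg=li),
                        _PwRec(mi, 2, ST, K.PW_VESTD, 0, sgn, vest[m], vv,
                               leg=li),
                    ]
                if m in ("ILIAC", "PSOAS", "RFEM"):
                    hi = muscle_index("HAM", side)
                    dly = derive_antagonistic_latency(m, "HAM", self.constants)
                    g = self._share(f"{base}.antaHAM.KL", 0.0, 0.0, 10.0)
                    lo = self._share(f"{base}.antaHAM.L0", 0.85, 0.4, 1.5)
                    self.pathways.append(_PwRec(mi, 2, SW, K.PW_L, hi, -1.0,
                                                dly, g, ofs=lo, leg=li))
                if m in ("RFEM", "BFSH"):
                    lof = self._share(f"{base}.L0", 0.85, 0.4, 1.5)
                    for st_name, mask in (("st", ST), ("lo", LO), ("sw", SW)):
                        gl = self._share(f"{base}.KL_{st_name}", 0.0, 0.0, 10.0)
                        gf = self._share(f"{base}.KF_{st_name}", 0.0, 0.0, 5.0)
                        self.pathways += [
                            _PwRec(mi, 2, mask, K.PW_L, mi, 1.0, mono[m], gl,
                                   ofs=lof, leg=li),
                            _PwRec(mi, 2, mask, K.PW_F, mi, 1.0, mono[m], gf,
                                   leg=li),
                        ]
                if m == "BFSH":
                    hi = muscle_index("HAM", side)
                    g = self._share(f"{base}.antaHAM.KF", 0.0, 0.0, 5.0)
                    self.pathways.append(_PwRec(mi, 2, LO | SW, K.PW_F, hi,
                                                -1.0, anta[m], g, leg=li))
                if m == "VAS":
                    gf = self._share(f"{base}.KF_st", 0.6, 0.0, 5.0)
                    self.pathways.append(_PwRec(mi, 2, ST, K.PW_F, mi, 1.0,
                                                mono[m], gf, leg=li))
                    ka = self._share(f"{base}.KA", 2.0, 0.0, 20.0)
                    ch = K.CH_KNEE_R if side == "r" else K.CH_KNEE_L
                    # knee-angle reference is a fixed constant, not optimized
                    self.pathways.append(_PwRec(mi, 2, ST, K.PW_KA, ch, -1.0,
                                                mono[m], ka,
                                                ofs_const=KA_THRESHOLD, leg=li))
                if m in ("GAS", "SOL"):
                    gf = self._share(f"{base}.KF", 0.7, 0.0, 5.0)
                    self.pathways.append(_PwRec(mi, 2, ST | LO, K.PW_F, mi,
                                                1.0, mono[m], gf, leg=li))
                if m == "TA":
                    gl = self._share(f"{base}.KL", 1.1, 0.0, 10.0)
                    lo = self._share(f"{base}.L0", 0.72, 0.4, 1.5)
                    self.pathways.append(_PwRec(mi, 2, 7, K.PW_L, mi, 1.0,
                                                mono[m], gl, ofs=lo, leg=li))
                    si = muscle_index("SOL", side)
                    gs = self._share(f"{base}.antaSOL.KF", 0.4, 0.0, 5.0)
                    self.pathways.append(_PwRec(mi, 2, 7, K.PW_F, si, -1.0,
                                                anta["TA"], gs, leg=li))
        for jn, (tgt, ch, dly) in (("lumbar", (20, K.CH_LUM, lum_d)),
                                   ("thoracic", (21, K.CH_THOR, thor_d))):
            kp = self._add(f"gait.{jn}.KP", 400.0, 0.0, 2000.0)
            kv = self._add(f"gait.{jn}.KV", 8.0, 0.0, 500.0)
            q0 = self._add(f"gait.{jn}.Q0", 0.0, -1.0, 0.5)
            self.pathways += [
                _PwRec(tgt, 2, 7, K.PW_TRUNKP, ch, -1.0, dly, kp, ofs=q0),
                _PwRec(tgt, 2, 7, K.PW_TRUNKD, ch + 1, -1.0, dly, kv),
            ]

        # ---- globals
        self._add("T1", 0.5, 0.1, 3.0)
        self._add("T2", 1.5, 0.3, 6.0)
        self._add("load_threshold", 0.1, 0.02, 0.5)

    # -- packing -----------------------------------------------------------

    def pathway_arrays(self, dt: float) -> dict:
        if self._packed_cache is not None and self._packed_cache[0] == dt:
            return self._packed_cache[1]
        n = len(self.pathways)
        arr = dict(
            pw_target=np.zeros(n, dtype=np.int64),
            pw_phase=np.zeros(n, dtype=np.int64),
            pw_statemask=np.zeros(n, dtype=np.int64),
            pw_type=np.zeros(n, dtype=np.int64),
            pw_source=np.zeros(n, dtype=np.int64),
            pw_sign=np.zeros(n),
            pw_delay_steps=np.zeros(n, dtype=np.int64),
            pw_gain_idx=np.zeros(n, dtype=np.int64),
            pw_ofs_idx=np.zeros(n, dtype=np.int64),
            pw_ofs_const=np.zeros(n),
            pw_leg=np.zeros(n, dtype=np.int64),
        )
        for i, p in enumerate(self.pathways):
            arr["pw_target"][i] = p.target
            arr["pw_phase"][i] = p.phase
            arr["pw_statemask"][i] = p.statemask
            arr["pw_type"][i] = p.ptype
            arr["pw_source"][i] = p.source
            arr["pw_sign"][i] = p.sign
            arr["pw_delay_steps"][i] = int(round(p.delay_ms * 1e-3 / dt))
            arr["pw_gain_idx"][i] = self._index[p.gain]
            arr["pw_ofs_idx"][i] = self._index[p.ofs] if p.ofs else -1
            arr["pw_ofs_const"][i] = p.ofs_const
            arr["pw_leg"][i] = p.leg
        self._packed_cache = (dt, arr)
        return arr

    # -- parameter file I/O ------------------------------------------------

    def save(self, path):
        with open(path, "w") as fh:
            fh.write("# name value std min max\n")
            for p in self.params:
                fh.write(f"{p.name}\t{p.value:.10g}\t{p.std:.10g}"
                         f"\t{p.lo:.10g}\t{p.hi:.10g}\n")

    def load(self, path):
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, value, std, lo, hi = line.split("\t")
                if name not in self._index:
                    raise ValueError(f"unknown parameter {name!r} in {path}")
                p = self.params[self._index[name]]
                p.value, p.std = float(value), float(std)
                p.lo, p.hi = float(lo), float(hi)
        self._packed_cache = None
        return self


def seated_hold_config(sharing: str = "per-leg") -> ControllerConfig:
    """Zero-excitation baseline: muscle pathways silent, trunk PD servos
    holding the lumbar and thoracic joints.  Keeps the model seated."""
    cfg = ControllerConfig(sharing=sharing)
    for name in cfg.names():
        if name in ("T1", "T2", "load_threshold"):
            continue
        if ".lumbar." in name or ".thoracic." in name:
            if name.endswith(".KP"):
                cfg[name] = 400.0
            elif name.endswith(".KV"):
                cfg[name] = 8.0
            else:
                cfg[name] = 0.0
        else:
            cfg[name] = 0.0
    cfg["T1"] = 3.0
    cfg["T2"] = 6.0
    return cfg


def standup_seed_config(sharing: str = "per-leg") -> ControllerConfig:
    """Documented initial guess for the sit-to-walk optimization.

    P1 leans the trunk forward (flexion setpoints on the trunk servos, mild
    TA drive to shift pressure toward the forefoot, vestibular hip-extensor
    feedback referenced to a posterior tilt) and P2 extends (knee/hip/ankle
    extensor drive with upright vestibular and trunk references).  The gait
    block keeps its force/length-feedback defaults.  This configuration
    leans but does not stand on its own; it is the warm-startable mean the
    shooting optimizer refines.
    """
    cfg = seated_hold_config(sharing)
    cfg["p1.lumbar.Q0"] = -0.5
    cfg["p1.thoracic.Q0"] = -0.1
    cfg["p1.theta0"] = -0.35
    cfg["p2.lumbar.Q0"] = -0.35
    cfg["p2.theta0"] = -0.2
    for side in ("r", "l"):
        cfg[f"p1.{side}.TA.C0"] = 0.15
        for mus in ("HAM", "GMAX"):
            cfg[f"p1.{side}.{mus}.vest.KP"] = 2.0
            cfg[f"p1.{side}.{mus}.vest.KV"] = 0.3
        cfg[f"p2.{side}.VAS.C0"] = 0.12
        cfg[f"p2.{side}.GMAX.C0"] = 0.10
        cfg[f"p2.{side}.HAM.C0"] = 0.05
        for mus in ("HAM", "GMAX"):
            cfg[f"p2.{side}.{mus}.vest.KP"] = 2.0
            cfg[f"p2.{side}.{mus}.vest.KV"] = 0.3
        # gait reflex defaults (force feedback plantarflexors, TA length
        # feedback, VAS stance force feedback) as in default_config
        dflt = ControllerConfig(sharing=sharing)
        for name in dflt.names():
            if name.startswith("gait."):
                cfg[name] = dflt[name]
    cfg["T1"] = 1.2
    cfg["T2"] = 2.4
    return cfg


def count_free_parameters(config: ControllerConfig) -> int:
    """Number of optimizable scalars exposed by the configuration."""
    return len(config.params)


def default_config(sharing: str = "per-leg") -> ControllerConfig:
    return ControllerConfig(sharing=sharing)
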