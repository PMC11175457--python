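"""Hill-type muscle-tendon dynamics.

A lumped contractile element (CE) with active force-length, force-velocity
and parallel passive elasticity, in series with an elastic tendon (quadratic
toe region).  No pennation (planar, fused muscle groups).

All quantities are normalized: CE length ``L = l_ce / l_opt``, CE velocity
``V`` in l_opt/s (positive = lengthening), forces by ``f_max``.  The curve
family is a conventional smooth Hill set pinned to the usual anchor points
(fl(1)=1, fv(0)=1, fv(-v_max)=0, fv bounded at FV_N for lengthening,
fp(L<=1)~0, ft(strain<=0)=0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import MTUParams  # noqa: F401  (canonical definition lives there)

# curve shape constants (fixture values, see README)
FL_WIDTH = 0.45          # gaussian width of the active force-length curve
FV_GAMMA = 0.25          # shortening curvature (a/F0 analogue)
FV_N = 1.5               # eccentric force plateau
FP_WIDTH = 0.56          # passive curve: fp(1 + FP_WIDTH) = 1
TENDON_STRAIN_REF = 0.04  # tendon strain at f_max
TAU_ACT = 0.010          # s
TAU_DEACT = 0.040        # s

#: eccentric slope continuity constant: fv'(0+) = fv'(0-) fixes FV_C.
_FV_SHORT_SLOPE = 1.0 + 1.0 / FV_GAMMA
_FV_C = (FV_N - 1.0) / _FV_SHORT_SLOPE


@dataclass(frozen=True)
class MuscleState:
    """State of one MTU: activation, normalized CE length/velocity/force."""
    a: float = 0.0
    L: float = 1.0
    V: float = 0.0
    F: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0):
            raise ValueError(f"activation {self.a} outside [0, 1]")
        if self.L <= 0:
            raise ValueError(f"normalized CE length {self.L} must be > 0")


def activation_rate(u: float, a: float,
                    tau_act: float = TAU_ACT, tau_deact: float = TAU_DEACT) -> float:
    """First-order activation dynamics da/dt = (u - a)/tau [1/s]."""
    tau = tau_act if u >= a else tau_deact
    return (u - a) / tau


def active_force_length(L):
    return np.exp(-((np.asarray(L, dtype=float) - 1.0) / FL_WIDTH) ** 2)


def force_velocity(V):
    """Hill force-velocity multiplier; V in l_opt/s, positive lengthening."""
    V = np.asarray(V, dtype=float)
    vmax = 1.0  # expressed per v_max; callers pass V/v_max
    short = (1.0 + V / vmax) / (1.0 - V / (FV_GAMMA * vmax))
    long_ = FV_N - (FV_N - 1.0) * _FV_C / (V + _FV_C)
    out = np.where(V < 0.0, short, long_)
    return np.maximum(out, 0.0)


def force_velocity_inverse(fv):
    """Normalized CE velocity (per v_max) giving the multiplier ``fv``."""
    fv = np.asarray(fv, dtype=float)
    fv = np.clip(fv, 0.0, FV_N - 1e-6)
    short = (fv - 1.0) / (1.0 + fv / FV_GAMMA)
    long_ = _FV_C * (FV_N - 1.0) / (FV_N - fv) - _FV_C
    return np.where(fv < 1.0, short, long_)


def passive_force(L):
    L = np.asarray(L, dtype=float)
    x = np.maximum(L - 1.0, 0.0) / FP_WIDTH
    return x * x


def tendon_force(strain):
    """Normalized tendon force from strain (quadratic toe, slack below 0)."""
    strain = np.asarray(strain, dtype=float)
    x = np.maximum(strain, 0.0) / TENDON_STRAIN_REF
    return x * x


def rigid_tendon_force(params, a: float, l_mt: float, v_mt: float) -> MuscleState:
    """Closed-form MTU force with an inextensible tendon (analytic oracle)."""
    L = (l_mt - params.l_slack) / params.l_opt
    V = v_mt / params.l_opt
    if L <= 0:
        return MuscleState(a=a, L=max(L, 1e-6), V=V, F=0.0)
    F = a * float(active_force_length(L)) * float(force_velocity(V / params.v_max)) \
        + float(passive_force(L))
    return MuscleState(a=a, L=L, V=V, F=max(F, 0.0))


def mtu_step(params, state: MuscleState, l_mt: float, dt: float,
             u: float | None = None, rigid_tendon: bool = False,
             v_mt: float = 0.0) -> MuscleState:
    """Advance one MTU by ``dt`` under total path length ``l_mt``.

    CE-tendon force equilibrium is enforced by inverting the force-velocity
    curve for the CE velocity that balances the tendon force, then advancing
    the CE length explicitly.  With ``rigid_tendon`` the closed-form
    evaluation is used and ``L`` follows the path directly.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a = state.a
    if u is not None:
        a = min(max(a + dt * activation_rate(u, a), 0.0), 1.0)

    if rigid_tendon:
        return rigid_tendon_force(params, a, l_mt, v_mt)

    L = state.L
    l_t = l_mt - L * params.l_opt
    strain = (l_t - params.l_slack) / params.l_slack
    f_t = float(tendon_force(strain))
    fl = float(active_force_length(L))
    fp = float(passive_force(L))
    denom = max(a * fl, 1e-3)
    fv_needed = (f_t - fp) / denom
    Vn = float(force_velocity_inverse(fv_needed))  # per v_max
    Vn = min(Vn, 2.0)  # eccentric inverse is ill-conditioned near its asymptote
    V = Vn * params.v_max
    L_new = L + dt * V
    if not (1e-3 < L_new < 10.0) or not math.isfinite(L_new):
        raise RuntimeError(
            f"MTU equilibrium failed for {params.name}: L={L_new}, l_mt={l_mt}")
    return MuscleState(a=a, L=L_new, V=V, F=max(f_t, 0.0))


def init_state(params, l_mt: float, a: float = 0.0) -> MuscleState:
    """Initial fiber state with an unstrained tendon (force ~ 0)."""
    L = (l_mt - params.l_slack) / params.l_opt
    L = min(max(L, 0.3), 1.8)
    return MuscleState(a=a, L=L, V=0.0, F=0.0)
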