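"""Hunt-Crossley compliant contact and regularized friction.

Normal force: ``F = k * x^{3/2} * (1 + 1.5*c*xdot)`` clamped at zero (no
adhesion), with ``x`` the penetration depth and ``xdot`` the penetration
rate.  Friction is a velocity-regularized Stribeck law that passes through
the origin, saturates at ``mu_d * N`` when sliding and never exceeds
``mu_s * N``.
"""

from __future__ import annotations

import math

import numpy as np

SLIP_VELOCITY_TOL = 0.01  # m/s, velocity scale of the friction regularization


def normal_force(x: float, xdot: float, k: float, c: float) -> float:
    """Hunt-Crossley normal force [N]; zero out of contact, clamped >= 0."""
    if x <= 0.0:
        return 0.0
    f = k * x ** 1.5 * (1.0 + 1.5 * c * xdot)
    return max(f, 0.0)


def friction_coefficient(v_t: float, mu_s: float, mu_d: float,
                         v_tol: float = SLIP_VELOCITY_TOL) -> float:
    """Signed friction coefficient opposing slip; |mu| <= mu_s always."""
    s = v_t / v_tol
    return (mu_d + (mu_s - mu_d) * math.exp(-abs(s))) * math.tanh(s)


def friction_force(n: float, v_t: float, mu_s: float, mu_d: float,
                   v_tol: float = SLIP_VELOCITY_TOL) -> float:
    """Tangential friction force [N] opposing the slip velocity ``v_t``."""
    if n < 0:
        raise ValueError("normal force must be >= 0")
    return -n * friction_coefficient(v_t, mu_s, mu_d, v_tol)


def sphere_plane_contact(center_y: float, radius: float):
    """Penetration of a sphere into the ground plane y=0 (normal +y)."""
    return radius - center_y


def sphere_box_contact(center, radius: float, box_center, half_extents):
    """Closest-point contact between a sphere and a fixed box (2-D rectangle).

    Returns ``(penetration, contact_point, normal)`` with the normal pointing
    from the box into the sphere (unit length).  Handles face and corner
    cases; when the sphere centre is inside the box the normal is along the
    axis of minimum exit distance.
    """
    center = np.asarray(center, dtype=float)
    bc = np.asarray(box_center, dtype=float)
    he = np.asarray(half_extents, dtype=float)
    d = center - bc
    clamped = np.clip(d, -he, he)
    if np.all(np.abs(d) < he):           # centre inside the box
        exit_dist = he - np.abs(d)
        ax = int(np.argmin(exit_dist))
        normal = np.zeros(2)
        normal[ax] = math.copysign(1.0, d[ax])
        closest = center.copy()
        closest[ax] = bc[ax] + normal[ax] * he[ax]
        pen = radius + float(exit_dist[ax])
        return pen, closest, normal
    closest = bc + clamped
    gap = center - closest
    dist = float(np.hypot(gap[0], gap[1]))
    if dist < 1e-12:
        normal = np.array([0.0, 1.0])
    else:
        normal = gap / dist
    return radius - dist, closest, normal
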