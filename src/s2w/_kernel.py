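"""Numba-compiled fixed-step rollout kernel.

The public API lives in :mod:`s2w.engine`; this module holds the flat-array
hot loop: forward kinematics of the planar tree, Jacobian-assembled mass
matrix and bias forces, via-point muscle geometry, Hill MTU dynamics with an
elastic tendon, Hunt-Crossley contact, delayed reflex pathways and the gait
state machine.

Everything is float64 and explicit loops; semi-implicit Euler integration.
Body layout: two massless prismatic phantoms (ground x, y) then the pelvis
revolute, matching the 3-DOF planar-free root.
"""

import os

import numpy as np

try:
    if os.environ.get("S2W_NO_JIT"):
        raise ImportError
    from numba import njit
except ImportError:                                    # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

_JIT = dict(cache=True, fastmath=False)

# trajectory column layout (see engine.TRAJ_COLUMNS)
NQ = 11
NM = 20
COL_T = 0
COL_Q = 1
COL_QD = 12
COL_A = 23
COL_U = 43
COL_FM = 63
COL_L = 83
COL_V = 103
COL_GRF_R = 123
COL_GRF_L = 125
COL_SEAT = 127
COL_PELVIS = 129
COL_HEAD = 131
COL_TAU = 133
COL_PHASE = 135
COL_STATE_R = 136
COL_STATE_L = 137
COL_HEEL_R = 138
COL_HEEL_L = 139
COL_COM = 140
COL_FEXT = 142
COL_MACOM = 144
NCOLS = 146

# muscle curve constants (mirrors s2w.muscle)
FL_WIDTH = 0.45
FV_GAMMA = 0.25
FV_N = 1.5
FP_WIDTH = 0.56
EPS_T = 0.04
_FV_C = (FV_N - 1.0) / (1.0 + 1.0 / FV_GAMMA)

LIMIT_RAMP = 0.01
SLIP_TOL = 0.01
TRUNK_TORQUE_LIMIT = 1000.0
DWELL = 0.020           # gait state machine hysteresis [s]
SWING_LOAD = 0.01       # load fraction below which Lift-off becomes Swing

# pathway type codes
PW_C = 0
PW_L = 1
PW_F = 2
PW_V = 3
PW_VESTP = 4
PW_VESTD = 5
PW_KA = 6
PW_TRUNKP = 7
PW_TRUNKD = 8

# channel layout in the delay ring buffer
CH_L = 0
CH_F = NM
CH_V = 2 * NM
CH_THETA = 3 * NM
CH_THETAD = 3 * NM + 1
CH_LUM = 3 * NM + 2      # q, qd
CH_THOR = 3 * NM + 4
CH_KNEE_R = 3 * NM + 6
CH_KNEE_L = 3 * NM + 7
NCH = 3 * NM + 8

ST_STANCE = 0
ST_LIFTOFF = 1
ST_SWING = 2


@njit(**_JIT)
def _fk(parent, jtype, jsign, jpos, jcoord, q, qd,
        th, org, om, vorg):
    nb = parent.shape[0]
    for b in range(nb):
        p = parent[b]
        if p < 0:
            th[b] = 0.0
            org[b, 0] = 0.0
            org[b, 1] = 0.0
            om[b] = 0.0
            vorg[b, 0] = 0.0
            vorg[b, 1] = 0.0
        else:
            c = np.cos(th[p])
            s = np.sin(th[p])
            rx = c * jpos[b, 0] - s * jpos[b, 1]
            ry = s * jpos[b, 0] + c * jpos[b, 1]
            org[b, 0] = org[p, 0] + rx
            org[b, 1] = org[p, 1] + ry
            vorg[b, 0] = vorg[p, 0] - om[p] * ry
            vorg[b, 1] = vorg[p, 1] + om[p] * rx
            th[b] = th[p]
            om[b] = om[p]
        ci = jcoord[b]
        if jtype[b] == 0:      # prismatic x (ground frame; phantoms unrotated)
            org[b, 0] += q[ci]
            vorg[b, 0] += qd[ci]
        elif jtype[b] == 1:    # prismatic y
            org[b, 1] += q[ci]
            vorg[b, 1] += qd[ci]
        else:                  # revolute
            th[b] += jsign[b] * q[ci]
            om[b] += jsign[b] * qd[ci]


@njit(**_JIT)
def _body_point(th, org, b, lx, ly, out):
    c = np.cos(th[b])
    s = np.sin(th[b])
    out[0] = org[b, 0] + c * lx - s * ly
    out[1] = org[b, 1] + s * lx + c * ly


@njit(**_JIT)
def _point_velocity(th, org, om, vorg, b, px, py, out):
    out[0] = vorg[b, 0] - om[b] * (py - org[b, 1])
    out[1] = vorg[b, 1] + om[b] * (px - org[b, 0])


@njit(**_JIT)
def _fv_inv(fv):
    # CE velocity (per v_max) bounded to [-1, 2]: beyond ~2*v_max lengthening
    # the curve is flat and the inverse ill-conditioned.
    if fv < 0.0:
        fv = 0.0
    if fv > FV_N - 1e-6:
        fv = FV_N - 1e-6
    if fv < 1.0:
        return (fv - 1.0) / (1.0 + fv / FV_GAMMA)
    v = _FV_C * (FV_N - 1.0) / (FV_N - fv) - _FV_C
    return v if v < 2.0 else 2.0


@njit(**_JIT)
def _fl(L):
    d = (L - 1.0) / FL_WIDTH
    return np.exp(-d * d)


@njit(**_JIT)
def _fp(L):
    if L <= 1.0:
        return 0.0
    x = (L - 1.0) / FP_WIDTH
    return x * x


@njit(**_JIT)
def _ft(strain):
    if strain <= 0.0:
        return 0.0
    x = strain / EPS_T
    return x * x


@njit(**_JIT)
def _friction_mu(vt, mus, mud):
    s = vt / SLIP_TOL
    return (mud + (mus - mud) * np.exp(-abs(s))) * np.tanh(s)


@njit(**_JIT)
def _apply_point_force(b, px, py, fx, fy, desc, rev_coord, rev_sign,
                       centers, axes, Q):
    """Accumulate the generalized force of a world force at a body point."""
    nqc = Q.shape[0]
    for ci in range(nqc):
        if not desc[b, ci]:
            continue
        if rev_coord[ci]:
            rx = px - centers[ci, 0]
            ry = py - centers[ci, 1]
            Q[ci] += rev_sign[ci] * (rx * fy - ry * fx)
        else:
            Q[ci] += axes[ci, 0] * fx + axes[ci, 1] * fy


@njit(**_JIT)
def _chol_solve(A, b, L, y, out):
    """Solve A x = b for SPD A via Cholesky (in-place work arrays)."""
    n = A.shape[0]
    for i in range(n):
        for j in range(i + 1):
            sacc = A[i, j]
            for k in range(j):
                sacc -= L[i, k] * L[j, k]
            if i == j:
                L[i, j] = np.sqrt(sacc if sacc > 1e-12 else 1e-12)
            else:
                L[i, j] = sacc / L[j, j]
    for i in range(n):
        sacc = b[i]
        for k in range(i):
            sacc -= L[i, k] * y[k]
        y[i] = sacc / L[i, i]
    for i in range(n - 1, -1, -1):
        sacc = y[i]
        for k in range(i + 1, n):
            sacc -= L[k, i] * out[k]
        out[i] = sacc / L[i, i]


@njit(**_JIT)
def rollout(
    # tree
    parent, jtype, jsign, jpos, jcoord,
    mass, inertia, com,
    # per-coordinate data
    rev_coord, rev_sign, coord_body, desc,
    qlo, qhi, klim, dlim, pdamp, has_limit, locked,
    # muscles
    fmax, lopt, lslack, vmax, vp_body, vp_loc, vp_off, span,
    tau_act, tau_deact, enable_muscles,
    # contact spheres + chair box
    sph_body, sph_loc, sph_r, sph_k, sph_c, sph_mus, sph_mud, sph_is_butt,
    box_on, box_cx, box_cy, box_hx, box_hy, box_k, box_c, box_mus, box_mud,
    # controller pathways
    pw_target, pw_phase, pw_statemask, pw_type, pw_source, pw_sign,
    pw_delay_steps, pw_gain_idx, pw_ofs_idx, pw_ofs_const, pw_leg,
    x, t1, t2, load_thr,
    # control mode: 0 = pathways, 1 = constant excitation
    u_mode, u_const, tau_const,
    # scenario
    q0, qd0, gravity, enable_contact, dt, t_max, fall_ratio,
    sample_every, head_body, head_loc, torso_top_body,
    # outputs
    out,
):
    """Integrate the full system; returns (status, nsamp, t_end, fell).

    status: 0 ok, 1 non-finite state, 2 muscle failure.
    """
    nb = parent.shape[0]
    nqc = q0.shape[0]
    nm = fmax.shape[0]

    q = q0.copy()
    qd = qd0.copy()

    th = np.zeros(nb)
    org = np.zeros((nb, 2))
    om = np.zeros(nb)
    vorg = np.zeros((nb, 2))

    # muscle state
    act = np.zeros(nm)
    Lce = np.zeros(nm)
    Vce = np.zeros(nm)
    Fn = np.zeros(nm)     # normalized tendon force
    lmt = np.zeros(nm)
    r_arm = np.zeros((nm, nqc))

    _fk(parent, jtype, jsign, jpos, jcoord, q, qd, th, org, om, vorg)
    pt = np.zeros(2)
    for m in range(nm):
        length = 0.0
        px = 0.0
        py = 0.0
        for k in range(vp_off[m], vp_off[m + 1]):
            _body_point(th, org, vp_body[k], vp_loc[k, 0], vp_loc[k, 1], pt)
            if k > vp_off[m]:
                length += np.sqrt((pt[0] - px) ** 2 + (pt[1] - py) ** 2)
            px = pt[0]
            py = pt[1]
        lmt[m] = length
        L = (length - lslack[m]) / lopt[m]
        if L < 0.3:
            L = 0.3
        if L > 1.8:
            L = 1.8
        Lce[m] = L

    # whole-body COM at start
    mtot = 0.0
    com0y = 0.0
    cpt = np.zeros(2)
    for b in range(nb):
        if mass[b] <= 0.0:
            continue
        _body_point(th, org, b, com[b, 0], com[b, 1], cpt)
        mtot += mass[b]
        com0y += mass[b] * cpt[1]
    com0y /= mtot

    # delay ring buffer, prefilled with initial values (hold-at-start rule)
    max_delay = 0
    for p in range(pw_delay_steps.shape[0]):
        if pw_delay_steps[p] > max_delay:
            max_delay = pw_delay_steps[p]
    nring = max_delay + 2
    ring = np.zeros((NCH, nring))
    theta0_ch = q[2]
    for m in range(nm):
        for j in range(nring):
            ring[CH_L + m, j] = Lce[m]
    for j in range(nring):
        ring[CH_THETA, j] = theta0_ch
        ring[CH_LUM, j] = q[3]
        ring[CH_THOR, j] = q[4]
        ring[CH_KNEE_R, j] = q[6]
        ring[CH_KNEE_L, j] = q[9]

    # gait state machine
    leg_state = np.zeros(2, dtype=np.int64)
    leg_state[0] = ST_STANCE
    leg_state[1] = ST_STANCE
    dwell_t = np.zeros(2)
    gait_init = False

    nsteps = int(np.floor(t_max / dt + 0.5))
    dwell_steps = DWELL / dt

    u = np.zeros(nm)
    tau_cmd = np.zeros(2)
    Mmat = np.zeros((nqc, nqc))
    Lchol = np.zeros((nqc, nqc))
    ytmp = np.zeros(nqc)
    qdd = np.zeros(nqc)
    h = np.zeros(nqc)
    rhs = np.zeros(nqc)
    Q = np.zeros(nqc)
    Jb = np.zeros((3, nqc))
    abias = np.zeros((nb, 2))
    centers = np.zeros((nqc, 2))
    axes = np.zeros((nqc, 2))
    vcenters = np.zeros((nqc, 2))
    comw = np.zeros((nb, 2))
    vcomw = np.zeros((nb, 2))
    grf = np.zeros((2, 2))      # per leg fx, fy
    heel_fy = np.zeros(2)
    seat = np.zeros(2)
    fext = np.zeros(2)
    legload = np.zeros(2)
    vpt = np.zeros(2)

    nsamp = 0
    fell = False
    status = 0
    t = 0.0
    step = 0
    bw = mtot * 9.81

    while step <= nsteps:
        # ---------------- kinematics ----------------
        _fk(parent, jtype, jsign, jpos, jcoord, q, qd, th, org, om, vorg)

        for ci in range(nqc):
            b = coord_body[ci]
            if rev_coord[ci]:
                centers[ci, 0] = org[b, 0]
                centers[ci, 1] = org[b, 1]
                vcenters[ci, 0] = vorg[b, 0]
                vcenters[ci, 1] = vorg[b, 1]
            else:
                if jtype[b] == 0:
                    axes[ci, 0] = 1.0
                    axes[ci, 1] = 0.0
                else:
                    axes[ci, 0] = 0.0
                    axes[ci, 1] = 1.0

        for b in range(nb):
            if mass[b] <= 0.0:
                continue
            _body_point(th, org, b, com[b, 0], com[b, 1], cpt)
            comw[b, 0] = cpt[0]
            comw[b, 1] = cpt[1]
            _point_velocity(th, org, om, vorg, b, cpt[0], cpt[1], vpt)
            vcomw[b, 0] = vpt[0]
            vcomw[b, 1] = vpt[1]

        # ---------------- muscle geometry ----------------
        for m in range(nm):
            length = 0.0
            n_pts = vp_off[m + 1] - vp_off[m]
            for ci in range(nqc):
                r_arm[m, ci] = 0.0
            px = 0.0
            py = 0.0
            pb = 0
            for k in range(vp_off[m], vp_off[m + 1]):
                _body_point(th, org, vp_body[k], vp_loc[k, 0], vp_loc[k, 1], pt)
                if k > vp_off[m]:
                    ex = pt[0] - px
                    ey = pt[1] - py
                    seg = np.sqrt(ex * ex + ey * ey)
                    if seg > 1e-12:
                        ex /= seg
                        ey /= seg
                        length += seg
                        for ci in range(nqc):
                            if not span[m, ci] or not rev_coord[ci]:
                                continue
                            dax = 0.0
                            day = 0.0
                            dbx = 0.0
                            dby = 0.0
                            if desc[pb, ci]:
                                dax = -rev_sign[ci] * (py - centers[ci, 1])
                                day = rev_sign[ci] * (px - centers[ci, 0])
                            if desc[vp_body[k], ci]:
                                dbx = -rev_sign[ci] * (pt[1] - centers[ci, 1])
                                dby = rev_sign[ci] * (pt[0] - centers[ci, 0])
                            # r = -dL/dq
                            r_arm[m, ci] -= ex * (dbx - dax) + ey * (dby - day)
                px = pt[0]
                py = pt[1]
                pb = vp_body[k]
            lmt[m] = length

        # ---------------- controller ----------------
        phase = 0
        if t >= t2:
            phase = 2
        elif t >= t1:
            phase = 1

        # leg loads from previous step's contact forces
        legload[0] = grf[0, 1] / bw
        legload[1] = grf[1, 1] / bw

        if phase == 2:
            if not gait_init:
                gait_init = True
                for leg in range(2):
                    if legload[leg] >= load_thr:
                        leg_state[leg] = ST_STANCE
                    else:
                        leg_state[leg] = ST_SWING
                    dwell_t[leg] = dwell_steps
            for leg in range(2):
                if dwell_t[leg] > 0.0:
                    dwell_t[leg] -= 1.0
                    continue
                st = leg_state[leg]
                other = legload[1 - leg]
                new = st
                if st == ST_STANCE:
                    if legload[leg] < load_thr and other >= load_thr:
                        new = ST_LIFTOFF
                elif st == ST_LIFTOFF:
                    if legload[leg] <= SWING_LOAD:
                        new = ST_SWING
                    elif legload[leg] >= load_thr:
                        new = ST_STANCE
                else:
                    if legload[leg] >= load_thr:
                        new = ST_STANCE
                if new != st:
                    leg_state[leg] = new
                    dwell_t[leg] = dwell_steps

        for m in range(nm):
            u[m] = 0.0
        tau_cmd[0] = 0.0
        tau_cmd[1] = 0.0

        if u_mode == 1:
            for m in range(nm):
                u[m] = u_const[m]
            tau_cmd[0] = tau_const[0]
            tau_cmd[1] = tau_const[1]
        else:
            ridx = step % nring
            for p in range(pw_target.shape[0]):
                if pw_phase[p] != phase:
                    continue
                if phase == 2 and pw_leg[p] >= 0:
                    if (pw_statemask[p] >> leg_state[pw_leg[p]]) & 1 == 0:
                        continue
                tp = pw_type[p]
                if tp == PW_C:
                    contrib = x[pw_gain_idx[p]]
                else:
                    didx = (ridx - pw_delay_steps[p]) % nring
                    if tp == PW_L:
                        sig = ring[CH_L + pw_source[p], didx]
                    elif tp == PW_F:
                        sig = ring[CH_F + pw_source[p], didx]
                    elif tp == PW_V:
                        sig = ring[CH_V + pw_source[p], didx]
                    elif tp == PW_VESTP:
                        sig = ring[CH_THETA, didx]
                    elif tp == PW_VESTD:
                        sig = ring[CH_THETAD, didx]
                    elif tp == PW_KA:
                        sig = ring[pw_source[p], didx]
                    elif tp == PW_TRUNKP:
                        sig = ring[pw_source[p], didx]
                    else:
                        sig = ring[pw_source[p], didx]
                    ofs = pw_ofs_const[p]
                    if pw_ofs_idx[p] >= 0:
                        ofs = x[pw_ofs_idx[p]]
                    if tp == PW_KA:
                        # suppression when the knee approaches full extension
                        d = ofs - sig
                        contrib = x[pw_gain_idx[p]] * d if d > 0.0 else 0.0
                    else:
                        contrib = x[pw_gain_idx[p]] * (sig - ofs)
                contrib *= pw_sign[p]
                tgt = pw_target[p]
                if tgt < nm:
                    u[tgt] += contrib
                else:
                    tau_cmd[tgt - nm] += contrib
            for m in range(nm):
                if u[m] < 0.0:
                    u[m] = 0.0
                elif u[m] > 1.0:
                    u[m] = 1.0
        for j in range(2):
            if tau_cmd[j] > TRUNK_TORQUE_LIMIT:
                tau_cmd[j] = TRUNK_TORQUE_LIMIT
            elif tau_cmd[j] < -TRUNK_TORQUE_LIMIT:
                tau_cmd[j] = -TRUNK_TORQUE_LIMIT

        # ---------------- muscle dynamics ----------------
        for m in range(nm if enable_muscles else 0):
            a = act[m]
            tau = tau_act if u[m] >= a else tau_deact
            a += dt * (u[m] - a) / tau
            if a < 0.0:
                a = 0.0
            elif a > 1.0:
                a = 1.0
            act[m] = a

            L = Lce[m]
            lt = lmt[m] - L * lopt[m]
            strain = (lt - lslack[m]) / lslack[m]
            ftn = _ft(strain)
            denom = a * _fl(L)
            if denom < 1e-3:
                denom = 1e-3
            fv_needed = (ftn - _fp(L)) / denom
            Vn = _fv_inv(fv_needed)
            V = Vn * vmax[m]
            L += dt * V
            if not np.isfinite(L):
                status = 2
                break
            # saturate: beyond this range the posture itself is pathological
            # and the rollout will end via the fall rule
            if L < 0.05:
                L = 0.05
            elif L > 2.5:
                L = 2.5
            Lce[m] = L
            Vce[m] = V
            Fn[m] = ftn
        if status != 0:
            break

        # ---------------- forces ----------------
        for ci in range(nqc):
            Q[ci] = 0.0

        # gravity
        for b in range(nb):
            if mass[b] <= 0.0:
                continue
            _apply_point_force(b, comw[b, 0], comw[b, 1], 0.0,
                               -mass[b] * gravity, desc, rev_coord, rev_sign,
                               centers, axes, Q)

        # muscles
        for m in range(nm if enable_muscles else 0):
            fm = Fn[m] * fmax[m]
            if fm <= 0.0:
                continue
            for ci in range(nqc):
                if span[m, ci]:
                    Q[ci] += fm * r_arm[m, ci]

        # joint limits
        for ci in range(nqc):
            if not has_limit[ci]:
                continue
            qi = q[ci]
            if qi > qhi[ci]:
                ex = qi - qhi[ci]
            elif qi < qlo[ci]:
                ex = qi - qlo[ci]
            else:
                continue
            ramp = abs(ex) / LIMIT_RAMP
            if ramp > 1.0:
                ramp = 1.0
            Q[ci] += -klim[ci] * ex - dlim[ci] * qd[ci] * ramp

        # passive viscous joint damping
        for ci in range(nqc):
            if pdamp[ci] > 0.0:
                Q[ci] -= pdamp[ci] * qd[ci]

        # trunk torques (coordinates 3 = lumbar, 4 = thoracic)
        Q[3] += tau_cmd[0]
        Q[4] += tau_cmd[1]

        # contact
        grf[0, 0] = 0.0
        grf[0, 1] = 0.0
        grf[1, 0] = 0.0
        grf[1, 1] = 0.0
        heel_fy[0] = 0.0
        heel_fy[1] = 0.0
        seat[0] = 0.0
        seat[1] = 0.0
        if enable_contact:
            for si in range(sph_body.shape[0]):
                b = sph_body[si]
                _body_point(th, org, b, sph_loc[si, 0], sph_loc[si, 1], cpt)
                if sph_is_butt[si]:
                    if box_on:
                        # sphere vs chair box (closest point on rectangle)
                        dx = cpt[0] - box_cx
                        dy = cpt[1] - box_cy
                        cxl = dx
                        if cxl > box_hx:
                            cxl = box_hx
                        elif cxl < -box_hx:
                            cxl = -box_hx
                        cyl = dy
                        if cyl > box_hy:
                            cyl = box_hy
                        elif cyl < -box_hy:
                            cyl = -box_hy
                        gx = dx - cxl
                        gy = dy - cyl
                        dist = np.sqrt(gx * gx + gy * gy)
                        if dist < 1e-12:
                            nx = 0.0
                            ny = 1.0
                            pen = sph_r[si]
                        else:
                            nx = gx / dist
                            ny = gy / dist
                            pen = sph_r[si] - dist
                        if pen > 0.0:
                            pxc = box_cx + cxl
                            pyc = box_cy + cyl
                            _point_velocity(th, org, om, vorg, b,
                                            cpt[0], cpt[1], vpt)
                            pen_rate = -(vpt[0] * nx + vpt[1] * ny)
                            fn = box_k * pen ** 1.5 * (1.0 + 1.5 * box_c * pen_rate)
                            if fn < 0.0:
                                fn = 0.0
                            vt = -vpt[0] * ny + vpt[1] * nx  # tangential
                            mu = _friction_mu(vt, box_mus, box_mud)
                            ftx = -mu * fn * (-ny)
                            fty = -mu * fn * nx
                            fx = fn * nx + ftx
                            fy = fn * ny + fty
                            _apply_point_force(b, pxc, pyc, fx, fy, desc,
                                               rev_coord, rev_sign, centers,
                                               axes, Q)
                            seat[0] += fx
                            seat[1] += fy
                    # buttock sphere may also hit the ground (falls)
                    pen = sph_r[si] - cpt[1]
                    if pen > 0.0:
                        _point_velocity(th, org, om, vorg, b, cpt[0], 0.0, vpt)
                        fn = sph_k[si] * pen ** 1.5 * (1.0 - 1.5 * sph_c[si] * vpt[1])
                        if fn < 0.0:
                            fn = 0.0
                        mu = _friction_mu(vpt[0], sph_mus[si], sph_mud[si])
                        _apply_point_force(b, cpt[0], 0.0, -mu * fn, fn, desc,
                                           rev_coord, rev_sign, centers, axes, Q)
                else:
                    pen = sph_r[si] - cpt[1]
                    if pen > 0.0:
                        _point_velocity(th, org, om, vorg, b, cpt[0], 0.0, vpt)
                        fn = sph_k[si] * pen ** 1.5 * (1.0 - 1.5 * sph_c[si] * vpt[1])
                        if fn < 0.0:
                            fn = 0.0
                        mu = _friction_mu(vpt[0], sph_mus[si], sph_mud[si])
                        fx = -mu * fn
                        _apply_point_force(b, cpt[0], 0.0, fx, fn, desc,
                                           rev_coord, rev_sign, centers, axes, Q)
                        leg = 0 if si < 2 else 1
                        grf[leg, 0] += fx
                        grf[leg, 1] += fn
                        if si == 0 or si == 2:
                            heel_fy[leg] += fn

        # ---------------- dynamics ----------------
        for i in range(nqc):
            h[i] = 0.0
            for j in range(nqc):
                Mmat[i, j] = 0.0
        for b in range(nb):
            if mass[b] <= 0.0:
                continue
            for ci in range(nqc):
                Jb[0, ci] = 0.0
                Jb[1, ci] = 0.0
                Jb[2, ci] = 0.0
            abx = 0.0
            aby = 0.0
            for ci in range(nqc):
                if not desc[b, ci]:
                    continue
                if rev_coord[ci]:
                    sgn = rev_sign[ci]
                    rx = comw[b, 0] - centers[ci, 0]
                    ry = comw[b, 1] - centers[ci, 1]
                    Jb[0, ci] = sgn
                    Jb[1, ci] = -sgn * ry
                    Jb[2, ci] = sgn * rx
                    vrx = vcomw[b, 0] - vcenters[ci, 0]
                    vry = vcomw[b, 1] - vcenters[ci, 1]
                    abx += -sgn * vry * qd[ci]
                    aby += sgn * vrx * qd[ci]
                else:
                    Jb[1, ci] = axes[ci, 0]
                    Jb[2, ci] = axes[ci, 1]
            abias[b, 0] = abx
            abias[b, 1] = aby
            mi = mass[b]
            Ii = inertia[b]
            for ci in range(nqc):
                j0 = Jb[0, ci]
                j1 = Jb[1, ci]
                j2 = Jb[2, ci]
                if j0 == 0.0 and j1 == 0.0 and j2 == 0.0:
                    continue
                for cj in range(ci, nqc):
                    v = Ii * j0 * Jb[0, cj] + mi * (j1 * Jb[1, cj] + j2 * Jb[2, cj])
                    Mmat[ci, cj] += v
                h[ci] += mi * (j1 * abx + j2 * aby)
        for i in range(nqc):
            for j in range(i):
                Mmat[i, j] = Mmat[j, i]

        for ci in range(nqc):
            rhs[ci] = Q[ci] - h[ci]
        for ci in range(nqc):
            if locked[ci]:
                for j in range(nqc):
                    Mmat[ci, j] = 0.0
                    Mmat[j, ci] = 0.0
                Mmat[ci, ci] = 1.0
                rhs[ci] = 0.0
        _chol_solve(Mmat, rhs, Lchol, ytmp, qdd)

        # ---------------- bookkeeping / output ----------------
        if step % sample_every == 0:
            row = out[nsamp]
            row[COL_T] = t
            for ci in range(nqc):
                row[COL_Q + ci] = q[ci]
                row[COL_QD + ci] = qd[ci]
            for m in range(nm):
                row[COL_A + m] = act[m]
                row[COL_U + m] = u[m]
                row[COL_FM + m] = Fn[m] * fmax[m]
                row[COL_L + m] = Lce[m]
                row[COL_V + m] = Vce[m]
            row[COL_GRF_R] = grf[0, 0]
            row[COL_GRF_R + 1] = grf[0, 1]
            row[COL_GRF_L] = grf[1, 0]
            row[COL_GRF_L + 1] = grf[1, 1]
            row[COL_SEAT] = seat[0]
            row[COL_SEAT + 1] = seat[1]
            _body_point(th, org, 2, com[2, 0], com[2, 1], cpt)
            row[COL_PELVIS] = cpt[0]
            row[COL_PELVIS + 1] = cpt[1]
            _body_point(th, org, head_body, head_loc[0], head_loc[1], cpt)
            row[COL_HEAD] = cpt[0]
            row[COL_HEAD + 1] = cpt[1]
            row[COL_TAU] = tau_cmd[0]
            row[COL_TAU + 1] = tau_cmd[1]
            row[COL_PHASE] = phase
            row[COL_STATE_R] = leg_state[0]
            row[COL_STATE_L] = leg_state[1]
            row[COL_HEEL_R] = heel_fy[0]
            row[COL_HEEL_L] = heel_fy[1]
            comx = 0.0
            comy = 0.0
            maccx = 0.0
            maccy = 0.0
            for b in range(nb):
                if mass[b] <= 0.0:
                    continue
                comx += mass[b] * comw[b, 0]
                comy += mass[b] * comw[b, 1]
                ax = abias[b, 0]
                ay = abias[b, 1]
                for ci in range(nqc):
                    if not desc[b, ci]:
                        continue
                    if rev_coord[ci]:
                        sgn = rev_sign[ci]
                        ax += -sgn * (comw[b, 1] - centers[ci, 1]) * qdd[ci]
                        ay += sgn * (comw[b, 0] - centers[ci, 0]) * qdd[ci]
                    else:
                        ax += axes[ci, 0] * qdd[ci]
                        ay += axes[ci, 1] * qdd[ci]
                maccx += mass[b] * ax
                maccy += mass[b] * ay
            row[COL_COM] = comx / mtot
            row[COL_COM + 1] = comy / mtot
            fext[0] = grf[0, 0] + grf[1, 0] + seat[0]
            fext[1] = grf[0, 1] + grf[1, 1] + seat[1] - mtot * gravity
            row[COL_FEXT] = fext[0]
            row[COL_FEXT + 1] = fext[1]
            row[COL_MACOM] = maccx
            row[COL_MACOM + 1] = maccy
            nsamp += 1

        if step == nsteps:
            break

        # integrate (semi-implicit Euler)
        ok = True
        for ci in range(nqc):
            qd[ci] += dt * qdd[ci]
            q[ci] += dt * qd[ci]
            if not np.isfinite(q[ci]):
                ok = False
        if not ok:
            status = 1
            break
        t += dt
        step += 1

        # write delay channels for the *new* state
        ridx = step % nring
        for m in range(nm):
            ring[CH_L + m, ridx] = Lce[m]
            ring[CH_F + m, ridx] = Fn[m]
            ring[CH_V + m, ridx] = Vce[m]
        ring[CH_THETA, ridx] = q[2]
        ring[CH_THETAD, ridx] = qd[2]
        ring[CH_LUM, ridx] = q[3]
        ring[CH_LUM + 1, ridx] = qd[3]
        ring[CH_THOR, ridx] = q[4]
        ring[CH_THOR + 1, ridx] = qd[4]
        ring[CH_KNEE_R, ridx] = q[6]
        ring[CH_KNEE_L, ridx] = q[9]

        # fall detection
        comy = 0.0
        # (uses previous FK; one-step lag is immaterial at dt = 2e-4)
        for b in range(nb):
            if mass[b] > 0.0:
                comy += mass[b] * comw[b, 1]
        comy /= mtot
        if comy < fall_ratio * com0y:
            fell = True
            break

    return status, nsamp, t, fell
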