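"""Numba kernels for the serial-chain arm: kinematics, RNEA dynamics, integration.

All kernels operate on plain float64 arrays so they stay backend-agnostic and
compile under numba.  The chain is a fixed-base serial manipulator with 7
revolute joints; per-joint parameters are

``p``     (7,3)   translation from the parent joint origin to this joint origin,
                  expressed in the parent joint frame (base frame for joint 0),
``E``     (7,3,3) fixed mounting rotation applied before the joint rotation,
``axis``  (7,3)   unit rotation axis in the joint's own frame,
``m``     (7,)    mass of the link body rigidly attached to the joint frame
                  (zero for massless intermediate frames),
``com``   (7,3)   centre of mass of that body in the joint frame,
``inert`` (7,3,3) inertia tensor about the body's own COM, joint frame,
``tip``   (3,)    fingertip reference point in the last joint frame.

World-frame Newton-Euler recursion; gravity enters as an external force on
each body (no fictitious base acceleration).
"""

import numpy as np
from numba import njit

DIVERGENCE_SPEED = 1.0e6  # rad/s; beyond this the integrator has blown up


@njit(cache=True)
def _cross(a, b):
    out = np.empty(3)
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]
    return out


@njit(cache=True)
def _axis_angle(axis, q):
    """Rodrigues rotation matrix about a unit axis."""
    c = np.cos(q)
    s = np.sin(q)
    v = 1.0 - c
    x, y, z = axis[0], axis[1], axis[2]
    R = np.empty((3, 3))
    R[0, 0] = c + x * x * v
    R[0, 1] = x * y * v - z * s
    R[0, 2] = x * z * v + y * s
    R[1, 0] = y * x * v + z * s
    R[1, 1] = c + y * y * v
    R[1, 2] = y * z * v - x * s
    R[2, 0] = z * x * v - y * s
    R[2, 1] = z * y * v + x * s
    R[2, 2] = c + z * z * v
    return R


@njit(cache=True)
def frames(q, p, E, axis):
    """World rotation and origin of every joint frame.

    Returns (R, o) with R (7,3,3), o (7,3); also the world joint axes a (7,3).
    """
    n = q.shape[0]
    R = np.empty((n, 3, 3))
    o = np.empty((n, 3))
    a = np.empty((n, 3))
    Rw = np.eye(3)
    ow = np.zeros(3)
    for i in range(n):
        ow = ow + Rw @ p[i]
        Rpre = Rw @ E[i]
        Rw = Rpre @ _axis_angle(axis[i], q[i])
        R[i] = Rw
        o[i] = ow
        a[i] = Rw @ axis[i]  # Rot(u,q) u = u, so post-rotation frame works
    return R, o, a


@njit(cache=True)
def fingertip(q, p, E, axis, tip):
    R, o, a = frames(q, p, E, axis)
    n = q.shape[0]
    return o[n - 1] + R[n - 1] @ tip


@njit(cache=True)
def tip_jacobian(q, p, E, axis, tip):
    """3x7 position Jacobian of the fingertip point."""
    R, o, a = frames(q, p, E, axis)
    n = q.shape[0]
    x = o[n - 1] + R[n - 1] @ tip
    J = np.zeros((3, n))
    for i in range(n):
        Ji = _cross(a[i], x - o[i])
        J[0, i] = Ji[0]
        J[1, i] = Ji[1]
        J[2, i] = Ji[2]
    return J


@njit(cache=True)
def rnea(q, qd, qdd, p, E, axis, m, com, inert, grav, armature, damping):
    """Joint torques realizing qdd at (q, qd) under gravity grav."""
    n = q.shape[0]
    R, o, a = frames(q, p, E, axis)

    omega = np.zeros((n, 3))
    domega = np.zeros((n, 3))
    ao = np.zeros((n, 3))      # linear acceleration of joint origins
    xc = np.zeros((n, 3))      # world COM positions
    ac = np.zeros((n, 3))      # COM accelerations

    w_prev = np.zeros(3)
    dw_prev = np.zeros(3)
    ao_prev = np.zeros(3)
    o_prev = np.zeros(3)
    for i in range(n):
        r = o[i] - o_prev
        ao_i = ao_prev + _cross(dw_prev, r) + _cross(w_prev, _cross(w_prev, r))
        w_i = w_prev + qd[i] * a[i]
        dw_i = dw_prev + qdd[i] * a[i] + qd[i] * _cross(w_prev, a[i])
        rc = R[i] @ com[i]
        xc[i] = o[i] + rc
        ac[i] = ao_i + _cross(dw_i, rc) + _cross(w_i, _cross(w_i, rc))
        omega[i] = w_i
        domega[i] = dw_i
        ao[i] = ao_i
        w_prev = w_i
        dw_prev = dw_i
        ao_prev = ao_i
        o_prev = o[i]

    tau = np.zeros(n)
    f_next = np.zeros(3)
    n_next = np.zeros(3)       # moment about o[i+1]
    o_next = np.zeros(3)
    for i in range(n - 1, -1, -1):
        Iw = R[i] @ inert[i] @ R[i].T
        F = m[i] * (ac[i] - grav)
        N = Iw @ domega[i] + _cross(omega[i], Iw @ omega[i])
        f_i = F + f_next
        n_i = N + _cross(xc[i] - o[i], F)
        if i < n - 1:
            n_i = n_i + n_next + _cross(o_next - o[i], f_next)
        tau[i] = a[i] @ n_i + armature * qdd[i] + damping * qd[i]
        f_next = f_i
        n_next = n_i
        o_next = o[i]
    return tau


@njit(cache=True)
def _fused_forward_dynamics(q, qd, tau, p, E, axis, m, com, inert, grav,
                            armature, damping, free):
    """Joint accelerations via CRBA mass matrix + Newton-Euler bias.

    Hand-rolled 3-vector arithmetic throughout: inside numba, 3x3 matmul
    dispatches to BLAS and its call overhead dominates the whole simulation.
    Algebraically identical to solve(mass_matrix, tau - rnea(qdd=0)).
    """
    n = q.shape[0]
    R = np.empty((n, 3, 3))
    o = np.empty((n, 3))
    a = np.empty((n, 3))
    # --- frames ---
    Rw = np.eye(3)
    ow = np.zeros(3)
    tmp = np.empty((3, 3))
    for i in range(n):
        for r_ in range(3):
            ow[r_] += Rw[r_, 0] * p[i, 0] + Rw[r_, 1] * p[i, 1] + Rw[r_, 2] * p[i, 2]
        # Rw = Rw @ E[i]
        for r_ in range(3):
            for c_ in range(3):
                tmp[r_, c_] = (Rw[r_, 0] * E[i, 0, c_] + Rw[r_, 1] * E[i, 1, c_]
                               + Rw[r_, 2] * E[i, 2, c_])
        Rq = _axis_angle(axis[i], q[i])
        for r_ in range(3):
            for c_ in range(3):
                Rw[r_, c_] = (tmp[r_, 0] * Rq[0, c_] + tmp[r_, 1] * Rq[1, c_]
                              + tmp[r_, 2] * Rq[2, c_])
        for r_ in range(3):
            for c_ in range(3):
                R[i, r_, c_] = Rw[r_, c_]
            o[i, r_] = ow[r_]
            a[i, r_] = (Rw[r_, 0] * axis[i, 0] + Rw[r_, 1] * axis[i, 1]
                        + Rw[r_, 2] * axis[i, 2])
    # --- velocity/acceleration recursion with qdd = 0 ---
    w = np.empty((n, 3))
    dw = np.empty((n, 3))
    xc = np.empty((n, 3))
    ac = np.empty((n, 3))
    Iw = np.empty((n, 3, 3))
    wp = np.zeros(3)
    dwp = np.zeros(3)
    aop = np.zeros(3)
    op = np.zeros(3)
    for i in range(n):
        r0 = o[i, 0] - op[0]
        r1 = o[i, 1] - op[1]
        r2 = o[i, 2] - op[2]
        # ao = aop + dwp x r + wp x (wp x r)
        c0 = dwp[1] * r2 - dwp[2] * r1
        c1 = dwp[2] * r0 - dwp[0] * r2
        c2 = dwp[0] * r1 - dwp[1] * r0
        u0 = wp[1] * r2 - wp[2] * r1
        u1 = wp[2] * r0 - wp[0] * r2
        u2 = wp[0] * r1 - wp[1] * r0
        ao0 = aop[0] + c0 + wp[1] * u2 - wp[2] * u1
        ao1 = aop[1] + c1 + wp[2] * u0 - wp[0] * u2
        ao2 = aop[2] + c2 + wp[0] * u1 - wp[1] * u0
        # w_i, dw_i
        wx = wp[0] + qd[i] * a[i, 0]
        wy = wp[1] + qd[i] * a[i, 1]
        wz = wp[2] + qd[i] * a[i, 2]
        dwx = dwp[0] + qd[i] * (wp[1] * a[i, 2] - wp[2] * a[i, 1])
        dwy = dwp[1] + qd[i] * (wp[2] * a[i, 0] - wp[0] * a[i, 2])
        dwz = dwp[2] + qd[i] * (wp[0] * a[i, 1] - wp[1] * a[i, 0])
        w[i, 0], w[i, 1], w[i, 2] = wx, wy, wz
        dw[i, 0], dw[i, 1], dw[i, 2] = dwx, dwy, dwz
        # rc = R_i com_i
        rc0 = R[i, 0, 0] * com[i, 0] + R[i, 0, 1] * com[i, 1] + R[i, 0, 2] * com[i, 2]
        rc1 = R[i, 1, 0] * com[i, 0] + R[i, 1, 1] * com[i, 1] + R[i, 1, 2] * com[i, 2]
        rc2 = R[i, 2, 0] * com[i, 0] + R[i, 2, 1] * com[i, 1] + R[i, 2, 2] * com[i, 2]
        xc[i, 0] = o[i, 0] + rc0
        xc[i, 1] = o[i, 1] + rc1
        xc[i, 2] = o[i, 2] + rc2
        d0 = dwy * rc2 - dwz * rc1
        d1 = dwz * rc0 - dwx * rc2
        d2 = dwx * rc1 - dwy * rc0
        u0 = wy * rc2 - wz * rc1
        u1 = wz * rc0 - wx * rc2
        u2 = wx * rc1 - wy * rc0
        ac[i, 0] = ao0 + d0 + wy * u2 - wz * u1
        ac[i, 1] = ao1 + d1 + wz * u0 - wx * u2
        ac[i, 2] = ao2 + d2 + wx * u1 - wy * u0
        # Iw = R I R^T
        for r_ in range(3):
            for c_ in range(3):
                tmp[r_, c_] = (R[i, r_, 0] * inert[i, 0, c_]
                               + R[i, r_, 1] * inert[i, 1, c_]
                               + R[i, r_, 2] * inert[i, 2, c_])
        for r_ in range(3):
            for c_ in range(3):
                Iw[i, r_, c_] = (tmp[r_, 0] * R[i, c_, 0] + tmp[r_, 1] * R[i, c_, 1]
                                 + tmp[r_, 2] * R[i, c_, 2])
        wp[0], wp[1], wp[2] = wx, wy, wz
        dwp[0], dwp[1], dwp[2] = dwx, dwy, dwz
        aop[0], aop[1], aop[2] = ao0, ao1, ao2
        op[0], op[1], op[2] = o[i, 0], o[i, 1], o[i, 2]
    # --- backward pass: bias torques ---
    bias = np.empty(n)
    fx = fy = fz = 0.0
    nx = ny = nz = 0.0
    onx = ony = onz = 0.0
    for i in range(n - 1, -1, -1):
        Fx = m[i] * (ac[i, 0] - grav[0])
        Fy = m[i] * (ac[i, 1] - grav[1])
        Fz = m[i] * (ac[i, 2] - grav[2])
        # N = Iw dw + w x (Iw w)
        Ix = Iw[i, 0, 0] * w[i, 0] + Iw[i, 0, 1] * w[i, 1] + Iw[i, 0, 2] * w[i, 2]
        Iy = Iw[i, 1, 0] * w[i, 0] + Iw[i, 1, 1] * w[i, 1] + Iw[i, 1, 2] * w[i, 2]
        Iz = Iw[i, 2, 0] * w[i, 0] + Iw[i, 2, 1] * w[i, 1] + Iw[i, 2, 2] * w[i, 2]
        Nx = (Iw[i, 0, 0] * dw[i, 0] + Iw[i, 0, 1] * dw[i, 1] + Iw[i, 0, 2] * dw[i, 2]
              + w[i, 1] * Iz - w[i, 2] * Iy)
        Ny = (Iw[i, 1, 0] * dw[i, 0] + Iw[i, 1, 1] * dw[i, 1] + Iw[i, 1, 2] * dw[i, 2]
              + w[i, 2] * Ix - w[i, 0] * Iz)
        Nz = (Iw[i, 2, 0] * dw[i, 0] + Iw[i, 2, 1] * dw[i, 1] + Iw[i, 2, 2] * dw[i, 2]
              + w[i, 0] * Iy - w[i, 1] * Ix)
        rx = xc[i, 0] - o[i, 0]
        ry = xc[i, 1] - o[i, 1]
        rz = xc[i, 2] - o[i, 2]
        nix = Nx + ry * Fz - rz * Fy
        niy = Ny + rz * Fx - rx * Fz
        niz = Nz + rx * Fy - ry * Fx
        if i < n - 1:
            dx = onx - o[i, 0]
            dy = ony - o[i, 1]
            dz = onz - o[i, 2]
            nix += nx + dy * fz - dz * fy
            niy += ny + dz * fx - dx * fz
            niz += nz + dx * fy - dy * fx
        bias[i] = (a[i, 0] * nix + a[i, 1] * niy + a[i, 2] * niz
                   + damping * qd[i])
        fx += Fx
        fy += Fy
        fz += Fz
        nx, ny, nz = nix, niy, niz
        onx, ony, onz = o[i, 0], o[i, 1], o[i, 2]
    # --- CRBA: composite inertias from the tip ---
    M = np.zeros((n, n))
    mc = 0.0
    ccx = ccy = ccz = 0.0
    Ic = np.zeros((3, 3))
    for i in range(n - 1, -1, -1):
        mt = mc + m[i]
        if mt > 0.0:
            nccx = (mc * ccx + m[i] * xc[i, 0]) / mt
            nccy = (mc * ccy + m[i] * xc[i, 1]) / mt
            nccz = (mc * ccz + m[i] * xc[i, 2]) / mt
        else:
            nccx, nccy, nccz = xc[i, 0], xc[i, 1], xc[i, 2]
        # shift old composite inertia and this body's inertia to the new com
        for r_ in range(3):
            for c_ in range(3):
                tmp[r_, c_] = Ic[r_, c_]
        dx = ccx - nccx
        dy = ccy - nccy
        dz = ccz - nccz
        d2 = dx * dx + dy * dy + dz * dz
        tmp[0, 0] += mc * (d2 - dx * dx)
        tmp[0, 1] += mc * (-dx * dy)
        tmp[0, 2] += mc * (-dx * dz)
        tmp[1, 0] += mc * (-dy * dx)
        tmp[1, 1] += mc * (d2 - dy * dy)
        tmp[1, 2] += mc * (-dy * dz)
        tmp[2, 0] += mc * (-dz * dx)
        tmp[2, 1] += mc * (-dz * dy)
        tmp[2, 2] += mc * (d2 - dz * dz)
        dx = xc[i, 0] - nccx
        dy = xc[i, 1] - nccy
        dz = xc[i, 2] - nccz
        d2 = dx * dx + dy * dy + dz * dz
        for r_ in range(3):
            for c_ in range(3):
                Ic[r_, c_] = tmp[r_, c_] + Iw[i, r_, c_]
        Ic[0, 0] += m[i] * (d2 - dx * dx)
        Ic[0, 1] += m[i] * (-dx * dy)
        Ic[0, 2] += m[i] * (-dx * dz)
        Ic[1, 0] += m[i] * (-dy * dx)
        Ic[1, 1] += m[i] * (d2 - dy * dy)
        Ic[1, 2] += m[i] * (-dy * dz)
        Ic[2, 0] += m[i] * (-dz * dx)
        Ic[2, 1] += m[i] * (-dz * dy)
        Ic[2, 2] += m[i] * (d2 - dz * dz)
        mc = mt
        ccx, ccy, ccz = nccx, nccy, nccz
        # unit acceleration about joint i: alpha = a_i, com acc = alpha x (cc - o_i)
        rx = ccx - o[i, 0]
        ry = ccy - o[i, 1]
        rz = ccz - o[i, 2]
        Fx = mc * (a[i, 1] * rz - a[i, 2] * ry)
        Fy = mc * (a[i, 2] * rx - a[i, 0] * rz)
        Fz = mc * (a[i, 0] * ry - a[i, 1] * rx)
        Nx = Ic[0, 0] * a[i, 0] + Ic[0, 1] * a[i, 1] + Ic[0, 2] * a[i, 2]
        Ny = Ic[1, 0] * a[i, 0] + Ic[1, 1] * a[i, 1] + Ic[1, 2] * a[i, 2]
        Nz = Ic[2, 0] * a[i, 0] + Ic[2, 1] * a[i, 1] + Ic[2, 2] * a[i, 2]
        for j in range(i + 1):
            dx = ccx - o[j, 0]
            dy = ccy - o[j, 1]
            dz = ccz - o[j, 2]
            mij = (a[j, 0] * (Nx + dy * Fz - dz * Fy)
                   + a[j, 1] * (Ny + dz * Fx - dx * Fz)
                   + a[j, 2] * (Nz + dx * Fy - dy * Fx))
            M[j, i] = mij
            M[i, j] = mij
        M[i, i] += armature
    # --- reduced SPD solve (Cholesky) over free joints ---
    nf = 0
    for i in range(n):
        if free[i]:
            nf += 1
    idx = np.empty(nf, dtype=np.int64)
    k = 0
    for i in range(n):
        if free[i]:
            idx[k] = i
            k += 1
    A = np.empty((nf, nf))
    b = np.empty(nf)
    for ii in range(nf):
        b[ii] = tau[idx[ii]] - bias[idx[ii]]
        for jj in range(nf):
            A[ii, jj] = M[idx[ii], idx[jj]]
    # in-place Cholesky
    for ii in range(nf):
        s = A[ii, ii]
        for kk in range(ii):
            s -= A[ii, kk] * A[ii, kk]
        if s <= 0.0:
            s = 1e-12
        A[ii, ii] = np.sqrt(s)
        for jj in range(ii + 1, nf):
            s = A[jj, ii]
            for kk in range(ii):
                s -= A[jj, kk] * A[ii, kk]
            A[jj, ii] = s / A[ii, ii]
    for ii in range(nf):
        s = b[ii]
        for kk in range(ii):
            s -= A[ii, kk] * b[kk]
        b[ii] = s / A[ii, ii]
    for ii in range(nf - 1, -1, -1):
        s = b[ii]
        for kk in range(ii + 1, nf):
            s -= A[kk, ii] * b[kk]
        b[ii] = s / A[ii, ii]
    qdd = np.zeros(n)
    for ii in range(nf):
        qdd[idx[ii]] = b[ii]
    return qdd


@njit(cache=True)
def mass_matrix(q, p, E, axis, m, com, inert, armature):
    n = q.shape[0]
    M = np.empty((n, n))
    zero3 = np.zeros(3)
    zd = np.zeros(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        M[:, i] = rnea(q, zd, e, p, E, axis, m, com, inert, zero3,
                       armature, 0.0)
    return 0.5 * (M + M.T)


@njit(cache=True)
def forward_dynamics(q, qd, tau, p, E, axis, m, com, inert, grav, armature,
                     damping, free):
    """Joint accelerations; joints with free[i]==0 are locked (qdd=0)."""
    n = q.shape[0]
    bias = rnea(q, qd, np.zeros(n), p, E, axis, m, com, inert, grav,
                armature, damping)
    M = mass_matrix(q, p, E, axis, m, com, inert, armature)
    nf = 0
    for i in range(n):
        if free[i]:
            nf += 1
    if nf == n:
        return np.linalg.solve(M, tau - bias)
    idx = np.empty(nf, dtype=np.int64)
    k = 0
    for i in range(n):
        if free[i]:
            idx[k] = i
            k += 1
    Mf = np.empty((nf, nf))
    rf = np.empty(nf)
    for ii in range(nf):
        rf[ii] = tau[idx[ii]] - bias[idx[ii]]
        for jj in range(nf):
            Mf[ii, jj] = M[idx[ii], idx[jj]]
    sol = np.linalg.solve(Mf, rf)
    qdd = np.zeros(n)
    for ii in range(nf):
        qdd[idx[ii]] = sol[ii]
    return qdd


@njit(cache=True)
def control_step(q, qd, tau, p, E, axis, m, com, inert, grav, armature,
                 damping, lower, upper, tau_lim, h, n_sub, free):
    """Advance one control interval (n_sub semi-implicit Euler substeps).

    Returns (q, qd, ok); ok=False on integrator divergence.  Torques are
    clamped to +-tau_lim; joint limits are enforced by clamping the angle and
    zeroing the limit-directed velocity component.
    """
    n = q.shape[0]
    qc = q.copy()
    vc = qd.copy()
    tc = np.empty(n)
    for i in range(n):
        t = tau[i]
        if t > tau_lim:
            t = tau_lim
        elif t < -tau_lim:
            t = -tau_lim
        tc[i] = t
    for s in range(n_sub):
        qdd = _fused_forward_dynamics(qc, vc, tc, p, E, axis, m, com, inert,
                                      grav, armature, damping, free)
        for i in range(n):
            vc[i] += qdd[i] * h
            qc[i] += vc[i] * h
            if qc[i] < lower[i]:
                qc[i] = lower[i]
                if vc[i] < 0.0:
                    vc[i] = 0.0
            elif qc[i] > upper[i]:
                qc[i] = upper[i]
                if vc[i] > 0.0:
                    vc[i] = 0.0
        nv = 0.0
        for i in range(n):
            nv += vc[i] * vc[i]
        if not np.isfinite(nv) or nv > DIVERGENCE_SPEED * DIVERGENCE_SPEED:
            return qc, vc, False
    return qc, vc, True


@njit(cache=True)
def open_loop_episode(q0, torques, p, E, axis, m, com, inert, grav, armature,
                      damping, lower, upper, tau_lim, h, n_sub, tip):
    """Run a full episode applying a (T,7) torque sequence open loop.

    Returns (angles (T,7), velocities (T,7), tippos (T,3), tipvel (T,3),
    n_done).  n_done < T signals divergence at that sample.
    """
    T = torques.shape[0]
    n = q0.shape[0]
    free = np.ones(n, dtype=np.int64)
    q = q0.copy()
    qd = np.zeros(n)
    angles = np.zeros((T, n))
    vels = np.zeros((T, n))
    tippos = np.zeros((T, 3))
    tipvel = np.zeros((T, 3))
    for t in range(T):
        q, qd, ok = control_step(q, qd, torques[t], p, E, axis, m, com, inert,
                                 grav, armature, damping, lower, upper,
                                 tau_lim, h, n_sub, free)
        angles[t] = q
        vels[t] = qd
        tippos[t] = fingertip(q, p, E, axis, tip)
        tipvel[t] = tip_jacobian(q, p, E, axis, tip) @ qd
        if not ok:
            return angles, vels, tippos, tipvel, t + 1
    return angles, vels, tippos, tipvel, T
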