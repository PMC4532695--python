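"""Compiled (numba) numerical core for Lyapunov-spectrum estimation.

Fixed-step classical RK4 integration of the base flow, of the variational
(tangent-matrix) flow used by the discrete Benettin/QR method, and of the
continuous Gram-Schmidt augmented system.  A small integer dispatch selects
the dynamical system, so the same compiled loops serve the Liley model and
every benchmark system.

Parameter-array layouts
-----------------------
liley (SYS_LILEY): length 28, see ``LileyParameters.to_array``.
diagonal (SYS_DIAG): the n decay/growth rates (per ms).
hopf (SYS_HOPF): (mu, omega); Cartesian normal form.
lorenz (SYS_LORENZ): (sigma, rho, beta).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SYS_LILEY = 0
SYS_DIAG = 1
SYS_HOPF = 2
SYS_LORENZ = 3

_SQRT2 = math.sqrt(2.0)
_E = math.e


def system_dim(sys_id: int, p: np.ndarray) -> int:
    if sys_id == SYS_LILEY:
        return 10
    if sys_id == SYS_DIAG:
        return len(p)
    if sys_id == SYS_HOPF:
        return 2
    if sys_id == SYS_LORENZ:
        return 3
    raise ValueError(f"unknown system id {sys_id}")


@njit(cache=True)
def _logistic(x):
    return 0.5 * (1.0 + math.tanh(0.5 * x))


@njit(cache=True)
def sys_rhs(sys_id, y, p, out):
    if sys_id == SYS_LILEY:
        h_e = y[0]
        h_i = y[1]
        a_e = _SQRT2 / p[22]
        a_i = _SQRT2 / p[23]
        S_e = p[18] * _logistic(a_e * (h_e - p[20]))
        S_i = p[19] * _logistic(a_i * (h_i - p[21]))
        psi_ee = (p[2] - h_e) / abs(p[2] - p[0])
        psi_ie = (p[3] - h_e) / abs(p[3] - p[0])
        psi_ei = (p[2] - h_i) / abs(p[2] - p[1])
        psi_ii = (p[3] - h_i) / abs(p[3] - p[1])
        out[0] = (p[0] - h_e + psi_ee * y[2] + psi_ie * y[6]) / p[4]
        out[1] = (p[1] - h_i + psi_ei * y[4] + psi_ii * y[8]) / p[5]
        for m in range(4):
            g = p[10 + m]
            if m == 0:
                drive = p[14] * S_e + p[24]
            elif m == 1:
                drive = p[15] * S_e + p[25]
            elif m == 2:
                drive = p[16] * S_i + p[26]
            else:
                drive = p[17] * S_i + p[27]
            I = y[2 + 2 * m]
            J = y[3 + 2 * m]
            out[2 + 2 * m] = J
            out[3 + 2 * m] = -2.0 * g * J - g * g * I + _E * p[6 + m] * g * drive
    elif sys_id == SYS_DIAG:
        for i in range(len(p)):
            out[i] = p[i] * y[i]
    elif sys_id == SYS_HOPF:
        mu = p[0]
        om = p[1]
        r2 = y[0] * y[0] + y[1] * y[1]
        out[0] = mu * y[0] - om * y[1] - y[0] * r2
        out[1] = om * y[0] + mu * y[1] - y[1] * r2
    else:  # lorenz
        out[0] = p[0] * (y[1] - y[0])
        out[1] = y[0] * (p[1] - y[2]) - y[1]
        out[2] = y[0] * y[1] - p[2] * y[2]


@njit(cache=True)
def sys_jac(sys_id, y, p, A):
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            A[i, j] = 0.0
    if sys_id == SYS_LILEY:
        h_e = y[0]
        h_i = y[1]
        a_e = _SQRT2 / p[22]
        a_i = _SQRT2 / p[23]
        s_e = _logistic(a_e * (h_e - p[20]))
        s_i = _logistic(a_i * (h_i - p[21]))
        dS_e = p[18] * a_e * s_e * (1.0 - s_e)
        dS_i = p[19] * a_i * s_i * (1.0 - s_i)
        psi_ee = (p[2] - h_e) / abs(p[2] - p[0])
        psi_ie = (p[3] - h_e) / abs(p[3] - p[0])
        psi_ei = (p[2] - h_i) / abs(p[2] - p[1])
        psi_ii = (p[3] - h_i) / abs(p[3] - p[1])
        A[0, 0] = (-1.0 - y[2] / abs(p[2] - p[0]) - y[6] / abs(p[3] - p[0])) / p[4]
        A[0, 2] = psi_ee / p[4]
        A[0, 6] = psi_ie / p[4]
        A[1, 1] = (-1.0 - y[4] / abs(p[2] - p[1]) - y[8] / abs(p[3] - p[1])) / p[5]
        A[1, 4] = psi_ei / p[5]
        A[1, 8] = psi_ii / p[5]
        for m in range(4):
            g = p[10 + m]
            A[2 + 2 * m, 3 + 2 * m] = 1.0
            A[3 + 2 * m, 2 + 2 * m] = -g * g
            A[3 + 2 * m, 3 + 2 * m] = -2.0 * g
            if m < 2:
                A[3 + 2 * m, 0] = _E * p[6 + m] * g * (p[14 + m]) * dS_e
            else:
                A[3 + 2 * m, 1] = _E * p[6 + m] * g * (p[14 + m]) * dS_i
    elif sys_id == SYS_DIAG:
        for i in range(n):
            A[i, i] = p[i]
    elif sys_id == SYS_HOPF:
        mu = p[0]
        om = p[1]
        x = y[0]
        z = y[1]
        A[0, 0] = mu - 3.0 * x * x - z * z
        A[0, 1] = -om - 2.0 * x * z
        A[1, 0] = om - 2.0 * x * z
        A[1, 1] = mu - x * x - 3.0 * z * z
    else:  # lorenz
        A[0, 0] = -p[0]
        A[0, 1] = p[0]
        A[1, 0] = p[1] - y[2]
        A[1, 1] = -1.0
        A[1, 2] = -y[0]
        A[2, 0] = y[1]
        A[2, 1] = y[0]
        A[2, 2] = -p[2]


@njit(cache=True)
def _finite(y, bound):
    for i in range(len(y)):
        v = y[i]
        if not (-bound < v < bound):  # also catches NaN
            return False
    return True


@njit(cache=True)
def integrate_transient(sys_id, p, y, t_total, dt, bound):
    """Advance the base flow by t_total with RK4 steps of size dt (in place).

    Returns True if the trajectory stayed inside the divergence bound.
    """
    n = len(y)
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    nsteps = int(round(t_total / dt))
    for step in range(nsteps):
        sys_rhs(sys_id, y, p, k1)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * dt * k1[i]
        sys_rhs(sys_id, tmp, p, k2)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * dt * k2[i]
        sys_rhs(sys_id, tmp, p, k3)
        for i in range(n):
            tmp[i] = y[i] + dt * k3[i]
        sys_rhs(sys_id, tmp, p, k4)
        for i in range(n):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if step % 200 == 0 and not _finite(y, bound):
            return False
    return _finite(y, bound)


@njit(cache=True)
def _mgs(Q, lognorms):
    """Modified Gram-Schmidt orthonormalization of the columns of Q in place.

    Stores log of the pre-normalization residual norms (the R diagonal of a
    positive-diagonal QR factorization) in ``lognorms``.
    """
    n, k = Q.shape
    for j in range(k):
        for m in range(j):
            dot = 0.0
            for i in range(n):
                dot += Q[i, m] * Q[i, j]
            for i in range(n):
                Q[i, j] -= dot * Q[i, m]
        nrm = 0.0
        for i in range(n):
            nrm += Q[i, j] * Q[i, j]
        nrm = math.sqrt(nrm)
        lognorms[j] = math.log(nrm)
        for i in range(n):
            Q[i, j] /= nrm


@njit(cache=True)
def _ortho_drift(Q):
    """max |e_i . e_j - delta_ij| over all column pairs."""
    n, k = Q.shape
    worst = 0.0
    for a in range(k):
        for b in range(a, k):
            dot = 0.0
            for i in range(n):
                dot += Q[i, a] * Q[i, b]
            target = 1.0 if a == b else 0.0
            d = abs(dot - target)
            if d > worst:
                worst = d
    return worst


@njit(cache=True)
def benettin_core(sys_id, p, y, Q, t_run, dt, dt_renorm, n_hist, bound):
    """Discrete QR (Benettin) tangent-flow integration.

    Integrates d/dt (y, Q) = (f(y), J(y) Q) with RK4, re-orthonormalizing the
    tangent frame every ``dt_renorm`` and accumulating log stretch factors.

    Returns (nu, hist_t, hist_lam, mean_trace, max_drift, diverged) where
    ``nu[j]`` is the accumulated log stretch of direction j (so
    lambda_j = nu[j] / t_run per ms), ``hist_lam`` holds running estimates at
    ``n_hist`` evenly spaced checkpoints, ``mean_trace`` is the time average
    of trace J along the trajectory, and ``max_drift`` the worst
    orthonormality defect observed just before renormalization.
    """
    n, k = Q.shape
    A = np.empty((n, n))
    ky1 = np.empty(n)
    ky2 = np.empty(n)
    ky3 = np.empty(n)
    ky4 = np.empty(n)
    ytmp = np.empty(n)
    kq1 = np.empty((n, k))
    kq2 = np.empty((n, k))
    kq3 = np.empty((n, k))
    kq4 = np.empty((n, k))
    qtmp = np.empty((n, k))
    lognorms = np.empty(k)
    nu = np.zeros(k)

    n_renorm = int(round(t_run / dt_renorm))
    steps_per = max(1, int(round(dt_renorm / dt)))
    hist_every = max(1, n_renorm // n_hist)
    hist_t = np.empty(n_hist)
    hist_lam = np.empty((n_hist, k))
    n_recorded = 0
    trace_acc = 0.0
    trace_n = 0
    max_drift = 0.0
    diverged = False

    for r in range(n_renorm):
        for s in range(steps_per):
            # stage 1
            sys_rhs(sys_id, y, p, ky1)
            sys_jac(sys_id, y, p, A)
            tr = 0.0
            for i in range(n):
                tr += A[i, i]
            trace_acc += tr
            trace_n += 1
            for i in range(n):
                for j in range(k):
                    acc = 0.0
                    for m in range(n):
                        acc += A[i, m] * Q[m, j]
                    kq1[i, j] = acc
            # stage 2
            for i in range(n):
                ytmp[i] = y[i] + 0.5 * dt * ky1[i]
            sys_rhs(sys_id, ytmp, p, ky2)
            sys_jac(sys_id, ytmp, p, A)
            for i in range(n):
                for j in range(k):
                    qtmp[i, j] = Q[i, j] + 0.5 * dt * kq1[i, j]
            for i in range(n):
                for j in range(k):
                    acc = 0.0
                    for m in range(n):
                        acc += A[i, m] * qtmp[m, j]
                    kq2[i, j] = acc
            # stage 3
            for i in range(n):
                ytmp[i] = y[i] + 0.5 * dt * ky2[i]
            sys_rhs(sys_id, ytmp, p, ky3)
            sys_jac(sys_id, ytmp, p, A)
            for i in range(n):
                for j in range(k):
                    qtmp[i, j] = Q[i, j] + 0.5 * dt * kq2[i, j]
            for i in range(n):
                for j in range(k):
                    acc = 0.0
                    for m in range(n):
                        acc += A[i, m] * qtmp[m, j]
                    kq3[i, j] = acc
            # stage 4
            for i in range(n):
                ytmp[i] = y[i] + dt * ky3[i]
            sys_rhs(sys_id, ytmp, p, ky4)
            sys_jac(sys_id, ytmp, p, A)
            for i in range(n):
                for j in range(k):
                    qtmp[i, j] = Q[i, j] + dt * kq3[i, j]
            for i in range(n):
                for j in range(k):
                    acc = 0.0
                    for m in range(n):
                        acc += A[i, m] * qtmp[m, j]
                    kq4[i, j] = acc
            for i in range(n):
                y[i] += dt / 6.0 * (ky1[i] + 2.0 * ky2[i] + 2.0 * ky3[i] + ky4[i])
                for j in range(k):
                    Q[i, j] += dt / 6.0 * (
                        kq1[i, j] + 2.0 * kq2[i, j] + 2.0 * kq3[i, j] + kq4[i, j]
                    )
        if not _finite(y, bound):
            diverged = True
            break
        drift = _ortho_drift(Q)
        if drift > max_drift:
            max_drift = drift
        _mgs(Q, lognorms)
        for j in range(k):
            nu[j] += lognorms[j]
        if (r + 1) % hist_every == 0 and n_recorded < n_hist:
            t_now = (r + 1) * dt_renorm
            hist_t[n_recorded] = t_now
            for j in range(k):
                hist_lam[n_recorded, j] = nu[j] / t_now
            n_recorded += 1

    mean_trace = trace_acc / trace_n if trace_n > 0 else 0.0
    return nu, hist_t[:n_recorded], hist_lam[:n_recorded], mean_trace, max_drift, diverged


@njit(cache=True)
def cgs_rhs(sys_id, p, n, k, z, dz, A, u):
    """Right-hand side of the continuous Gram-Schmidt augmented system.

    ``z`` packs (y, e_1..e_k, nu_1..nu_k), total length n + k*n + k.  With
    J the Jacobian at y and u_i = J e_i::

        dy/dt   = f(y)
        de_i/dt = u_i - (e_i.u_i) e_i - sum_{j<i} [(e_j.u_i) + (e_i.u_j)] e_j
        dnu_i/dt = e_i.u_i

    which keeps the frame orthonormal to first order while nu_i accumulates
    the i-th instantaneous expansion rate.
    """
    y = z[:n]
    sys_rhs(sys_id, y, p, dz[:n])
    sys_jac(sys_id, y, p, A)
    # u[:, i] = J e_i
    for ii in range(k):
        base = n + ii * n
        for r in range(n):
            acc = 0.0
            for c in range(n):
                acc += A[r, c] * z[base + c]
            u[r, ii] = acc
    for ii in range(k):
        base = n + ii * n
        # a_ii = e_i . u_i
        aii = 0.0
        for r in range(n):
            aii += z[base + r] * u[r, ii]
        for r in range(n):
            dz[base + r] = u[r, ii] - aii * z[base + r]
        for jj in range(ii):
            bj = n + jj * n
            c1 = 0.0  # e_j . u_i
            c2 = 0.0  # e_i . u_j
            for r in range(n):
                c1 += z[bj + r] * u[r, ii]
                c2 += z[base + r] * u[r, jj]
            coef = c1 + c2
            for r in range(n):
                dz[base + r] -= coef * z[bj + r]
        dz[n + k * n + ii] = aii


@njit(cache=True)
def cgs_core(sys_id, p, y0, Q0, t_run, dt, dt_renorm, n_hist, bound):
    """Continuous Gram-Schmidt integration of the augmented system.

    Same contract as :func:`benettin_core`; hard re-orthonormalization every
    ``dt_renorm`` is kept as numerical insurance, with the log of any norm
    drift folded into the accumulators so the estimates stay exact.
    """
    n = len(y0)
    k = Q0.shape[1]
    nz = n + k * n + k
    z = np.empty(nz)
    for i in range(n):
        z[i] = y0[i]
    for j in range(k):
        for i in range(n):
            z[n + j * n + i] = Q0[i, j]
        z[n + k * n + j] = 0.0

    dz = np.empty(nz)
    kz1 = np.empty(nz)
    kz2 = np.empty(nz)
    kz3 = np.empty(nz)
    kz4 = np.empty(nz)
    ztmp = np.empty(nz)
    A = np.empty((n, n))
    u = np.empty((n, k))
    E = np.empty((n, k))
    lognorms = np.empty(k)

    n_renorm = int(round(t_run / dt_renorm))
    steps_per = max(1, int(round(dt_renorm / dt)))
    hist_every = max(1, n_renorm // n_hist)
    hist_t = np.empty(n_hist)
    hist_lam = np.empty((n_hist, k))
    n_recorded = 0
    max_drift = 0.0
    diverged = False

    for r in range(n_renorm):
        for s in range(steps_per):
            cgs_rhs(sys_id, p, n, k, z, kz1, A, u)
            for i in range(nz):
                ztmp[i] = z[i] + 0.5 * dt * kz1[i]
            cgs_rhs(sys_id, p, n, k, ztmp, kz2, A, u)
            for i in range(nz):
                ztmp[i] = z[i] + 0.5 * dt * kz2[i]
            cgs_rhs(sys_id, p, n, k, ztmp, kz3, A, u)
            for i in range(nz):
                ztmp[i] = z[i] + dt * kz3[i]
            cgs_rhs(sys_id, p, n, k, ztmp, kz4, A, u)
            for i in range(nz):
                z[i] += dt / 6.0 * (kz1[i] + 2.0 * kz2[i] + 2.0 * kz3[i] + kz4[i])
            # frame-norm errors self-amplify at ~2|lambda| on contracting
            # directions, so drift is checked often and any early hard
            # renormalization is folded into the accumulators exactly
            if (s + 1) % 5 == 0 and s + 1 < steps_per:
                for j in range(k):
                    for i in range(n):
                        E[i, j] = z[n + j * n + i]
                if _ortho_drift(E) > 1e-9:
                    _mgs(E, lognorms)
                    for j in range(k):
                        z[n + k * n + j] += lognorms[j]
                        for i in range(n):
                            z[n + j * n + i] = E[i, j]
        if not _finite(z[:n], bound):
            diverged = True
            break
        for j in range(k):
            for i in range(n):
                E[i, j] = z[n + j * n + i]
        drift = _ortho_drift(E)
        if drift > max_drift:
            max_drift = drift
        _mgs(E, lognorms)
        for j in range(k):
            z[n + k * n + j] += lognorms[j]
            for i in range(n):
                z[n + j * n + i] = E[i, j]
        if (r + 1) % hist_every == 0 and n_recorded < n_hist:
            t_now = (r + 1) * dt_renorm
            hist_t[n_recorded] = t_now
            for j in range(k):
                hist_lam[n_recorded, j] = z[n + k * n + j] / t_now
            n_recorded += 1

    nu = np.empty(k)
    for j in range(k):
        nu[j] = z[n + k * n + j]
    return nu, hist_t[:n_recorded], hist_lam[:n_recorded], max_drift, diverged
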