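"""Compiled batch integrator for the reduced model.

The recovery-likelihood metric integrates hundreds of initial conditions for
1000 weeks per parameter set, and the sensitivity analysis repeats that for
thousands of parameter draws.  This module provides a numba-compiled,
L-stable Rosenbrock(2,3) integrator (the ode23s scheme) specialized to the
reduced vector field, using the closed-form Jacobian.  The system is stiff
whenever predators are abundant (urchin loss rates reach ~10^3/week while
kelp relaxes at ~1/week), so an implicit-capable scheme is required for the
long post-transient phase.

Numerical equivalence with :func:`kelpres.model_core.simulate` is checked in
the test suite.  Parameters are passed as a float array in
:data:`kelpres.params.PARAMETER_NAMES` order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rhs3", "jac3", "integrate_tail_mean", "batch_tail_mean", "integrate_final"]

_KAPPA_D_TINY = 1e-12

# parameter indices (PARAMETER_NAMES order)
_R, _K, _KD, _AA, _KS, _DA, _DD, _ED, _EU, _AD, _AU, _GU, _KA, _DU, _B, _ES, _DS = range(17)


@njit(cache=True, fastmath=False)
def _drift_eq(A: float, U: float, pa: np.ndarray) -> float:
    prod = pa[_ED] * pa[_DA] * A
    if pa[_KD] < _KAPPA_D_TINY:
        return prod / pa[_DD]
    if prod == 0.0:
        return 0.0
    a = pa[_KD] * (pa[_AD] * U + pa[_DD])
    b = pa[_DD] - prod * pa[_KD]
    c = -prod
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        disc = 0.0
    s = np.sqrt(disc)
    if b > 0.0:
        out = 2.0 * c / (-b - s)
    else:
        out = (-b + s) / (2.0 * a)
    return out if out > 0.0 else 0.0


@njit(cache=True, fastmath=False)
def rhs3(y: np.ndarray, pa: np.ndarray) -> np.ndarray:
    """Reduced vector field (dA, dU, dS); negative inputs are clamped."""
    A = y[0] if y[0] > 0.0 else 0.0
    U = y[1] if y[1] > 0.0 else 0.0
    S = y[2] if y[2] > 0.0 else 0.0
    D = _drift_eq(A, U, pa)
    T = A + D
    P = 1.0 / (1.0 + pa[_KD] * D)
    fear = 1.0 / (1.0 + pa[_KS] * S)
    susc = 1.0 / (1.0 + pa[_KA] * T)
    nutr = 1.0 + pa[_B] * T
    pred = pa[_AU] * U * S / (1.0 + pa[_GU] * U) * susc
    graze_live = P * pa[_AA] * A * U * fear
    graze_drift = (1.0 - P) * pa[_AD] * D * U
    out = np.empty(3)
    out[0] = pa[_R] * A * (1.0 - A / pa[_K]) - graze_live - pa[_DA] * A
    out[1] = pa[_EU] * (graze_live + graze_drift) - pred - pa[_DU] * U
    out[2] = pa[_ES] * nutr * pred - pa[_DS] * S
    return out


@njit(cache=True, fastmath=False)
def jac3(y: np.ndarray, pa: np.ndarray) -> np.ndarray:
    """Closed-form Jacobian of :func:`rhs3` (mirrors model_core)."""
    A = y[0] if y[0] > 0.0 else 0.0
    U = y[1] if y[1] > 0.0 else 0.0
    S = y[2] if y[2] > 0.0 else 0.0
    D = _drift_eq(A, U, pa)
    prod = pa[_ED] * pa[_DA]
    if pa[_KD] < _KAPPA_D_TINY:
        D_A = prod / pa[_DD]
        D_U = 0.0
    else:
        a = pa[_KD] * (pa[_AD] * U + pa[_DD])
        b = pa[_DD] - prod * A * pa[_KD]
        gD = 2.0 * a * D + b
        if gD < 1e-300:
            gD = 1e-300
        D_A = prod * (1.0 + pa[_KD] * D) / gD
        D_U = -pa[_KD] * pa[_AD] * D * D / gD

    T = A + D
    P = 1.0 / (1.0 + pa[_KD] * D)
    Q = 1.0 - P
    P_D = -pa[_KD] * P * P
    Ff = 1.0 / (1.0 + pa[_KS] * S)
    Ff_S = -pa[_KS] * Ff * Ff
    Fs = 1.0 / (1.0 + pa[_KA] * T)
    Fs_T = -pa[_KA] * Fs * Fs
    Fn = 1.0 + pa[_B] * T
    om = 1.0 + pa[_GU] * U
    H = U / om
    H_U = 1.0 / (om * om)

    fA_A = pa[_R] * (1.0 - 2.0 * A / pa[_K]) - P * pa[_AA] * U * Ff - pa[_DA]
    fA_D = -P_D * pa[_AA] * A * U * Ff
    fA_U = -P * pa[_AA] * A * Ff
    fA_S = -P * pa[_AA] * A * U * Ff_S

    fU_A = pa[_EU] * P * pa[_AA] * Ff * U - pa[_AU] * H * S * Fs_T
    fU_D = (
        pa[_EU] * U * (P_D * pa[_AA] * A * Ff - P_D * pa[_AD] * D + Q * pa[_AD])
        - pa[_AU] * H * S * Fs_T
    )
    fU_U = (
        pa[_EU] * (P * pa[_AA] * A * Ff + Q * pa[_AD] * D)
        - pa[_AU] * H_U * S * Fs
        - pa[_DU]
    )
    fU_S = pa[_EU] * P * pa[_AA] * A * U * Ff_S - pa[_AU] * H * Fs

    fS_A = pa[_ES] * pa[_AU] * H * S * (pa[_B] * Fs + Fn * Fs_T)
    fS_U = pa[_ES] * Fn * pa[_AU] * H_U * S * Fs
    fS_S = pa[_ES] * Fn * pa[_AU] * H * Fs - pa[_DS]

    J = np.empty((3, 3))
    J[0, 0] = fA_A + fA_D * D_A
    J[0, 1] = fA_U + fA_D * D_U
    J[0, 2] = fA_S
    J[1, 0] = fU_A + fU_D * D_A
    J[1, 1] = fU_U + fU_D * D_U
    J[1, 2] = fU_S
    J[2, 0] = fS_A + fS_A * D_A  # fS_D == fS_A (symmetric in total kelp)
    J[2, 1] = fS_U + fS_A * D_U
    J[2, 2] = fS_S
    return J


@njit(cache=True, fastmath=False)
def _solve3(M: np.ndarray, b1: np.ndarray, b2: np.ndarray, b3: np.ndarray):
    """Solve M x = b for three right-hand sides (Gauss, partial pivoting)."""
    a = M.copy()
    r = np.empty((3, 3))
    r[0] = b1
    r[1] = b2
    r[2] = b3
    for col in range(3):
        piv = col
        best = abs(a[col, col])
        for row in range(col + 1, 3):
            if abs(a[row, col]) > best:
                best = abs(a[row, col])
                piv = row
        if piv != col:
            for j in range(3):
                a[col, j], a[piv, j] = a[piv, j], a[col, j]
            for j in range(3):
                r[j, col], r[j, piv] = r[j, piv], r[j, col]
        d = a[col, col]
        if d == 0.0:
            d = 1e-300
        for row in range(col + 1, 3):
            f = a[row, col] / d
            if f != 0.0:
                for j in range(col, 3):
                    a[row, j] -= f * a[col, j]
                for j in range(3):
                    r[j, row] -= f * r[j, col]
    x = np.empty((3, 3))
    for j in range(3):
        for row in range(2, -1, -1):
            s = r[j, row]
            for col2 in range(row + 1, 3):
                s -= a[row, col2] * x[j, col2]
            x[j, row] = s / (a[row, row] if a[row, row] != 0.0 else 1e-300)
    return x[0], x[1], x[2]


_RD = 1.0 / (2.0 + np.sqrt(2.0))
_E32 = 6.0 + np.sqrt(2.0)


@njit(cache=True, fastmath=False)
def _integrate(
    y0: np.ndarray,
    pa: np.ndarray,
    t_end: float,
    tail_start: float,
    rtol: float,
    atol: float,
    max_steps: int,
):
    """Rosenbrock(2,3) integration to ``t_end``.

    Returns (integral of A over [tail_start, t_end], final state, status):
    status 0 = success, 1 = step budget exhausted, 2 = step size underflow /
    non-finite state.
    """
    y = y0.copy()
    for i in range(3):
        if y[i] < 0.0:
            y[i] = 0.0
    t = 0.0
    acc = 0.0
    dt = 1e-4
    nsteps = 0
    I3 = np.eye(3)
    f0 = rhs3(y, pa)
    while t < t_end:
        if nsteps >= max_steps:
            return acc, y, 1
        if t + dt > t_end:
            dt = t_end - t

        J = jac3(y, pa)
        W = I3 - (dt * _RD) * J
        k1, _, _ = _solve3(W, f0, f0, f0)
        f1 = rhs3(y + 0.5 * dt * k1, pa)
        rhs_k2 = f1 - k1
        k2s, _, _ = _solve3(W, rhs_k2, rhs_k2, rhs_k2)
        k2 = k2s + k1
        ynew = y + dt * k2
        bad = False
        for i in range(3):
            if not np.isfinite(ynew[i]):
                bad = True
        if bad:
            dt *= 0.1
            nsteps += 1
            if dt < 1e-13 * max(t, 1.0):
                return acc, y, 2
            continue
        f2 = rhs3(ynew, pa)
        rhs_k3 = f2 - _E32 * (k2 - f1) - 2.0 * (k1 - f0)
        k3, _, _ = _solve3(W, rhs_k3, rhs_k3, rhs_k3)

        errnorm = 0.0
        for i in range(3):
            err = (dt / 6.0) * (k1[i] - 2.0 * k2[i] + k3[i])
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            e = abs(err) / sc
            if e > errnorm:
                errnorm = e
        nsteps += 1

        if errnorm <= 1.0:
            t1 = t + dt
            lo = t if t > tail_start else tail_start
            if t1 > lo:
                if dt > 0.0:
                    a_lo = y[0] + (ynew[0] - y[0]) * (lo - t) / dt
                else:
                    a_lo = y[0]
                acc += 0.5 * (a_lo + ynew[0]) * (t1 - lo)
            t = t1
            y = ynew
            clamped = False
            for i in range(3):
                if y[i] < 0.0:
                    y[i] = 0.0
                    clamped = True
            f0 = f2 if not clamped else rhs3(y, pa)
            # conservative early exit: bound on remaining relative change
            if t < tail_start:
                fmax = 0.0
                for i in range(3):
                    rel = abs(f0[i]) / (1.0 + abs(y[i]))
                    if rel > fmax:
                        fmax = rel
                if fmax * (t_end - t) < 1e-7:
                    return y[0] * (t_end - tail_start), y, 0
            fac = 0.9 * errnorm ** (-1.0 / 3.0) if errnorm > 0.0 else 5.0
            if fac > 5.0:
                fac = 5.0
            dt *= fac
        else:
            fac = 0.9 * errnorm ** (-1.0 / 3.0)
            if fac < 0.1:
                fac = 0.1
            dt *= fac
            if dt < 1e-13 * max(t, 1.0):
                return acc, y, 2
    return acc, y, 0


@njit(cache=True, fastmath=False)
def integrate_tail_mean(
    y0: np.ndarray,
    pa: np.ndarray,
    t_end: float = 1000.0,
    tail: float = 100.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    max_steps: int = 500_000,
):
    """Tail-window average of A plus final state and status for one IC."""
    tail_start = t_end - tail
    acc, y, status = _integrate(y0, pa, t_end, tail_start, rtol, atol, max_steps)
    return acc / tail, y, status


@njit(cache=True, fastmath=False)
def integrate_final(
    y0: np.ndarray,
    pa: np.ndarray,
    t_end: float,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    max_steps: int = 500_000,
):
    """Final state of one integration (tail bookkeeping skipped)."""
    _acc, y, status = _integrate(y0, pa, t_end, t_end, rtol, atol, max_steps)
    return y, status


@njit(cache=True, fastmath=False)
def integrate_nodes(
    y0: np.ndarray,
    pa: np.ndarray,
    t_end: float,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    max_steps: int = 500_000,
    buf_size: int = 4096,
):
    """Integrate and record the trajectory's accepted states.

    Returns (nodes, n_recorded, status).  When the buffer fills, every other
    recorded state is dropped and recording continues at twice the stride,
    so the stored nodes always span the whole trajectory with bounded
    memory.  Used to trace deterministic-flow legs of transition paths.
    """
    buf = np.empty((buf_size, 3))
    y = y0.copy()
    for i in range(3):
        if y[i] < 0.0:
            y[i] = 0.0
    buf[0] = y
    nrec = 1
    stride = 1
    count = 0
    t = 0.0
    dt = 1e-4
    nsteps = 0
    I3 = np.eye(3)
    f0 = rhs3(y, pa)
    status = 0
    while t < t_end:
        if nsteps >= max_steps:
            status = 1
            break
        if t + dt > t_end:
            dt = t_end - t
        J = jac3(y, pa)
        W = I3 - (dt * _RD) * J
        k1, _, _ = _solve3(W, f0, f0, f0)
        f1 = rhs3(y + 0.5 * dt * k1, pa)
        rk2 = f1 - k1
        k2s, _, _ = _solve3(W, rk2, rk2, rk2)
        k2 = k2s + k1
        ynew = y + dt * k2
        bad = False
        for i in range(3):
            if not np.isfinite(ynew[i]):
                bad = True
        if bad:
            dt *= 0.1
            nsteps += 1
            if dt < 1e-13 * max(t, 1.0):
                status = 2
                break
            continue
        f2 = rhs3(ynew, pa)
        rk3 = f2 - _E32 * (k2 - f1) - 2.0 * (k1 - f0)
        k3, _, _ = _solve3(W, rk3, rk3, rk3)
        errnorm = 0.0
        for i in range(3):
            err = (dt / 6.0) * (k1[i] - 2.0 * k2[i] + k3[i])
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            e = abs(err) / sc
            if e > errnorm:
                errnorm = e
        nsteps += 1
        if errnorm <= 1.0:
            t += dt
            y = ynew
            clamped = False
            for i in range(3):
                if y[i] < 0.0:
                    y[i] = 0.0
                    clamped = True
            f0 = f2 if not clamped else rhs3(y, pa)
            count += 1
            if count % stride == 0:
                if nrec >= buf_size:
                    # thin the buffer, double the stride
                    half = nrec // 2
                    for j in range(half):
                        buf[j] = buf[2 * j + 1]
                    nrec = half
                    stride *= 2
                buf[nrec] = y
                nrec += 1
            fmax = 0.0
            for i in range(3):
                rel = abs(f0[i]) / (1.0 + abs(y[i]))
                if rel > fmax:
                    fmax = rel
            if fmax * (t_end - t) < 1e-9:
                break
            fac = 0.9 * errnorm ** (-1.0 / 3.0) if errnorm > 0.0 else 5.0
            if fac > 5.0:
                fac = 5.0
            dt *= fac
        else:
            fac = 0.9 * errnorm ** (-1.0 / 3.0)
            if fac < 0.1:
                fac = 0.1
            dt *= fac
            if dt < 1e-13 * max(t, 1.0):
                status = 2
                break
    if nrec < buf_size and (nrec == 0 or (buf[nrec - 1] != y).any()):
        buf[nrec] = y
        nrec += 1
    return buf[:nrec], nrec, status


@njit(cache=True, fastmath=False)
def batch_tail_mean(
    Y0: np.ndarray,
    pa: np.ndarray,
    t_end: float = 1000.0,
    tail: float = 100.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    max_steps: int = 500_000,
):
    """Tail-mean A, final states and statuses for a batch of ICs."""
    n = Y0.shape[0]
    tails = np.empty(n)
    finals = np.empty((n, 3))
    status = np.zeros(n, dtype=np.int64)
    for i in range(n):
        tm, y, st = integrate_tail_mean(Y0[i], pa, t_end, tail, rtol, atol, max_steps)
        tails[i] = tm
        finals[i] = y
        status[i] = st
    return tails, finals, status
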