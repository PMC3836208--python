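"""Symmetry-reduced dynamics and a batched compiled integrator.

With a niche-per-clone affinity structure and class-wise identical
parameters, clones that start from identical (healthy, preleukemic) cell
counts stay identical forever.  Grouping the ``q`` clones into ``G`` such
classes collapses the ``2q``-species system to ``2G`` equations.  For a
class-``g`` clone with healthy abundance ``h_g`` and preleukemic abundance
``z_g`` the niche denominator is::

    D_g = s_h h_g + s_p z_g + u_h H + u_p Z

(``H``, ``Z`` totals over all clones), every niche supplies ``p`` resource
units per hour, and with ``S = sum_g N_g / D_g`` the carrying capacities are
proportional to abundance::

    k_h,g = v_h p h_g (s_h / D_g + u_h S)
    k_p,g = v_p p z_g (s_p / D_g + u_p S)

so each species follows ``dc/dt = c/tau (1 - 1/phi)`` with an abundance-free
capacity ratio ``phi``.  The batched integrator runs one adaptive
Dormand-Prince 5(4) solver per parameter set, samples checkpoints by cubic
Hermite interpolation, and applies the same steady-state criterion and
abundance floor as the full-system path.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit, prange

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

    prange = range  # type: ignore

__all__ = ["reduce_classes", "integrate_reduced_batch", "HAVE_NUMBA"]


def reduce_classes(h0: np.ndarray, z0: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group clones with identical initial ``(h0, z0)`` pairs.

    Returns ``(sizes, h0_class, z0_class)`` with classes in order of first
    appearance.  Valid because clones are exchangeable up to their initial
    condition.
    """
    pairs = np.stack([np.asarray(h0), np.asarray(z0)], axis=1)
    uniq, first, counts = np.unique(
        pairs, axis=0, return_index=True, return_counts=True
    )
    order = np.argsort(first)
    uniq, counts = uniq[order], counts[order]
    return counts.astype(np.int64), uniq[:, 0].astype(float), uniq[:, 1].astype(float)


# Dormand-Prince 5(4) coefficients (the classic RK45 pair).
_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = np.zeros((7, 7))
_DP_A[1, 0] = 1 / 5
_DP_A[2, :2] = (3 / 40, 9 / 40)
_DP_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_DP_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_DP_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_DP_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_DP_B = _DP_A[6, :7].copy()  # 5th-order solution weights (FSAL)
_DP_E = np.array(
    [71 / 57600, 0.0, -71 / 16695, 71 / 1920, -17253 / 339200, 22 / 525, -1 / 40]
)


@njit(cache=True)
def _rhs(y, dy, G, Ng, sh, uh, vh, sp, up, vp, p, tau):
    H = 0.0
    Z = 0.0
    for g in range(G):
        H += Ng[g] * y[g]
        Z += Ng[g] * y[G + g]
    S = 0.0
    for g in range(G):
        D = sh * y[g] + sp * y[G + g] + uh * H + up * Z
        dy[g] = D  # reuse dy[0:G] as scratch for D_g
        if D > 0.0:
            S += Ng[g] / D
    for g in range(G):
        D = dy[g]
        invD = 1.0 / D if D > 0.0 else 0.0
        phi_h = vh * p * (sh * invD + uh * S)
        phi_p = vp * p * (sp * invD + up * S)
        h = y[g]
        z = y[G + g]
        dy[g] = h / tau * (1.0 - 1.0 / phi_h) if (phi_h > 0.0 and h > 0.0) else 0.0
        dy[G + g] = z / tau * (1.0 - 1.0 / phi_p) if (phi_p > 0.0 and z > 0.0) else 0.0


@njit(cache=True)
def _integrate_one(y, G, Ng, sh, uh, vh, sp, up, vp, p, tau,
                   rel_tol, check_dt, t_max, floor, rtol, atol, dt_max,
                   A, B, C, E):
    d = 2 * G
    k = np.empty((7, d))
    ytmp = np.empty(d)
    ynew = np.empty(d)
    ycp = np.empty(d)
    yprev = np.empty(d)

    for i in range(d):
        if y[i] < floor:
            y[i] = 0.0
        yprev[i] = y[i]

    _rhs(y, k[0], G, Ng, sh, uh, vh, sp, up, vp, p, tau)
    t = 0.0
    next_cp = check_dt
    dt = 1e-2
    converged = False
    t_conv = -1.0

    while t < t_max - 1e-9:
        h_step = dt
        if t + h_step > t_max:
            h_step = t_max - t
        # -- one Dormand-Prince step ------------------------------------
        for s in range(1, 7):
            for i in range(d):
                acc = 0.0
                for j in range(s):
                    acc += A[s, j] * k[j][i]
                ytmp[i] = y[i] + h_step * acc
            if s == 6:
                for i in range(d):
                    ynew[i] = ytmp[i]
            _rhs(ytmp, k[s], G, Ng, sh, uh, vh, sp, up, vp, p, tau)
        errnorm = 0.0
        for i in range(d):
            err = 0.0
            for j in range(7):
                err += E[j] * k[j][i]
            err *= h_step
            ay = abs(y[i])
            an = abs(ynew[i])
            scale = atol + rtol * (ay if ay > an else an)
            e = err / scale
            errnorm += e * e
        errnorm = np.sqrt(errnorm / d)

        if errnorm <= 1.0 or h_step <= 1e-12:
            # accepted: process checkpoints inside (t, t+h_step]
            t_new = t + h_step
            clamped = False
            while next_cp <= t_new + 1e-9 and not converged:
                th = (next_cp - t) / h_step
                # cubic Hermite using endpoint derivatives k[0], k[6]
                h00 = (1.0 + 2.0 * th) * (1.0 - th) * (1.0 - th)
                h10 = th * (1.0 - th) * (1.0 - th)
                h01 = th * th * (3.0 - 2.0 * th)
                h11 = th * th * (th - 1.0)
                relmax = 0.0
                for i in range(d):
                    yi = (h00 * y[i] + h10 * h_step * k[0][i]
                          + h01 * ynew[i] + h11 * h_step * k[6][i])
                    if yi < floor:
                        yi = 0.0
                    ycp[i] = yi
                    denom = yprev[i] if yprev[i] > floor else floor
                    rel = abs(yi - yprev[i]) / denom
                    if rel > relmax:
                        relmax = rel
                if relmax < rel_tol:
                    converged = True
                    t_conv = next_cp
                    for i in range(d):
                        y[i] = ycp[i]
                else:
                    for i in range(d):
                        yprev[i] = ycp[i]
                    next_cp += check_dt
            if converged:
                break
            for i in range(d):
                y[i] = ynew[i]
                k[0][i] = k[6][i]  # FSAL
            t = t_new
            for i in range(d):
                if y[i] != 0.0 and y[i] < floor:
                    y[i] = 0.0
                    clamped = True
            if clamped:
                _rhs(y, k[0], G, Ng, sh, uh, vh, sp, up, vp, p, tau)
            # step-size update
            if errnorm == 0.0:
                fac = 10.0
            else:
                fac = 0.9 * errnorm ** -0.2
                if fac > 10.0:
                    fac = 10.0
                elif fac < 0.2:
                    fac = 0.2
            dt = h_step * fac
            if dt > dt_max:
                dt = dt_max
        else:
            fac = 0.9 * errnorm ** -0.2
            if fac < 0.1:
                fac = 0.1
            dt = h_step * fac
    return converged, t_conv


@njit(cache=True, parallel=True)
def _integrate_batch(y0, Ng, sh, uh, vh, sp_arr, up_arr, vp_arr, p, tau,
                     rel_tol, check_dt, t_max, floor, rtol, atol, dt_max,
                     A, B, C, E):
    B_n = sp_arr.shape[0]
    d = y0.shape[0]
    G = d // 2
    yout = np.empty((B_n, d))
    conv = np.zeros(B_n, dtype=np.bool_)
    tconv = np.full(B_n, -1.0)
    for b in prange(B_n):
        y = y0.copy()
        c, tc = _integrate_one(
            y, G, Ng, sh, uh, vh, sp_arr[b], up_arr[b], vp_arr[b], p, tau,
            rel_tol, check_dt, t_max, floor, rtol, atol, dt_max, A, B, C, E,
        )
        conv[b] = c
        tconv[b] = tc
        for i in range(d):
            yout[b, i] = y[i]
    return yout, conv, tconv


def integrate_reduced_batch(
    Ng: np.ndarray,
    h0: np.ndarray,
    z0: np.ndarray,
    s_p: np.ndarray,
    u_p: np.ndarray,
    v_p: np.ndarray,
    *,
    s_h: float,
    u_h: float,
    v_h: float,
    p: float,
    tau: float,
    rel_change_tol: float = 1e-6,
    check_interval: float = 1.0,
    t_max: float = 1e7,
    abundance_floor: float = 1e-9,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dt_max_intervals: float = 64.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Integrate one reduced system for every preleukemic parameter triple.

    Parameters are per-clone-class initial conditions (``Ng`` class sizes,
    ``h0``/``z0`` per-clone abundances) shared across the batch, and arrays
    ``s_p, u_p, v_p`` of preleukemic parameters, one entry per run.

    Returns ``(h_final, z_final, converged, t_converged)`` with the final
    per-clone abundances of shape ``(B, G)``.
    """
    Ng = np.ascontiguousarray(Ng, dtype=np.int64)
    G = Ng.shape[0]
    y0 = np.concatenate([np.asarray(h0, float), np.asarray(z0, float)])
    s_p = np.ascontiguousarray(s_p, dtype=float)
    u_p = np.ascontiguousarray(u_p, dtype=float)
    v_p = np.ascontiguousarray(v_p, dtype=float)
    yout, conv, tconv = _integrate_batch(
        y0, Ng, float(s_h), float(u_h), float(v_h), s_p, u_p, v_p,
        float(p), float(tau),
        float(rel_change_tol), float(check_interval), float(t_max),
        float(abundance_floor), float(rtol), float(atol),
        float(dt_max_intervals * check_interval),
        _DP_A, _DP_B, _DP_C, _DP_E,
    )
    return yout[:, :G], yout[:, G:], conv, tconv
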