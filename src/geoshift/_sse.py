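"""Numba kernels for the state-dependent birth-death (MuSSE) likelihood.

Per branch, the coupled ODEs

    dE_i/dt = mu_i - (lam_i + mu_i + sum_{j!=i} q_ij) E_i
              + lam_i E_i^2 + sum_{j!=i} q_ij E_j
    dD_i/dt = -(lam_i + mu_i + sum_{j!=i} q_ij) D_i
              + sum_{j!=i} q_ij D_j + 2 lam_i E_i D_i

are integrated from the branch's young end toward the root with an adaptive
Cash-Karp Runge-Kutta 4(5) scheme (relative tolerance 1e-10, absolute
1e-12).  D is renormalized at every node and branch end, with the log of
the scaling factors accumulated, to avoid underflow on large trees.
"""

import numpy as np
from numba import njit

# Cash-Karp tableau
_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0],
    [1.0 / 5.0, 0.0, 0.0, 0.0, 0.0],
    [3.0 / 40.0, 9.0 / 40.0, 0.0, 0.0, 0.0],
    [3.0 / 10.0, -9.0 / 10.0, 6.0 / 5.0, 0.0, 0.0],
    [-11.0 / 54.0, 5.0 / 2.0, -70.0 / 27.0, 35.0 / 27.0, 0.0],
    [1631.0 / 55296.0, 175.0 / 512.0, 575.0 / 13824.0,
     44275.0 / 110592.0, 253.0 / 4096.0],
])
_B5 = np.array([37.0 / 378.0, 0.0, 250.0 / 621.0, 125.0 / 594.0, 0.0,
                512.0 / 1771.0])
_B4 = np.array([2825.0 / 27648.0, 0.0, 18575.0 / 48384.0,
                13525.0 / 55296.0, 277.0 / 14336.0, 1.0 / 4.0])

RTOL = 1e-10
ATOL = 1e-12


@njit(cache=True)
def _rhs(y, lam, mu, q, k, out):
    for i in range(k):
        qi = -q[i, i]
        tot = lam[i] + mu[i] + qi
        s_e = 0.0
        s_d = 0.0
        for j in range(k):
            if j != i:
                s_e += q[i, j] * y[j]
                s_d += q[i, j] * y[k + j]
        ei = y[i]
        out[i] = mu[i] - tot * ei + lam[i] * ei * ei + s_e
        out[k + i] = -tot * y[k + i] + s_d + 2.0 * lam[i] * ei * y[k + i]


@njit(cache=True)
def _integrate(y, t_len, lam, mu, q, a, b5, b4, rtol, atol):
    """Advance y over t_len with adaptive Cash-Karp RK45; returns 1 on
    success, 0 on failure (step underflow or non-finite values)."""
    k = lam.shape[0]
    n = 2 * k
    t = 0.0
    h = t_len
    ks = np.empty((6, n))
    ytmp = np.empty(n)
    y5 = np.empty(n)
    while t < t_len:
        if h > t_len - t:
            h = t_len - t
        _rhs(y, lam, mu, q, k, ks[0])
        for s in range(1, 6):
            for m in range(n):
                acc = 0.0
                for j in range(s):
                    acc += a[s, j] * ks[j, m]
                ytmp[m] = y[m] + h * acc
            _rhs(ytmp, lam, mu, q, k, ks[s])
        errnorm = 0.0
        for m in range(n):
            acc5 = 0.0
            acc4 = 0.0
            for s in range(6):
                acc5 += b5[s] * ks[s, m]
                acc4 += b4[s] * ks[s, m]
            y5[m] = y[m] + h * acc5
            sc = atol + rtol * max(abs(y[m]), abs(y5[m]))
            e = abs(h * (acc5 - acc4)) / sc
            if e > errnorm:
                errnorm = e
        if not np.isfinite(errnorm):
            return 0
        if errnorm <= 1.0:
            t += h
            for m in range(n):
                y[m] = y5[m]
            # keep E in [0, 1] against round-off
            for i in range(k):
                if y[i] < 0.0:
                    if y[i] < -1e-6:
                        return 0
                    y[i] = 0.0
                elif y[i] > 1.0:
                    if y[i] > 1.0 + 1e-6:
                        return 0
                    y[i] = 1.0
            fac = 5.0 if errnorm == 0.0 else 0.9 * errnorm ** (-0.2)
            if fac > 5.0:
                fac = 5.0
            h *= fac
        else:
            fac = 0.9 * errnorm ** (-0.2)
            if fac < 0.2:
                fac = 0.2
            h *= fac
        if h < 1e-14 * t_len:
            return 0
    return 1


@njit(cache=True)
def musse_loglik_core(post, left, right, blen, tipstate, lam, mu, q, rho,
                      use_fitzjohn, root_w, cond_surv):
    """MuSSE log-likelihood by postorder branch integration.

    Returns (loglik, status): status 0 = ok, otherwise the node id where
    integration failed (as a negative likelihood is meaningless then).
    """
    n = post.shape[0]
    k = lam.shape[0]
    e_arr = np.zeros((n, k))
    d_arr = np.zeros((n, k))
    logcomp = 0.0
    y = np.empty(2 * k)
    root = post[n - 1]
    for idx in range(n):
        nd = post[idx]
        if left[nd] < 0:
            for i in range(k):
                e_arr[nd, i] = 1.0 - rho[i]
                d_arr[nd, i] = rho[i] if tipstate[nd] == i else 0.0
        else:
            lc = left[nd]
            rc = right[nd]
            for i in range(k):
                e_arr[nd, i] = e_arr[lc, i]
                d_arr[nd, i] = d_arr[lc, i] * d_arr[rc, i] * lam[i]
        mx = 0.0
        for i in range(k):
            if d_arr[nd, i] > mx:
                mx = d_arr[nd, i]
        if mx <= 0.0:
            return -np.inf, 0
        for i in range(k):
            d_arr[nd, i] /= mx
        logcomp += np.log(mx)
        if nd != root and blen[nd] > 0.0:
            for i in range(k):
                y[i] = e_arr[nd, i]
                y[k + i] = d_arr[nd, i]
            ok = _integrate(y, blen[nd], lam, mu, q, _A, _B5, _B4,
                            RTOL, ATOL)
            if ok == 0:
                return np.nan, nd + 1
            mx = 0.0
            for i in range(k):
                e_arr[nd, i] = y[i]
                d_arr[nd, i] = y[k + i]
                if y[k + i] > mx:
                    mx = y[k + i]
            if mx <= 0.0:
                return -np.inf, 0
            for i in range(k):
                d_arr[nd, i] /= mx
            logcomp += np.log(mx)
    # root treatment
    d_root = d_arr[root]
    e_root = e_arr[root]
    tot = 0.0
    for i in range(k):
        tot += d_root[i]
    if tot <= 0.0:
        return -np.inf, 0
    w = np.empty(k)
    for i in range(k):
        w[i] = d_root[i] / tot if use_fitzjohn else root_w[i]
    if cond_surv:
        denom = 0.0
        for i in range(k):
            denom += w[i] * lam[i] * (1.0 - e_root[i]) ** 2
        if denom <= 0.0:
            return -np.inf, 0
        logcomp -= np.log(denom)
    lik = 0.0
    for i in range(k):
        lik += w[i] * d_root[i]
    if lik <= 0.0:
        return -np.inf, 0
    return np.log(lik) + logcomp, 0
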