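"""Numba kernels for the diploid ancestry HMM.

State space is specialist-allele dosage k in {0, 1, 2} (ascending).  The
haploid ancestry chain over genetic distance d is

    Q(d) = exp(-d*T) * I + (1 - exp(-d*T)) * Pi,   Pi rows = (alpha, 1-alpha)

(single-pulse kinetics); the diploid chain is the product of two independent
haploid chains collapsed to dosage.  Emissions are precomputed per
(individual, site, dosage) by the caller.
"""

import numpy as np
from numba import njit


@njit(inline="always")
def _fill_diploid_trans(x, alpha, A):
    # x = exp(-d*T); haploid transition entries
    pss = x + (1.0 - x) * alpha
    psg = 1.0 - pss
    pgs = (1.0 - x) * alpha
    pgg = 1.0 - pgs
    A[0, 0] = pgg * pgg
    A[0, 1] = 2.0 * pgg * pgs
    A[0, 2] = pgs * pgs
    A[1, 0] = psg * pgg
    A[1, 1] = pss * pgg + psg * pgs
    A[1, 2] = pss * pgs
    A[2, 0] = psg * psg
    A[2, 1] = 2.0 * pss * psg
    A[2, 2] = pss * pss


@njit
def chain_loglik(E, d, T, alpha):
    """Scaled-forward log-likelihood summed over individuals.

    E: (n_ind, n_sites, 3) emissions; d: (n_sites-1,) Morgans between
    consecutive sites.  Returns -inf on numerical underflow to zero.
    """
    n_ind, n_sites, _ = E.shape
    pi0 = (1.0 - alpha) ** 2
    pi1 = 2.0 * alpha * (1.0 - alpha)
    pi2 = alpha * alpha
    A = np.empty((3, 3))
    f = np.empty((n_ind, 3))
    total = 0.0
    for i in range(n_ind):
        f[i, 0] = pi0 * E[i, 0, 0]
        f[i, 1] = pi1 * E[i, 0, 1]
        f[i, 2] = pi2 * E[i, 0, 2]
        s = f[i, 0] + f[i, 1] + f[i, 2]
        if s <= 0.0:
            return -np.inf
        total += np.log(s)
        f[i, 0] /= s
        f[i, 1] /= s
        f[i, 2] /= s
    for t in range(1, n_sites):
        _fill_diploid_trans(np.exp(-d[t - 1] * T), alpha, A)
        for i in range(n_ind):
            a0 = f[i, 0] * A[0, 0] + f[i, 1] * A[1, 0] + f[i, 2] * A[2, 0]
            a1 = f[i, 0] * A[0, 1] + f[i, 1] * A[1, 1] + f[i, 2] * A[2, 1]
            a2 = f[i, 0] * A[0, 2] + f[i, 1] * A[1, 2] + f[i, 2] * A[2, 2]
            b0 = a0 * E[i, t, 0]
            b1 = a1 * E[i, t, 1]
            b2 = a2 * E[i, t, 2]
            s = b0 + b1 + b2
            if s <= 0.0:
                return -np.inf
            total += np.log(s)
            f[i, 0] = b0 / s
            f[i, 1] = b1 / s
            f[i, 2] = b2 / s
    return total


@njit
def block_logliks(E, d, starts, stops, T, alpha, out):
    """Per-block log-likelihood, each block an independent chain."""
    for b in range(starts.size):
        s0, s1 = starts[b], stops[b]
        out[b] = chain_loglik(E[:, s0:s1, :], d[s0 : s1 - 1], T, alpha)


@njit
def chain_forward_backward(E1, d, T, alpha):
    """Posterior dosage probabilities and log-likelihood for one individual.

    Scaled forward/backward; posteriors rows sum to 1.
    """
    n = E1.shape[0]
    pi = np.empty(3)
    pi[0] = (1.0 - alpha) ** 2
    pi[1] = 2.0 * alpha * (1.0 - alpha)
    pi[2] = alpha * alpha
    f = np.empty((n, 3))
    c = np.empty(n)
    A = np.empty((3, 3))
    for k in range(3):
        f[0, k] = pi[k] * E1[0, k]
    c[0] = f[0, 0] + f[0, 1] + f[0, 2]
    for k in range(3):
        f[0, k] /= c[0]
    for t in range(1, n):
        _fill_diploid_trans(np.exp(-d[t - 1] * T), alpha, A)
        for k in range(3):
            f[t, k] = (
                f[t - 1, 0] * A[0, k] + f[t - 1, 1] * A[1, k] + f[t - 1, 2] * A[2, k]
            ) * E1[t, k]
        c[t] = f[t, 0] + f[t, 1] + f[t, 2]
        for k in range(3):
            f[t, k] /= c[t]
    b = np.empty((n, 3))
    for k in range(3):
        b[n - 1, k] = 1.0
    for t in range(n - 2, -1, -1):
        _fill_diploid_trans(np.exp(-d[t] * T), alpha, A)
        for j in range(3):
            acc = 0.0
            for k in range(3):
                acc += A[j, k] * E1[t + 1, k] * b[t + 1, k]
            b[t, j] = acc / c[t + 1]
    post = np.empty((n, 3))
    loglik = 0.0
    for t in range(n):
        loglik += np.log(c[t])
        s = 0.0
        for k in range(3):
            post[t, k] = f[t, k] * b[t, k]
            s += post[t, k]
        for k in range(3):
            post[t, k] /= s
    return post, loglik


@njit
def chain_viterbi(E1, d, T, alpha):
    """Most probable dosage path for one individual; ties break toward lower dosage."""
    n = E1.shape[0]
    delta = np.empty((n, 3))
    psi = np.empty((n, 3), dtype=np.int64)
    pi = np.empty(3)
    pi[0] = (1.0 - alpha) ** 2
    pi[1] = 2.0 * alpha * (1.0 - alpha)
    pi[2] = alpha * alpha
    A = np.empty((3, 3))
    for k in range(3):
        delta[0, k] = np.log(pi[k] * E1[0, k])
        psi[0, k] = 0
    for t in range(1, n):
        _fill_diploid_trans(np.exp(-d[t - 1] * T), alpha, A)
        for k in range(3):
            best, arg = -np.inf, 0
            for j in range(3):
                v = delta[t - 1, j] + np.log(A[j, k])
                if v > best:  # strict: first (lowest-dosage) argmax retained
                    best, arg = v, j
            delta[t, k] = best + np.log(E1[t, k])
            psi[t, k] = arg
    path = np.empty(n, dtype=np.int64)
    best, arg = -np.inf, 0
    for k in range(3):
        if delta[n - 1, k] > best:
            best, arg = delta[n - 1, k], k
    path[n - 1] = arg
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
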