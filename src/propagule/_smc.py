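"""Numba kernels for the pairwise sequentially-Markovian-coalescent HMM.

Hidden states are discretized coalescence-time intervals for one
pseudo-diploid; emissions are binarized per-window heterozygosity; the
transition kernel follows the SMC recombination process: with probability
1 - exp(-2*rho*w*t) a recombination falls on the (two-branch) tree of height
t within a window span, the break point is uniform on (0, t), and the floating
lineage re-coalesces under the piecewise-constant rates lambda_j.

All rates are per generation, all times in generations.  ``bounds`` is the
array of K finite interval left edges (bounds[0] == 0); the K-th interval is
unbounded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=False)
def hmm_params(lam, bounds, mu2w, rho2w, gl_x, gl_w):
    """Build (pi, A, e1, m) from per-interval coalescence rates.

    pi: stationary distribution of the interval of the pair's TMRCA;
    e1: P(window heterozygous | state); A: window-to-window transitions;
    m: representative (conditional-mean) TMRCA per interval.
    """
    K = lam.shape[0]
    dt = np.empty(K)
    for j in range(K - 1):
        dt[j] = bounds[j + 1] - bounds[j]
    dt[K - 1] = np.inf

    eout = np.empty(K)
    pi = np.empty(K)
    m = np.empty(K)
    s = 1.0
    for j in range(K):
        if j == K - 1:
            eout[j] = 0.0
            m[j] = bounds[j] + 1.0 / lam[j]
        else:
            x = lam[j] * dt[j]
            eout[j] = np.exp(-x)
            if x < 1e-6:
                m[j] = bounds[j] + 0.5 * dt[j]
            else:
                m[j] = bounds[j] + 1.0 / lam[j] - dt[j] * eout[j] / (1.0 - eout[j])
        pi[j] = s * (1.0 - eout[j])
        s *= eout[j]

    # cumulative hazard at the finite left edges
    cum = np.empty(K)
    cum[0] = 0.0
    for j in range(1, K):
        cum[j] = cum[j - 1] + lam[j - 1] * (bounds[j] - bounds[j - 1])

    e1 = np.empty(K)
    pr = np.empty(K)
    for j in range(K):
        e1[j] = -np.expm1(-mu2w * m[j])
        pr[j] = -np.expm1(-rho2w * m[j])

    A = np.zeros((K, K))
    nq = gl_x.shape[0]
    for j in range(K):
        t = m[j]
        for q in range(nq):
            u = 0.5 * t * (gl_x[q] + 1.0)
            w = 0.5 * gl_w[q]  # weights normalized: sum(0.5*gl_w) == 1
            # hazard at u
            iu = K - 1
            for i in range(K - 1):
                if u < bounds[i + 1]:
                    iu = i
                    break
            lam_u = cum[iu] + lam[iu] * (u - bounds[iu])
            # survival from u to each interval edge
            prev = 1.0  # exp(-(Lambda(max(b_0,u)) - Lambda(u))) with b_0=0 -> max=u
            for k in range(K):
                if k == K - 1:
                    nxt = 0.0
                else:
                    edge = bounds[k + 1]
                    if edge <= u:
                        nxt = 1.0
                    else:
                        ie = K - 1
                        for i in range(K - 1):
                            if edge < bounds[i + 1]:
                                ie = i
                                break
                        lam_e = cum[ie] + lam[ie] * (edge - bounds[ie])
                        nxt = np.exp(-(lam_e - lam_u))
                A[j, k] += w * (prev - nxt)
                prev = nxt
        for k in range(K):
            A[j, k] = pr[j] * A[j, k]
        A[j, j] += 1.0 - pr[j]
    return pi, A, e1, m


@njit(cache=False)
def forward_backward(pi, A, e1, obs):
    """Scaled forward-backward over one observation chain.

    Returns (loglik, c0, C, n1, n0): initial-state posteriors, expected
    transition counts, and expected het/hom emission counts per state.
    """
    K = pi.shape[0]
    T = obs.shape[0]
    e0 = 1.0 - e1

    alpha = np.empty((T, K))
    scale = np.empty(T)
    # init
    s = 0.0
    for j in range(K):
        em = e1[j] if obs[0] == 1 else e0[j]
        alpha[0, j] = pi[j] * em
        s += alpha[0, j]
    if s < _TINY:
        s = _TINY
    scale[0] = s
    for j in range(K):
        alpha[0, j] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            em = e1[k] if obs[t] == 1 else e0[k]
            alpha[t, k] = acc * em
            s += alpha[t, k]
        if s < _TINY:
            s = _TINY
        scale[t] = s
        for k in range(K):
            alpha[t, k] /= s

    c0 = np.zeros(K)
    C = np.zeros((K, K))
    n1 = np.zeros(K)
    n0 = np.zeros(K)
    beta = np.ones(K)
    beta_next = np.empty(K)
    # t = T-1 contribution
    for j in range(K):
        g = alpha[T - 1, j] * beta[j]
        if obs[T - 1] == 1:
            n1[j] += g
        else:
            n0[j] += g
    for t in range(T - 2, -1, -1):
        # emission-weighted beta at t+1
        for k in range(K):
            em = e1[k] if obs[t + 1] == 1 else e0[k]
            beta_next[k] = em * beta[k] / scale[t + 1]
        for j in range(K):
            acc = 0.0
            for k in range(K):
                x = alpha[t, j] * A[j, k] * beta_next[k]
                C[j, k] += x
                acc += A[j, k] * beta_next[k]
            beta[j] = acc
        gsum = 0.0
        for j in range(K):
            g = alpha[t, j] * beta[j]
            gsum += g
            if obs[t] == 1:
                n1[j] += g
            else:
                n0[j] += g
        # guard drift in scaled recursion
        if gsum > 0:
            for j in range(K):
                beta[j] /= gsum
    for j in range(K):
        c0[j] = alpha[0, j] * beta[j]

    ll = 0.0
    for t in range(T):
        ll += np.log(scale[t])
    return ll, c0, C, n1, n0


@njit(cache=False)
def neg_q(loglam, bounds, mu2w, rho2w, gl_x, gl_w, c0, C, n1, n0):
    """Negative expected complete-data log-likelihood (the EM Q-function)."""
    K = loglam.shape[0]
    lam = np.empty(K)
    for j in range(K):
        lam[j] = np.exp(loglam[j])
    pi, A, e1, _ = hmm_params(lam, bounds, mu2w, rho2w, gl_x, gl_w)
    q = 0.0
    for j in range(K):
        if c0[j] > 0:
            p = pi[j]
            if p < _TINY:
                p = _TINY
            q += c0[j] * np.log(p)
        if n1[j] > 0:
            p = e1[j]
            if p < _TINY:
                p = _TINY
            q += n1[j] * np.log(p)
        if n0[j] > 0:
            p = 1.0 - e1[j]
            if p < _TINY:
                p = _TINY
            q += n0[j] * np.log(p)
        for k in range(K):
            if C[j, k] > 0:
                p = A[j, k]
                if p < _TINY:
                    p = _TINY
                q += C[j, k] * np.log(p)
    return -q
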