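"""Numba inner loops for chain simulation, forward-backward and Viterbi.

All kernels take 0-based integer state codes and plain float64 arrays.
Public modules convert to/from the 1-based labels used in trace files.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_chain(cum_rows, start, u):
    """Sample a Markov chain path from per-row CDFs.

    cum_rows : (n_states, n_states) row-wise cumulative sums of the
        transition matrix.  start : initial state code.  u : uniform
    draws, one per transition; the returned path has len(u)+1 entries.
    """
    n = u.shape[0]
    path = np.empty(n + 1, dtype=np.int64)
    path[0] = start
    s = start
    for t in range(n):
        r = u[t]
        row = cum_rows[s]
        k = 0
        while row[k] < r:
            k += 1
        s = k
        path[t + 1] = s
    return path


@njit(cache=True)
def simulate_modulated_chain(cum_b, x, start, u):
    """Sample the observable chain o(t+1) ~ B^(x(t))[o(t), :].

    cum_b : (K, N, N) row CDFs of each B matrix; x : (T-1,) internal
    codes; returns o of length T.
    """
    n = x.shape[0]
    o = np.empty(n + 1, dtype=np.int64)
    o[0] = start
    s = start
    for t in range(n):
        r = u[t]
        row = cum_b[x[t], s]
        k = 0
        while row[k] < r:
            k += 1
        s = k
        o[t + 1] = s
    return o


@njit(cache=True)
def forward_backward(e, A, pi):
    """Scaled forward-backward for a (possibly sub-stochastic) chain.

    e : (S, K) per-step evidence, A : (K, K), pi : (K,).  Returns
    (gamma, xi, logZ): single-frame marginals (S, K), pairwise
    marginals (S-1, K, K) and the log normalizer (log of total path
    weight).  Scaling per step keeps everything in float range for any S.
    """
    S, K = e.shape
    alpha = np.empty((S, K))
    c = np.empty(S)
    tot = 0.0
    for j in range(K):
        v = pi[j] * e[0, j]
        alpha[0, j] = v
        tot += v
    c[0] = tot
    for j in range(K):
        alpha[0, j] /= tot
    for t in range(1, S):
        tot = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * A[i, j]
            v = acc * e[t, j]
            alpha[t, j] = v
            tot += v
        c[t] = tot
        for j in range(K):
            alpha[t, j] /= tot

    beta = np.empty((S, K))
    for j in range(K):
        beta[S - 1, j] = 1.0
    gamma = np.empty((S, K))
    xi = np.empty((S - 1, K, K))
    for t in range(S - 2, -1, -1):
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += A[i, j] * e[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]
    logZ = 0.0
    for t in range(S):
        logZ += np.log(c[t])
        tot = 0.0
        for j in range(K):
            v = alpha[t, j] * beta[t, j]
            gamma[t, j] = v
            tot += v
        for j in range(K):
            gamma[t, j] /= tot
    for t in range(S - 1):
        tot = 0.0
        for i in range(K):
            for j in range(K):
                v = alpha[t, i] * A[i, j] * e[t + 1, j] * beta[t + 1, j]
                xi[t, i, j] = v
                tot += v
        for i in range(K):
            for j in range(K):
                xi[t, i, j] /= tot
    return gamma, xi, logZ


@njit(cache=True)
def accumulate_b_counts(gamma, o, K, N):
    """Sum responsibilities into (K, N, N) observable-transition counts."""
    S = gamma.shape[0]
    counts = np.zeros((K, N, N))
    for t in range(S):
        a = o[t]
        b = o[t + 1]
        for mu in range(K):
            counts[mu, a, b] += gamma[t, mu]
    return counts


@njit(cache=True)
def viterbi(log_e, log_A, log_pi):
    """Most probable state path; ties broken toward the lower index."""
    S, K = log_e.shape
    delta = np.empty((S, K))
    psi = np.zeros((S, K), dtype=np.int64)
    for j in range(K):
        delta[0, j] = log_pi[j] + log_e[0, j]
    for t in range(1, S):
        for j in range(K):
            best = delta[t - 1, 0] + log_A[0, j]
            arg = 0
            for i in range(1, K):
                v = delta[t - 1, i] + log_A[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + log_e[t, j]
            psi[t, j] = arg
    path = np.empty(S, dtype=np.int64)
    best = delta[S - 1, 0]
    arg = 0
    for j in range(1, K):
        if delta[S - 1, j] > best:
            best = delta[S - 1, j]
            arg = j
    path[S - 1] = arg
    for t in range(S - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
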