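"""Variational-Bayes inference for the double-chain Markov model.

The model couples a slow homogeneous hidden chain x(1..T-1) over K
internal states (initial distribution pi, transition matrix A) to the
observed discrete chain o(1..T): the transition o(t) -> o(t+1) is
governed by the N x N matrix B^(x(t)).  The complete-data likelihood is

    P(o, x | pi, A, B) = pi_{x(1)} * prod_t A[x(t), x(t+1)]
                                   * prod_t B^(x(t))[o(t), o(t+1)].

With independent Dirichlet priors on pi and on every row of A and of
each B^(mu), the variational posterior factorizes as q(x) q(pi, A, B)
and both factors have closed-form coordinate updates:

* VB-M: each Dirichlet row's pseudocounts are the prior plus the
  expected transition counts under q(x);
* VB-E: forward-backward over x under the "geometric-mean" parameters
  exp(E_q[log theta]) (sub-stochastic, as usual in VB treatments of
  hidden Markov chains).

The evidence lower bound after an E-step is
    F = log Z~  -  sum of Dirichlet KL(q || prior) terms,
where log Z~ is the normalizer of the scaled forward pass under the
geometric-mean parameters.  F increases monotonically over iterations.
The reported F additionally carries the conventional +log K! labeling-
degeneracy term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from . import _kernels

__all__ = [
    "DCMMModel",
    "Priors",
    "VBResult",
    "emission_matrix",
    "forward_backward",
    "vb_fit",
    "viterbi_internal",
    "dirichlet_kl",
]


@dataclass(frozen=True)
class DCMMModel:
    """Point estimate (pi, A, B) of the double-chain parameterization."""

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        K = len(pi)
        if A.shape != (K, K) or B.shape[0] != K or B.shape[1] != B.shape[2]:
            raise ValueError("inconsistent shapes for (pi, A, B)")
        for arr, name in ((pi[None, :], "pi"), (A, "A"), (B.reshape(-1, B.shape[2]), "B")):
            if np.any(arr < 0) or not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"rows of {name} must be distributions")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def N(self) -> int:
        return self.B.shape[1]


@dataclass(frozen=True)
class Priors:
    """Dirichlet pseudocounts for the model parameters.

    Rows of A get (u_ad on the diagonal, u_a off it); a large u_ad/u_a
    ratio encodes the required persistence of the internal state
    (tau_int >> dt) and is the one prior a user normally tunes.  Rows of
    B^(mu) get (u_bd, u_b); results are robust over wide ranges of
    these.  pi gets a symmetric Dirichlet(u_pi).
    """

    u_pi: float = 1.0
    u_a: float = 1.0
    u_ad: float = 100.0
    u_b: float = 1.0
    u_bd: float = 1.0

    def __post_init__(self):
        if min(self.u_pi, self.u_a, self.u_ad, self.u_b, self.u_bd) <= 0:
            raise ValueError("all prior pseudocounts must be positive")

    def pi_row(self, K):
        return np.full(K, self.u_pi)

    def a_matrix(self, K):
        M = np.full((K, K), self.u_a)
        np.fill_diagonal(M, self.u_ad)
        return M

    def b_matrices(self, K, N):
        M = np.full((K, N, N), self.u_b)
        for mu in range(K):
            np.fill_diagonal(M[mu], self.u_bd)
        return M


@dataclass
class VBResult:
    """Converged variational fit for one K."""

    model: DCMMModel
    F: float
    w_pi: np.ndarray
    w_A: np.ndarray
    w_B: np.ndarray
    responsibilities: np.ndarray
    F_history: np.ndarray
    converged: bool
    n_iter: int

    @property
    def K(self) -> int:
        return self.model.K


def emission_matrix(o, B):
    """Per-step evidence table: entry (t, mu) = B^(mu)[o(t), o(t+1)].

    o holds 1-based observable labels of length T; the table has shape
    (T-1, K).
    """
    B = np.asarray(B, dtype=float)
    o = np.asarray(o)
    N = B.shape[1]
    if o.min() < 1 or o.max() > N:
        raise ValueError(f"observable labels must lie in 1..{N}")
    oi = o - 1
    return B[:, oi[:-1], oi[1:]].T.copy()


def forward_backward(emissions, A_eff, pi_eff):
    """Exact chain marginals given per-step evidence.

    A_eff and pi_eff may be sub-stochastic (VB geometric-mean
    parameters).  Returns (gamma, xi, logZ): single-frame marginals
    (S, K), pairwise marginals (S-1, K, K), and the log of the total
    path weight.  Scaled recursions; no underflow for any S.
    """
    e = np.ascontiguousarray(emissions, dtype=float)
    A_eff = np.ascontiguousarray(A_eff, dtype=float)
    pi_eff = np.ascontiguousarray(pi_eff, dtype=float)
    if e.ndim != 2:
        raise ValueError("emissions must be (S, K)")
    bad = np.flatnonzero(e.sum(axis=1) == 0)
    if bad.size:
        raise FloatingPointError(
            f"all-zero emission column at step {bad[0]}: the observed transition "
            "has probability 0 under every internal state"
        )
    return _kernels.forward_backward(e, A_eff, pi_eff)


def dirichlet_kl(w, u):
    """KL(Dir(w) || Dir(u)) summed over the rows of w and u."""
    w = np.atleast_2d(np.asarray(w, dtype=float))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    w0 = w.sum(axis=1)
    u0 = u.sum(axis=1)
    kl = (
        gammaln(w0)
        - gammaln(u0)
        - np.sum(gammaln(w) - gammaln(u), axis=1)
        + np.sum((w - u) * (digamma(w) - digamma(w0)[:, None]), axis=1)
    )
    return float(kl.sum())


def _geometric_mean_params(w):
    """exp(E[log theta]) for Dirichlet rows w (sub-stochastic)."""
    w = np.asarray(w, dtype=float)
    return np.exp(digamma(w) - digamma(w.sum(axis=-1, keepdims=True)))


def _elbo(logZ, w_pi, w_A, w_B, priors: Priors):
    K, N = w_B.shape[0], w_B.shape[1]
    kl = dirichlet_kl(w_pi, priors.pi_row(K))
    kl += dirichlet_kl(w_A, priors.a_matrix(K))
    kl += dirichlet_kl(w_B.reshape(-1, N), priors.b_matrices(K, N).reshape(-1, N))
    return logZ - kl


def _init_responsibilities(S, K, rng):
    """Contiguous block assignment (random label order) plus Dirichlet jitter."""
    labels = rng.permutation(K)
    edges = np.linspace(0, S, K + 1).astype(int)
    gamma = rng.dirichlet(np.ones(K), size=S) * 0.25
    for b in range(K):
        gamma[edges[b] : edges[b + 1], labels[b]] += 0.75
    return gamma / gamma.sum(axis=1, keepdims=True)


def _m_step(gamma, xi_sum, oi, K, N, priors: Priors):
    w_pi = priors.pi_row(K) + gamma[0]
    w_A = priors.a_matrix(K) + xi_sum
    w_B = priors.b_matrices(K, N) + _kernels.accumulate_b_counts(
        np.ascontiguousarray(gamma), oi, K, N
    )
    return w_pi, w_A, w_B


def vb_fit(
    o,
    K,
    priors: Priors | None = None,
    max_iter=1000,
    tol=1e-6,
    n_restarts=10,
    seed=None,
    N=None,
) -> VBResult:
    """Fit the double-chain model with K internal states by VB-EM.

    Runs `n_restarts` initializations (contiguous-block responsibilities
    with Dirichlet jitter) and returns the restart with the highest
    converged evidence bound F.  F includes the +log K! labeling-
    degeneracy term.  Non-convergence within `max_iter` flags the
    result; it is not an error.
    """
    o = np.asarray(o)
    if len(o) < 3:
        raise ValueError("need at least 3 frames")
    if K < 1:
        raise ValueError("K must be at least 1")
    priors = priors or Priors()
    N = int(N if N is not None else o.max())
    if o.min() < 1 or o.max() > N:
        raise ValueError(f"observable labels must lie in 1..{N}")
    oi = np.ascontiguousarray(o - 1, dtype=np.int64)
    S = len(o) - 1
    root = np.random.SeedSequence(seed)
    best = None
    for ss in root.spawn(max(n_restarts, 1)):
        rng = np.random.default_rng(ss)
        gamma = _init_responsibilities(S, K, rng)
        xi_sum = gamma[:-1].T @ gamma[1:]
        w_pi, w_A, w_B = _m_step(gamma, xi_sum, oi, K, N, priors)
        history = []
        converged = False
        for it in range(max_iter):
            pi_eff = _geometric_mean_params(w_pi)
            A_eff = _geometric_mean_params(w_A)
            B_eff = _geometric_mean_params(w_B)
            e = emission_matrix(o, B_eff)
            gamma, xi, logZ = forward_backward(e, A_eff, pi_eff)
            F = _elbo(logZ, w_pi, w_A, w_B, priors)
            history.append(F)
            if len(history) > 1 and abs(history[-1] - history[-2]) < tol:
                converged = True
                break
            w_pi, w_A, w_B = _m_step(gamma, xi.sum(axis=0), oi, K, N, priors)
        F_final = history[-1] + math.lgamma(K + 1)
        if best is None or F_final > best.F:
            model = DCMMModel(
                pi=w_pi / w_pi.sum(),
                A=w_A / w_A.sum(axis=1, keepdims=True),
                B=w_B / w_B.sum(axis=2, keepdims=True),
            )
            best = VBResult(
                model=model,
                F=F_final,
                w_pi=w_pi,
                w_A=w_A,
                w_B=w_B,
                responsibilities=gamma,
                F_history=np.asarray(history),
                converged=converged,
                n_iter=len(history),
            )
    return best


def viterbi_internal(o, model: DCMMModel):
    """Most probable internal-state path under a fitted model.

    Returns 1-based labels of length T-1; ties break toward the lower
    state index.
    """
    o = np.asarray(o)
    with np.errstate(divide="ignore"):
        log_e = np.log(emission_matrix(o, model.B))
        log_A = np.log(model.A)
        log_pi = np.log(model.pi)
    path, _ = _kernels.viterbi(
        np.ascontiguousarray(log_e),
        np.ascontiguousarray(log_A),
        np.ascontiguousarray(log_pi),
    )
    return path + 1
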