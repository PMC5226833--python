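"""Accuracy and reliability metrics for decoded internal-state paths.

overlap_chi scores a decoded hidden path against ground truth; d_conf /
d_int / d_tot quantify, from rates alone, how separable the internal
states are (and hence how trustworthy a decoding is on real data where
no ground truth exists); dwell_cv is the coefficient-of-variation
diagnostic of homogeneous Markovianity (CV ~ 1 for geometric dwells,
CV > 1 signals a mixture of kinetic regimes).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ReliabilityScores",
    "match_labels",
    "overlap_chi",
    "d_conf",
    "d_int",
    "d_tot",
    "reliability_scores",
    "dwell_cv",
    "dwell_lengths",
]

#: sentinel reported when an internal state has zero exit probability
ABSORBING_CAP = 64.0


@dataclass(frozen=True)
class ReliabilityScores:
    """Separability scores, all in bits.

    D_conf : mean |log2| ratio of intra-basin rates across pairs of
        internal states (how different the kinetics are).
    D_int : mean |log2| ratio of intra-basin rate to total inter-basin
        exit probability (how well separated the two time scales are).
    D_tot = D_conf + alpha * D_int with the empirical weight alpha.
    """

    D_conf: float
    D_int: float
    alpha: float = 0.8

    @property
    def D_tot(self) -> float:
        return self.D_conf + self.alpha * self.D_int


def _offdiag_rates(B):
    """(K, N*(N-1)) off-diagonal per-frame rates in fixed (a, b) lex order."""
    B = np.asarray(B, dtype=float)
    K, N, _ = B.shape
    mask = ~np.eye(N, dtype=bool)
    return B[:, mask].reshape(K, N * (N - 1))


def match_labels(B_est, B_true, x_est=None, x_true=None):
    """Permutation aligning estimated internal states with true ones.

    Returns `perm` with perm[i] = j meaning estimated state i+1
    corresponds to true state j+1; minimizes the summed elementwise L1
    distance between matched B matrices, exhaustively over K!
    permutations (K <= 6).  If the two lists have different K, falls
    back to maximizing path co-occupancy (requires x_est and x_true).
    """
    B_est = np.asarray(B_est, dtype=float)
    B_true = np.asarray(B_true, dtype=float)
    K_est, K_true = B_est.shape[0], B_true.shape[0]
    if K_est != K_true:
        if x_est is None or x_true is None:
            raise ValueError(
                "K mismatch: provide x_est and x_true to match states on path overlap"
            )
        cont = np.zeros((K_est, K_true))
        for i, j in zip(np.asarray(x_est) - 1, np.asarray(x_true) - 1):
            cont[i, j] += 1
        rows, cols = linear_sum_assignment(-cont)
        perm = np.arange(max(K_est, K_true))
        perm[rows] = cols
        return tuple(int(p) for p in perm[:K_est])
    if K_est > 6:
        raise ValueError("exhaustive matching supported for K <= 6")
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(K_true)):
        cost = sum(np.abs(B_est[i] - B_true[j]).sum() for i, j in enumerate(perm))
        if cost < best_cost:
            best, best_cost = perm, cost
    return best


def overlap_chi(x_true, x_pred, permutation=None):
    """Fraction of frames where the (relabeled) decoded path equals truth.

    chi = (1/(T-1)) sum_t delta(x_true(t), perm(x_pred(t))).
    """
    x_true = np.asarray(x_true)
    x_pred = np.asarray(x_pred)
    if x_true.shape != x_pred.shape:
        raise ValueError("paths must have equal length")
    if permutation is not None:
        perm = np.asarray(permutation)
        x_pred = perm[x_pred - 1] + 1
    return float(np.mean(x_true == x_pred))


def d_conf(B):
    """Dissimilarity of intra-basin rates across internal states (bits).

    Average over unordered internal-state pairs (mu > nu) and ordered
    observable pairs (a != b) of |log2(k_ab^(mu) / k_ab^(nu))|.
    Depends only on rate ratios, so per-frame probabilities k*dt and
    physical rates k give the identical score.
    """
    rates = _offdiag_rates(B)
    K = rates.shape[0]
    if K < 2:
        return 0.0
    if np.any(rates <= 0):
        raise ValueError(
            "zero off-diagonal rate; estimate rates with pseudocounts before scoring"
        )
    total = 0.0
    for mu, nu in itertools.combinations(range(K), 2):
        total += np.mean(np.abs(np.log2(rates[mu] / rates[nu])))
    return float(total / (K * (K - 1) / 2))


def d_int(B, A):
    """Time-scale separation between intra- and inter-basin kinetics (bits).

    For each internal state mu, the mean over observable pairs of
    |log2(k_ab^(mu) / sum_{nu != mu} gamma^(mu)->(nu))|, averaged over
    states.  An absorbing internal state (zero exit probability) is
    reported at the ABSORBING_CAP sentinel with a warning.
    """
    rates = _offdiag_rates(B)
    A = np.asarray(A, dtype=float)
    K = rates.shape[0]
    if np.any(rates <= 0):
        raise ValueError(
            "zero off-diagonal rate; estimate rates with pseudocounts before scoring"
        )
    per_state = np.empty(K)
    for mu in range(K):
        exit_p = A[mu].sum() - A[mu, mu]
        if exit_p <= 0:
            warnings.warn(
                f"internal state {mu + 1} is absorbing; D_int capped at {ABSORBING_CAP}",
                RuntimeWarning,
                stacklevel=2,
            )
            per_state[mu] = ABSORBING_CAP
        else:
            per_state[mu] = min(
                np.mean(np.abs(np.log2(rates[mu] / exit_p))), ABSORBING_CAP
            )
    return float(np.mean(per_state))


def d_tot(B, A, alpha=0.8):
    """Combined separability score D_conf + alpha * D_int."""
    return reliability_scores(B, A, alpha=alpha).D_tot


def reliability_scores(B, A, alpha=0.8) -> ReliabilityScores:
    return ReliabilityScores(D_conf=d_conf(B), D_int=d_int(B, A), alpha=alpha)


def dwell_lengths(labels, state, drop_truncated=True):
    """Lengths of contiguous runs of `state` in a label sequence.

    The first and last runs of the sequence are censored (their true
    dwell extends beyond the record) and are dropped by default.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.array([], dtype=int)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    runs = [(s, e) for s, e in zip(starts, ends) if labels[s] == state]
    if drop_truncated:
        runs = [(s, e) for s, e in runs if s != 0 and e != len(labels)]
    return np.array([e - s for s, e in runs], dtype=int)


def dwell_cv(labels, state, window=None):
    """CV of dwell durations: sqrt(<tau^2> - <tau>^2) / <tau>.

    Computed over completed dwells only.  With `window` = m, returns an
    array of the CV over sliding blocks of m consecutive dwells (the
    windowed variant used to localize heterogeneity along a trace).
    Returns NaN when fewer than 2 dwells (or m dwells) are available.
    """
    tau = dwell_lengths(labels, state).astype(float)

    def _cv(t):
        if len(t) < 2:
            return np.nan
        m = t.mean()
        var = np.mean(t**2) - m**2
        return float(np.sqrt(max(var, 0.0)) / m)

    if window is None:
        return _cv(tau)
    if window < 2:
        raise ValueError("window must be at least 2 dwells")
    if len(tau) < window:
        return np.array([np.nan])
    return np.array([_cv(tau[i : i + window]) for i in range(len(tau) - window + 1)])
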