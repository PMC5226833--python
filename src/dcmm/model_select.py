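"""Model selection over K and decomposition into homogeneous components.

The number of internal states is chosen by sweeping K, fitting the
variational model at each K, and maximizing the modified evidence

    G(K) = F(K) - log((K - K_obs)!),

where K_obs is the number of internal states actually visited by the
decoded path.  F conventionally carries a +log K! labeling-degeneracy
term, but when only K_obs of the K labels are realized the true
degeneracy is K! / (K - K_obs)!; G applies that correction, which
removes the plateau F(K) otherwise shows past the true K.

A decoded trace is then cut at the internal-state switches into
"components" — maximal constant-x intervals, each a homogeneous Markov
chain with its own empirical transition-rate estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .vbdcmm import DCMMModel, Priors, VBResult, vb_fit, viterbi_internal

__all__ = [
    "ModelScan",
    "Component",
    "count_observed_states",
    "modified_evidence",
    "select_model",
    "decompose",
]


@dataclass
class Component:
    """One homogeneous interval of a decoded trace.

    interval is half-open [t_start, t_end) in 1-based frame indices of
    the internal path x (x is defined on t = 1..T-1).  rates is the
    N x N per-frame transition-probability estimate from the interval's
    observable transitions with +0.5 pseudocount per cell; entries
    k_ab * dt for a != b are the intra-basin rates used downstream.
    """

    trace_id: str
    t_start: int
    t_end: int
    label: int
    rates: np.ndarray
    counts: np.ndarray
    n_transitions: int
    low_confidence: bool = False

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


@dataclass
class ModelScan:
    """Result of sweeping K = 1..K_max on one trace."""

    K_values: list
    F: dict
    K_obs: dict
    G: dict
    K_star: int
    results: dict
    paths: dict

    @property
    def best(self) -> VBResult:
        return self.results[self.K_star]

    @property
    def best_path(self) -> np.ndarray:
        return self.paths[self.K_star]


def count_observed_states(x) -> int:
    """Number of distinct internal-state labels in a decoded path."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("empty path")
    return int(len(np.unique(x)))


def modified_evidence(F, K, K_obs) -> float:
    """G = F - log((K - K_obs)!); the label-degeneracy-corrected evidence."""
    if K_obs > K:
        raise ValueError("K_obs cannot exceed K")
    return float(F - math.lgamma(K - K_obs + 1))


def select_model(
    o,
    K_max=5,
    priors: Priors | None = None,
    seed=None,
    n_restarts=10,
    max_iter=1000,
    tol=1e-6,
    N=None,
) -> ModelScan:
    """Fit K = 1..K_max and pick K* = argmax G(K) (ties -> smaller K)."""
    if K_max < 1:
        raise ValueError("K_max must be at least 1")
    root = np.random.SeedSequence(seed)
    K_values = list(range(1, K_max + 1))
    F, K_obs, G, results, paths = {}, {}, {}, {}, {}
    for K, ss in zip(K_values, root.spawn(len(K_values))):
        res = vb_fit(
            o,
            K,
            priors=priors,
            n_restarts=n_restarts,
            max_iter=max_iter,
            tol=tol,
            seed=ss.generate_state(1)[0] % (2**31),
            N=N,
        )
        x = viterbi_internal(o, res.model)
        results[K] = res
        paths[K] = x
        F[K] = res.F
        K_obs[K] = count_observed_states(x)
        G[K] = modified_evidence(res.F, K, K_obs[K])
    K_star = max(K_values, key=lambda K: (G[K], -K))
    return ModelScan(
        K_values=K_values, F=F, K_obs=K_obs, G=G, K_star=K_star,
        results=results, paths=paths,
    )


def _transition_counts(o, t0, t1, N):
    """Counts of o(t) -> o(t+1) for t in [t0, t1), 0-based frame indices."""
    counts = np.zeros((N, N))
    a = o[t0:t1] - 1
    b = o[t0 + 1 : t1 + 1] - 1
    np.add.at(counts, (a, b), 1.0)
    return counts


def decompose(o, x, min_dwell=10, trace_id="trace", N=None, pseudocount=0.5):
    """Cut a decoded trace at internal-state switches into Components.

    Maximal constant-label runs of x become components tiling the path;
    per-component rates are (count + pseudocount) / row total.
    Components shorter than `min_dwell` frames are flagged
    low-confidence but kept.
    """
    o = np.asarray(o)
    x = np.asarray(x)
    if len(x) != len(o) - 1:
        raise ValueError("x must have length len(o) - 1")
    N = int(N if N is not None else o.max())
    change = np.flatnonzero(x[1:] != x[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(x)]))
    components = []
    for s, e in zip(starts, ends):
        counts = _transition_counts(o, s, e, N)
        reg = counts + pseudocount
        rates = reg / reg.sum(axis=1, keepdims=True)
        components.append(
            Component(
                trace_id=trace_id,
                t_start=int(s) + 1,
                t_end=int(e) + 1,
                label=int(x[s]),
                rates=rates,
                counts=counts,
                n_transitions=int(counts.sum() - np.trace(counts)),
                low_confidence=bool(e - s < min_dwell),
            )
        )
    return components
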