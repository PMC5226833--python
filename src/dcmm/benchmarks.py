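"""Canonical validation workflows on synthetic data.

These functions bundle the standard benchmark runs used to validate
the decoder: simulate traces under a stated condition, push them
through the noise-filtering and variational-decoding stages, and score
the result against the known ground truth.  Problem sizes (number of
traces, restarts) are arguments so callers can trade precision for
runtime.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from . import cluster as cluster_mod
from .hmm_filter import fit_gaussian_hmm, viterbi_discretize
from .metrics import match_labels, overlap_chi
from .model_select import decompose
from .simulate import multistate_config, simulate_trace, two_state_config
from .vbdcmm import vb_fit, viterbi_internal

__all__ = [
    "decode_two_state_trace",
    "two_state_overlap",
    "two_state_k_selection",
    "clustering_ensemble",
    "dwell_cv_benchmark",
]


def decode_two_state_trace(gt, seed, n_restarts=5):
    """Filter -> fit at K=2 -> Viterbi -> label-matched overlap chi."""
    hmm = fit_gaussian_hmm(gt.o_n, 2, seed=seed)
    o = viterbi_discretize(gt.o_n, hmm)
    res = vb_fit(o, 2, n_restarts=n_restarts, seed=seed)
    x = viterbi_internal(o, res.model)
    perm = match_labels(res.model.B, gt.config.B)
    return overlap_chi(gt.x, x, perm), res


def two_state_overlap(k2, n_traces, seed, n_restarts=5, T=8801, gamma=0.001):
    """Mean decoded-path overlap for a two-internal-state condition.

    Simulates `n_traces` with state-1 rates 0.05/0.05 and state-2 rates
    `k2`, runs the full filter/decode pipeline at K=2, and returns the
    per-trace chi values.
    """
    cfg = two_state_config(k2=k2, gamma=gamma, T=T)
    root = np.random.SeedSequence(seed)
    chis = []
    for i, ss in enumerate(root.spawn(n_traces)):
        gt = simulate_trace(cfg, rng=np.random.default_rng(ss))
        chi, _ = decode_two_state_trace(
            gt, seed=int(ss.generate_state(1)[0] % 2**31), n_restarts=n_restarts
        )
        chis.append(chi)
    return np.asarray(chis)


def two_state_k_selection(n_traces, seed, n_restarts=10, K_values=(1, 2, 3), k2=(0.00625, 0.025)):
    """Per-trace argmax of the evidence bound F over candidate K.

    Returns the list of best-K values, one per simulated benchmark
    trace; the modal value identifies the recovered number of internal
    states for the condition.
    """
    cfg = two_state_config(k2=k2)
    root = np.random.SeedSequence(seed)
    best = []
    for ss in root.spawn(n_traces):
        gt = simulate_trace(cfg, rng=np.random.default_rng(ss))
        sub_seed = int(ss.generate_state(1)[0] % 2**31)
        hmm = fit_gaussian_hmm(gt.o_n, 2, seed=sub_seed)
        o = viterbi_discretize(gt.o_n, hmm)
        F = {
            K: vb_fit(o, K, n_restarts=n_restarts, seed=sub_seed + K).F
            for K in K_values
        }
        best.append(max(F, key=F.get))
    return best


def _majority_label(x, t_start, t_end):
    """Dominant true internal label over a half-open 1-based interval of x."""
    seg = x[t_start - 1 : t_end - 1]
    vals, counts = np.unique(seg, return_counts=True)
    return int(vals[np.argmax(counts)])


def clustering_ensemble(
    seed,
    n_traces=30,
    max_traces=80,
    min_arrows_per_path=12,
    min_dwell=500,
    n_restarts=3,
    n_init=200,
    K_range=range(2, 15, 2),
    config=None,
):
    """Ensemble clustering benchmark: K=4 internal x N=4 observable states.

    Simulates and decodes traces (at the generating K) one at a time
    until every one of the K(K-1) = 12 directed inter-basin paths has
    at least `min_arrows_per_path` decoded arrows — path identity
    checked against the ground-truth internal path, since decoding and
    the minimum-dwell filter lose some transitions.  The floor sits
    slightly above the min-cluster-size rule of 10 to absorb arrows
    that k-means trades between neighboring classes.  Components
    shorter than `min_dwell` frames (too few observable transitions to
    pin down all N(N-1) rates) are dropped before arrow construction.
    Returns (scan, arrows, n_traces_used).
    """
    cfg = config or multistate_config()
    K_true = cfg.K
    root = np.random.SeedSequence(seed)
    comps_by_trace = {}
    type_counts = Counter()
    n_used = 0
    for i, ss in enumerate(root.spawn(max_traces)):
        gt = simulate_trace(cfg, rng=np.random.default_rng(ss))
        sub_seed = int(ss.generate_state(1)[0] % 2**31)
        hmm = fit_gaussian_hmm(gt.o_n, cfg.N, seed=sub_seed)
        o = viterbi_discretize(gt.o_n, hmm)
        res = vb_fit(o, K_true, n_restarts=n_restarts, seed=sub_seed, N=cfg.N)
        x = viterbi_internal(o, res.model)
        comps = decompose(o, x, min_dwell=min_dwell, trace_id=f"t{i}", N=cfg.N)
        kept = [c for c in comps if not c.low_confidence]
        comps_by_trace[f"t{i}"] = kept
        for a, b in zip(kept, kept[1:]):
            if a.label != b.label and a.t_end == b.t_start:
                mu = _majority_label(gt.x, a.t_start, a.t_end)
                nu = _majority_label(gt.x, b.t_start, b.t_end)
                if mu != nu:
                    type_counts[(mu, nu)] += 1
        n_used = i + 1
        enough = len(type_counts) == K_true * (K_true - 1) and min(
            type_counts.values()
        ) >= min_arrows_per_path
        if n_used >= n_traces and enough:
            break
    arrows = cluster_mod.build_arrows(comps_by_trace)
    scan = cluster_mod.select_clusters(
        arrows,
        K_range=[K for K in K_range if K <= len(arrows)],
        min_cluster_size=10,
        n_init=n_init,
        seed=seed,
    )
    return scan, arrows, n_used


def dwell_cv_benchmark(seed, p=0.05, min_dwells=1000):
    """CV of dwell times in a homogeneous two-state chain.

    Simulates a single-regime observable chain with per-frame switch
    probability `p` each way, long enough for at least `min_dwells`
    completed dwells, and returns the pooled CV over both states.
    """
    from .metrics import dwell_lengths
    from .simulate import simulate_observable

    T = int(np.ceil(min_dwells / p * 1.3)) + 2
    B = np.array([[[1 - p, p], [p, 1 - p]]])
    o = simulate_observable(np.ones(T - 1, dtype=int), B, seed=seed)
    tau = np.concatenate([dwell_lengths(o, 1), dwell_lengths(o, 2)]).astype(float)
    assert len(tau) >= min_dwells
    m = tau.mean()
    return float(np.sqrt(np.mean(tau**2) - m**2) / m), len(tau)
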