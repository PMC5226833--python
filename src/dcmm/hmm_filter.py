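"""Idealization of noisy FRET signals with a Gaussian-emission HMM.

This is the pre-processing stage: a real-valued trace o_n is converted
into the discrete observable sequence o in {1..N} by fitting an N-state
Gaussian HMM (Baum-Welch, via hmmlearn) and Viterbi-decoding the most
probable state path.  States are always relabeled in ascending order of
emission mean, so label 1 is the lowest-FRET state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM

__all__ = ["GaussianHmm", "fit_gaussian_hmm", "viterbi_discretize", "compute_fret"]

#: emission s.d. floor; prevents zero-variance collapse on noiseless input
SD_FLOOR = 1e-4


@dataclass(frozen=True)
class GaussianHmm:
    """Fitted N-state Gaussian-emission HMM, states ordered by mean."""

    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float = np.nan

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        transmat = np.asarray(self.transmat, dtype=float)
        startprob = np.asarray(self.startprob, dtype=float)
        if np.any(np.diff(means) < 0):
            raise ValueError("means must be sorted ascending (canonical ordering)")
        if np.any(sds <= 0):
            raise ValueError("emission s.d.s must be positive")
        if not np.allclose(transmat.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("rows of transmat must sum to 1")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "transmat", transmat)
        object.__setattr__(self, "startprob", startprob)

    @property
    def N(self) -> int:
        return len(self.means)


def _to_hmmlearn(hmm: GaussianHmm) -> GaussianHMM:
    m = GaussianHMM(n_components=hmm.N, covariance_type="diag", init_params="")
    m.startprob_ = hmm.startprob.copy()
    m.transmat_ = hmm.transmat.copy()
    m.means_ = hmm.means[:, None].copy()
    m.covars_ = np.maximum(hmm.sds, SD_FLOOR)[:, None] ** 2
    return m


def _canonical_order(model: GaussianHMM, score: float) -> GaussianHmm:
    order = np.argsort(model.means_[:, 0])
    return GaussianHmm(
        means=model.means_[order, 0],
        sds=np.maximum(np.sqrt(model.covars_[order, 0, 0]), SD_FLOOR),
        transmat=model.transmat_[np.ix_(order, order)],
        startprob=model.startprob_[order],
        log_likelihood=score,
    )


def fit_gaussian_hmm(
    o_n, N, max_iter=500, tol=1e-6, n_restarts=3, seed=None
) -> GaussianHmm:
    """Baum-Welch fit of an N-state Gaussian HMM to a 1-d signal.

    The first restart initializes the emission means by a 1-d k-means
    of the signal (robust to skewed state occupancies), the second by
    a quantile split, and further restarts by jittered quantiles; the
    restart with the highest log-likelihood wins.  A restart that
    collapses a state to near-zero occupancy is discarded with a
    warning.
    """
    y = np.asarray(o_n, dtype=float)
    y = y[np.isfinite(y)]
    if N < 2:
        raise ValueError("N must be at least 2")
    if len(y) < 10 * N:
        raise ValueError(f"need at least {10 * N} frames to fit {N} states")
    X = y[:, None]
    rng = np.random.default_rng(seed)
    best, best_score = None, -np.inf
    for r in range(n_restarts):
        if r == 0:
            from sklearn.cluster import KMeans

            km = KMeans(n_clusters=N, n_init=3, random_state=int(rng.integers(2**31 - 1)))
            means = np.sort(km.fit(X).cluster_centers_[:, 0])
        else:
            q = np.linspace(0, 1, 2 * N + 1)[1::2]
            if r > 1:
                q = np.clip(q + rng.normal(0, 0.05, size=N), 0.01, 0.99)
            means = np.sort(np.quantile(y, q))
        model = GaussianHMM(
            n_components=N,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol,
            init_params="",
            params="stmc",
            random_state=int(rng.integers(2**31 - 1)),
        )
        model.startprob_ = np.full(N, 1.0 / N)
        model.transmat_ = np.full((N, N), 0.1 / max(N - 1, 1)) + np.eye(N) * (0.9 - 0.1 / max(N - 1, 1))
        model.transmat_ /= model.transmat_.sum(axis=1, keepdims=True)
        model.means_ = means[:, None]
        spread = max(y.std() / (2 * N), SD_FLOOR)
        model.covars_ = np.full((N, 1), spread**2)
        hmmlearn_log = logging.getLogger("hmmlearn.base")
        old_level = hmmlearn_log.level
        hmmlearn_log.setLevel(logging.ERROR)  # its ConvergenceMonitor logs benign oscillations
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X)
                score = model.score(X)
        except (ValueError, FloatingPointError):
            continue
        finally:
            hmmlearn_log.setLevel(old_level)
        occupancy = np.bincount(model.predict(X), minlength=N) / len(y)
        if occupancy.min() < 1.0 / len(y):
            warnings.warn(
                f"restart {r}: state with near-zero occupancy, fit discarded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        if score > best_score:
            best, best_score = model, score
    if best is None:
        raise RuntimeError("all HMM restarts degenerated; check the input signal")
    return _canonical_order(best, best_score)


def viterbi_discretize(o_n, hmm: GaussianHmm):
    """Most probable discrete path under the HMM; 1-based labels.

    NaN frames (missing signal) are dropped before decoding, so the
    returned sequence covers the finite frames contiguously.
    """
    y = np.asarray(o_n, dtype=float)
    y = y[np.isfinite(y)]
    model = _to_hmmlearn(hmm)
    return model.predict(y[:, None]) + 1


def compute_fret(donor, acceptor):
    """FRET efficiency E = I_A / (I_A + I_D), per frame.

    Frames with zero total intensity are returned as NaN (missing) and
    excluded by the downstream idealization.
    """
    d = np.asarray(donor, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    if d.shape != a.shape:
        raise ValueError("donor and acceptor series must have equal length")
    if np.any(d < 0) or np.any(a < 0):
        raise ValueError("intensities must be non-negative after background handling")
    total = d + a
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(total > 0, a / total, np.nan)
    return e
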