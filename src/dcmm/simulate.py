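"""Synthetic two-layer Markov trajectories with FRET-like read-out.

The generative model has a slow homogeneous chain over K hidden
"internal states" x(1..T-1) with per-frame transition matrix A
(entries gamma^(mu)->(nu) * dt), and an observable chain o(1..T) over N
states whose per-frame transition matrix B^(mu) (entries k_{a->b}^(mu)
* dt) is slaved to the current internal state: o(t+1) is drawn from row
o(t) of B^(x(t)).  A noisy signal o_n maps each observable state to a
FRET-efficiency level plus i.i.d. Gaussian noise.

State labels in returned paths are 1-based (o in {1..N}, x in {1..K}).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_internal_path",
    "simulate_observable",
    "add_noise",
    "simulate_trace",
    "generate_benchmark_grid",
    "two_state_config",
    "multistate_config",
]

_ATOL = 1e-12


def _check_stochastic(M, name):
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if np.any(M < 0):
        raise ValueError(f"{name} has negative entries")
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError(f"rows of {name} must sum to 1")
    return M


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic-trace condition.

    A : (K, K) per-frame internal transition probabilities.
    B : (K, N, N) per-frame observable transition probabilities.
    levels : N FRET-efficiency values, strictly increasing.
    sigma : s.d. of the additive Gaussian noise on the signal.
    """

    A: np.ndarray
    B: np.ndarray
    T: int = 8801
    dt: float = 0.1
    levels: tuple = (0.1, 0.9)
    sigma: float = 0.1
    pi: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        A = _check_stochastic(self.A, "A")
        B = np.asarray(self.B, dtype=float)
        if B.ndim != 3 or B.shape[0] != A.shape[0]:
            raise ValueError("B must be a (K, N, N) stack with one matrix per internal state")
        for mu in range(B.shape[0]):
            _check_stochastic(B[mu], f"B[{mu}]")
        levels = tuple(float(v) for v in self.levels)
        if len(levels) != B.shape[1]:
            raise ValueError("need one signal level per observable state")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("levels must be strictly increasing")
        if any(not (-0.2 <= v <= 1.2) for v in levels):
            raise ValueError("levels must lie in the FRET-like range [-0.2, 1.2]")
        if self.K < 1 or self.N < 2 or self.T < 2:
            raise ValueError("require K >= 1, N >= 2, T >= 2")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        pi = self.pi
        if pi is None:
            pi = np.full(self.K, 1.0 / self.K)
        else:
            pi = np.asarray(pi, dtype=float)
            if pi.shape != (self.K,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
                raise ValueError("pi must be a length-K distribution")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "pi", pi)

    @property
    def K(self) -> int:
        return self.A.shape[0]

    @property
    def N(self) -> int:
        return self.B.shape[1]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        for k in ("A", "B", "pi"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        d["levels"] = tuple(d["levels"])
        return cls(**d)


@dataclass
class GroundTruth:
    """One simulated trace: hidden path x, ideal observable o, noisy signal o_n."""

    x: np.ndarray
    o: np.ndarray
    o_n: np.ndarray
    config: SimConfig | None = None

    def __post_init__(self):
        if len(self.x) != len(self.o) - 1:
            raise ValueError("x must have length len(o) - 1")
        if len(self.o_n) != len(self.o):
            raise ValueError("o_n must have the same length as o")

    @property
    def time(self) -> np.ndarray:
        dt = self.config.dt if self.config is not None else 1.0
        return np.arange(len(self.o)) * dt


def simulate_internal_path(A, pi, T, seed=None, rng=None):
    """Sample the internal-state path x(1..T-1) from the homogeneous chain A.

    Returns a length T-1 array of 1-based labels.  `rng` may be passed
    instead of `seed` to draw from an existing generator stream.
    """
    A = _check_stochastic(A, "A")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (A.shape[0],) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must be a distribution over the K internal states")
    if T < 2:
        raise ValueError("T must be at least 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    start = rng.choice(A.shape[0], p=pi)
    u = rng.random(T - 2)
    cum = np.cumsum(A, axis=1)
    cum[:, -1] = 1.0
    return _kernels.simulate_chain(cum, start, u) + 1


def simulate_observable(x, B, o1=None, seed=None, rng=None):
    """Sample o(1..T) with o(t+1) drawn from row o(t) of B^(x(t)).

    x holds 1-based internal labels of length T-1; o1 is the 1-based
    initial observable (default: uniform draw).
    """
    B = np.asarray(B, dtype=float)
    x = np.asarray(x)
    if x.min() < 1 or x.max() > B.shape[0]:
        raise ValueError("x contains an internal label with no B matrix")
    if rng is None:
        rng = np.random.default_rng(seed)
    N = B.shape[1]
    if o1 is None:
        o1 = rng.integers(1, N + 1)
    u = rng.random(len(x))
    cum = np.cumsum(B, axis=2)
    cum[:, :, -1] = 1.0
    return _kernels.simulate_modulated_chain(cum, x - 1, int(o1) - 1, u) + 1


def add_noise(o, levels, sigma, seed=None, rng=None):
    """Map observable labels to signal levels and add Gaussian noise."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    levels = np.asarray(levels, dtype=float)
    clean = levels[np.asarray(o) - 1]
    if sigma == 0:
        return clean
    return clean + rng.normal(0.0, sigma, size=len(clean))


def simulate_trace(config: SimConfig, seed=None, rng=None) -> GroundTruth:
    """Draw one full trace (x, o, o_n) under `config`."""
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    x = simulate_internal_path(config.A, config.pi, config.T, rng=rng)
    o = simulate_observable(x, config.B, rng=rng)
    o_n = add_noise(o, config.levels, config.sigma, rng=rng)
    return GroundTruth(x=x, o=o, o_n=o_n, config=config)


def _two_state_B(k_lh, k_hl):
    return np.array([[1.0 - k_lh, k_lh], [k_hl, 1.0 - k_hl]])


def two_state_config(
    k1=(0.05, 0.05),
    k2=(0.00625, 0.025),
    gamma=0.001,
    T=8801,
    dt=0.1,
    levels=(0.1, 0.9),
    sigma=0.1,
) -> SimConfig:
    """Benchmark condition: K=2 internal states, N=2 observables.

    k1, k2 : (k_{L->H} dt, k_{H->L} dt) per-frame probabilities inside
    each internal state; gamma : per-frame interconversion probability
    (symmetric).  The defaults are the standard two-state benchmark with
    a 20x slower L->H rate in the second internal state.
    """
    A = np.array([[1.0 - gamma, gamma], [gamma, 1.0 - gamma]])
    B = np.stack([_two_state_B(*k1), _two_state_B(*k2)])
    return SimConfig(A=A, B=B, T=T, dt=dt, levels=levels, sigma=sigma)


def multistate_config(
    rates=(0.32, 0.08, 0.02, 0.005),
    gamma_exit=0.00025,
    T=40001,
    dt=0.1,
    levels=None,
    sigma=0.05,
    N=4,
) -> SimConfig:
    """K internal states, N observables; state mu has a uniform
    intra-basin per-frame rate rates[mu] for every a != b transition and
    a symmetric total interconversion probability `gamma_exit` split
    evenly over the other internal states.

    The defaults are the ensemble-clustering benchmark: four internal
    states with 4-fold separated intra-basin rates, four observables,
    and interconversion slow enough (mean regime dwell 1/gamma_exit =
    4000 frames) that each homogeneous component supplies enough
    observable transitions to estimate all N(N-1) rates.
    """
    rates = np.asarray(rates, dtype=float)
    K = len(rates)
    if np.any(rates * (N - 1) >= 1.0):
        raise ValueError("per-frame exit probability (N-1)*rate must stay below 1")
    A = np.full((K, K), gamma_exit / max(K - 1, 1))
    np.fill_diagonal(A, 1.0 - gamma_exit)
    B = np.empty((K, N, N))
    for mu in range(K):
        B[mu] = np.full((N, N), rates[mu])
        np.fill_diagonal(B[mu], 1.0 - (N - 1) * rates[mu])
    if levels is None:
        levels = tuple(np.linspace(0.1, 0.9, N))
    return SimConfig(A=A, B=B, T=T, dt=dt, levels=tuple(levels), sigma=sigma)


def generate_benchmark_grid(
    ratios,
    n_traces=100,
    seed=0,
    base_k1=(0.05, 0.05),
    gamma=0.001,
    T=8801,
    sigma=0.1,
):
    """Traces for a grid of rate-ratio conditions.

    ratios : iterable of (r_lh, r_hl) multipliers applied to base_k1 to
    build the second internal state's rates (the benchmark sweep covers
    0.125..8).  Returns {(r_lh, r_hl): [(SimConfig, GroundTruth), ...]}.
    Per-trace RNG streams are spawned from the root seed, so the grid is
    reproducible trace-by-trace.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("empty grid")
    out = {}
    root = np.random.SeedSequence(seed)
    for (r_lh, r_hl), ss_cond in zip(ratios, root.spawn(len(ratios))):
        cfg = two_state_config(
            k1=base_k1,
            k2=(base_k1[0] * r_lh, base_k1[1] * r_hl),
            gamma=gamma,
            T=T,
            sigma=sigma,
        )
        traces = [
            simulate_trace(cfg, rng=np.random.default_rng(s))
            for s in ss_cond.spawn(n_traces)
        ]
        out[(r_lh, r_hl)] = [(cfg, gt) for gt in traces]
    return out
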