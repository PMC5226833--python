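import numpy as np
import pytest

import dcmm


@pytest.fixture(scope="session")
def benchmark_config():
    """The standard two-state benchmark condition (K=2, N=2, T=8801)."""
    return dcmm.two_state_config()


@pytest.fixture(scope="session")
def benchmark_trace(benchmark_config):
    """One simulated trace under the benchmark condition."""
    return dcmm.simulate_trace(benchmark_config, seed=7)


@pytest.fixture(scope="session")
def benchmark_decoded(benchmark_config, benchmark_trace):
    """HMM-idealized observables plus a converged K=2 variational fit."""
    gt = benchmark_trace
    hmm = dcmm.fit_gaussian_hmm(gt.o_n, 2, seed=0)
    o = dcmm.viterbi_discretize(gt.o_n, hmm)
    res = dcmm.vb_fit(o, 2, n_restarts=5, seed=0)
    x = dcmm.viterbi_internal(o, res.model)
    return {"hmm": hmm, "o": o, "result": res, "x": x}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
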