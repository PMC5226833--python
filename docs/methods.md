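# Methods

## The model

`dcmm` analyzes single-molecule time series whose kinetics change from
one time interval to another — *dynamic disorder*. The observed signal
(e.g. a FRET efficiency trace sampled at fixed Δt) hops between N
discrete observable states, but the hopping rates themselves are
modulated by a slower hidden process: the molecule's *internal state*
x(t) ∈ {1..K}, one of K kinetic regimes corresponding to superbasins of
the conformational landscape.

The generative model is a double-chain (Markov-modulated) Markov
model. The internal chain is homogeneous: x(1..T−1) starts from π and
evolves with the K×K row-stochastic matrix **A**, whose entries are the
per-frame interconversion probabilities γ^(μ)→(ν)Δt. The observable
chain is non-homogeneous and slaved to it: given o(t) and x(t), the next
observable o(t+1) is drawn from row o(t) of the N×N matrix **B**^(x(t)),
whose off-diagonal entries are intra-basin transition probabilities
k_{a→b}^(μ)Δt. The complete-data likelihood is

    P(o, x | π, A, B) = π_{x(1)} · ∏ₜ A[x(t), x(t+1)] · ∏ₜ B^(x(t))[o(t), o(t+1)].

The model is identifiable only when two time-scale separations hold:
the intra-basin rates of different internal states must differ
appreciably, and intra-basin hopping must be much faster than
interconversion (τ_conf ≪ τ_int). The reliability scores below
quantify both.

## Variational inference

For a fixed K, the parameters carry independent Dirichlet priors on π
and on every row of **A** and of each **B**^(μ). The posterior is
approximated by a factorized distribution q(x)·q(π, A, B), optimized by
coordinate ascent on the evidence lower bound F ≤ log P(o|K):

* **VB-M step.** Because the likelihood is conjugate, each Dirichlet
  row's posterior pseudocounts are the prior plus expected transition
  counts under q(x).
* **VB-E step.** q(x) is an exact chain posterior computed by scaled
  forward–backward under the geometric-mean parameters
  exp(E_q[log θ]) (sub-stochastic, the standard treatment for hidden
  Markov chains under VB).
* **Bound.** After an E-step, F equals the forward-pass log-normalizer
  minus the sum of Dirichlet KL divergences of posterior from prior; it
  is monotone over iterations and the iteration stops when |ΔF| <
  1e-6 nats (default) or after 1000 iterations. The reported F adds
  the conventional +log K! labeling-degeneracy term.

Each fit runs several restarts (default 10); a restart initializes the
responsibilities by splitting the trace into K contiguous blocks in a
random label order plus Dirichlet jitter, which biases the search
toward the persistent-regime solutions the model is for. The restart
with the highest converged F wins. The decoded internal path is the
Viterbi path under the posterior-mean parameters, with ties broken
toward the lower state index.

### Priors

Defaults: rows of **A** get Dirichlet(u_ad = 100 on the diagonal,
u_a = 1 off it) — the one prior a user normally tunes, encoding that
internal states persist for many frames (τ_int ≫ Δt); rows of **B**
get Dirichlet(1, 1) and π gets Dirichlet(1), to which results are
insensitive over wide ranges. All are configurable through `Priors`.

### Model selection

F(K) flattens rather than peaks when K exceeds the number of regimes
the trace actually visits, because the +log K! degeneracy term
overcounts: if only K_obs ≤ K labels appear in the decoded path, the
true labeling degeneracy is K!/(K−K_obs)!. The corrected score

    G(K) = F(K) − log((K − K_obs)!)

peaks at the supported K; `select_model` scans K = 1..K_max (default 5)
and returns K* = argmax G with ties to the smaller K.

## Noise filtering

Idealization of the real-valued signal into o ∈ {1..N} is a separate
pre-processing stage: an N-state Gaussian-emission HMM (free per-state
variance) is fitted by Baum–Welch (hmmlearn backend; the first restart
initializes the emission means by a 1-d k-means of the signal, which is
robust to skewed state occupancies, and further restarts use quantile
splits with jitter) and the discrete path
is the HMM Viterbi path, with states relabeled by ascending mean. N is
a user input. Frames with missing signal (zero total donor+acceptor
intensity) are dropped, and the chain treats the gap as contiguous —
the simplest convention; acceptable when gaps are rare relative to
dwell lengths.

## Reliability scores

With per-frame probabilities kΔt (ratio-based, so Δt cancels):

* D_conf: mean over internal-state pairs and observable pairs of
  |log₂(k_{a→b}^(μ)/k_{a→b}^(ν))| — how different the regimes are.
* D_int: mean over states of |log₂(k_{a→b}^(μ)/Σ_{ν≠μ} γ^(μ)→(ν))| —
  the intra/inter time-scale separation. An absorbing state is
  reported at a 64-bit cap with a warning.
* D_tot = D_conf + α·D_int with the empirical weight α = 0.8.

Decoding accuracy against a known truth is the overlap
χ = (1/(T−1))Σₜ δ(x(t), x̂(t)) after aligning labels (exhaustive
permutation matching on the estimated **B** matrices for equal K;
Hungarian assignment on path co-occupancy otherwise). The dwell-time
CV φ = sd(τ)/mean(τ) over completed dwells diagnoses homogeneous
Markovianity: φ ≈ 1 for a single geometric regime, φ > 1 for a
mixture; a windowed variant (default 20 dwells) localizes the excess.

## Ensemble clustering of kinetic arrows

A decoded trace is cut at internal-state switches into homogeneous
*components*; each component's rate matrix is estimated from its own
transition counts with +0.5 pseudocount per cell (avoiding log 0
downstream; components shorter than `min_dwell` frames are flagged
low-confidence). Every pair of adjacent components with different
labels defines a *kinetic arrow*: the 2N(N−1)-vector of log "before"
rates followed by log "after" rates (natural log; any base rescales all
distances uniformly and cannot change an argmin).

At equilibrium, detailed balance makes every transition class
bidirectional, so arrows should form antiparallel mirror pairs (the
mirror operator swaps the two blocks). For each even candidate count
K, k-means (best of n_init restarts; squared-Euclidean default,
city-block optional) clusters the arrows; an exhaustive search over all
(K−1)!! perfect matchings pairs clusters to minimize the centroid
pairing distance D_c(K) = (2/K)Σ‖C_i − C̃_j‖², and the element-level
pairing score D(K) = (2/K)Σ⟨‖C_iⁿ − C̃_jᵐ‖⟩ scores that matching on
all arrows. K* = argmin D(K), restricted to K whose clusters all hold
at least `min_cluster_size` (default 10) arrows — the size rule
matters because splitting a true mirror class can shave D slightly
while producing statistically meaningless clusters. The matched pairs
define a graph of basins connected by bidirectional kinetic paths.

## Synthetic data generator

The simulator draws x by Monte Carlo from **A** (x(1) ~ π, uniform by
default), draws o from the x-slaved **B** matrices (o(1) uniform), and
adds i.i.d. Gaussian noise to the mapped signal levels. Defaults mirror
the benchmark conditions used throughout:

* Two-state benchmark (`two_state_config`): K = 2, N = 2, T = 8801
  frames at Δt = 0.1 s, levels 0.1/0.9 (duplex/triplex-like FRET
  values), σ = 0.1 (chosen to visually match published noisy traces;
  the generating σ is not stated there), k^(1)Δt = 0.05/0.05,
  k^(2)Δt = 0.00625/0.025, γΔt = 0.001 both ways.
* Rate-ratio grid (`generate_benchmark_grid`): the second state's
  rates scaled by factors 0.125–8, 100 traces per condition.
* Clustering ensemble (`multistate_config`): K = 4, N = 4, uniform
  intra-basin rates (0.32, 0.08, 0.02, 0.005) per frame — 4-fold
  separated between adjacent regimes — total interconversion
  2.5e-4 per frame (mean regime dwell 4000 frames), T = 40001,
  levels evenly spaced in [0.1, 0.9], σ = 0.05. These values were
  chosen so that a typical component supplies ≳10 transitions for
  every one of the 12 intra-basin rate cells; with fewer counts the
  log-rate estimates are too noisy for the 12 transition classes to
  separate, regardless of the clustering method.

What the generator does *not* emulate: donor/acceptor blinking and
photobleaching, baseline drift, photon-counting (shot) noise statistics,
and non-geometric dwell distributions. Passing benchmarks therefore
demonstrate correctness of the inference given the model class, not
robustness to these experimental artifacts.

## Numerical choices

* Forward–backward and Viterbi use per-step scaled recursions
  (numba kernels); no underflow for any trace length.
* An all-zero evidence column (an observed transition impossible under
  every internal state) raises an error naming the frame; it cannot
  occur under Dirichlet posteriors, only with user-supplied degenerate
  models.
* Component rate estimation and arrow construction share the same
  +0.5 pseudocount convention.
* Gaussian-HMM emission s.d. is floored at 1e-4 to survive noiseless
  input.
* In `decompose`, whole-segment counting is used; frames misassigned
  at segment boundaries slightly bias component rates, which is
  visible as scatter in the arrow clouds.

## Benchmark problem sizes

The bundled benchmarks (`dcmm.benchmarks`, also used by
`scripts/acceptance.py`) use 100 traces for the two-state overlap
conditions (25 in the test suite's quick mode), 25 traces × 10 restarts
for the K-selection count, ≥1000 completed dwells for the dwell-CV
check, and an ensemble grown until each of the 12 directed inter-basin
paths has ≥12 *decoded* arrows (≈30–50 traces; the floor sits slightly
above the cluster-size rule of 10 to absorb arrows that k-means trades
between neighboring classes) with 200 k-means restarts per candidate K
for the clustering benchmark. These sizes
give stable means while keeping a full run in the minutes range on one
CPU.

## Known limitations

* Per-trace inference only; no joint (empirical-Bayes) fitting across
  traces, and no automatic selection of N.
* The E-step's geometric-mean parameterization makes F a bound, not
  the exact evidence; model comparison inherits the usual VB caveat
  that bounds for different K are compared.
* k-means with mirror pairing assumes transition classes are
  approximately isotropic blobs in log-rate space; strongly elongated
  clouds (rates estimated from very short components) can split or
  merge classes — hence the min-dwell filter and the cluster-size
  rule.
* The K-mismatch label-matching fallback (path co-occupancy) is
  heuristic; χ values across different K are comparable only within
  its assumptions.
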