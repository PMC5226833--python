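# dcmm — decoding dynamic disorder in single-molecule time traces

Single-molecule FRET trajectories of biomolecules such as H-DNA (a
duplex–triplex-forming DNA) often show *dynamic disorder*: the apparent
two-state hopping rates change from one stretch of the trace to the
next, because a slower, hidden process — the molecule's *internal
state*, a superbasin of its conformational landscape — modulates the
kinetics. `dcmm` decodes that hidden layer. It is written for
single-molecule biophysicists who have time traces (FRET efficiency or
donor/acceptor intensities at fixed frame rate) and want to know how
many kinetic regimes a molecule visits, when it switches, and how the
regimes are connected.

## Model

The observed chain o(t) ∈ {1..N} (idealized FRET states) and the
hidden chain x(t) ∈ {1..K} (internal states) form a double-chain
Markov model: x evolves homogeneously with per-frame transition matrix
**A** (entries γ^(μ)→(ν)Δt), while the observable transition matrix is
slaved to it, o(t+1) ~ **B**^(x(t))[o(t), ·] with entries k_{a→b}^(μ)Δt.
Inference is variational Bayes: Dirichlet priors on all rows, a
factorized posterior q(x)q(π, **A**, **B**) optimized by forward–backward
E-steps and conjugate count M-steps, yielding an evidence lower bound
F(K). The number of internal states is selected by the
degeneracy-corrected evidence G(K) = F(K) − log((K−K_obs)!), and the
hidden path by Viterbi decoding. Decoded traces are cut into
homogeneous components, and across an ensemble the component-to-
component transitions ("kinetic arrows" in log-rate space) are
clustered with k-means plus an antiparallel mirror-pairing score D(K)
to reconstruct the connectivity of the landscape. See
`docs/methods.md` for the full model, priors and numerical choices.

## Worked example

Simulate the standard benchmark (two internal states, T = 8801 frames
at 10 Hz, fast regime k·Δt = 0.05/0.05, slow regime 0.00625/0.025,
interconversion 0.001 per frame, Gaussian noise σ = 0.1 on FRET levels
0.1/0.9), then run the full analysis:

```python
import dcmm

cfg = dcmm.two_state_config()            # the benchmark condition
gt  = dcmm.simulate_trace(cfg, seed=1)   # x, o, and noisy signal o_n

hmm = dcmm.fit_gaussian_hmm(gt.o_n, N=2, seed=0)
o   = dcmm.viterbi_discretize(gt.o_n, hmm)

scan = dcmm.select_model(o, K_max=3, seed=0, n_restarts=5)
x    = scan.best_path
perm = dcmm.match_labels(scan.best.model.B, cfg.B)

print("HMM means:", hmm.means.round(3))
print("F(K):", {K: round(F, 1) for K, F in scan.F.items()})
print("selected K* =", scan.K_star)
print("overlap chi =", round(dcmm.overlap_chi(gt.x, x, perm), 3))
```

Output:

```
HMM means: [0.1   0.899]
F(K): {1: -1333.9, 2: -1318.7, 3: -1325.5}
selected K* = 2
overlap chi = 0.943
```

The noise filter recovers the two FRET levels; the evidence bound is
maximized at K = 2 (the generating number of internal states); and the
decoded internal path agrees with the hidden truth on 94% of frames —
disagreements concentrate at switch boundaries and transient
excursions. With K and rates in hand, `dcmm.reliability_scores` gives
the separability scores (D_conf, D_int, D_tot) that predict decoding
accuracy on real traces where no ground truth exists, and
`dcmm.decompose` + `dcmm.select_clusters` perform the ensemble
clustering stage.

A command-line interface mirrors the library:

```sh
dcmm simulate --out traces/ --n-traces 10 --seed 1
dcmm run --in traces/ --out results/ --seed 1
```

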