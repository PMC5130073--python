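# Methods

## Model

The simulation unit is a binary Hopfield-type attractor network: `N` neurons
with states ±1, full symmetric connectivity, no self-connections.  A neuron
fires (+1) exactly when its local field `Σ_j w_ij x_j` is strictly positive;
a zero field therefore yields −1.  Recall is asynchronous — one neuron at a
time, a fresh uniform permutation per sweep — and stops at the first sweep
with no flip (guaranteed to happen for symmetric zero-diagonal weights by the
energy argument; a `max_sweeps` cap of 100 guards degenerate inputs, and the
convergence flag is reported).  The permutation order is the *only*
stochasticity in recall, and it matters: different orders can settle in
different fixed points from the same cue.

Two learning rules are implemented, both one-shot, local and incremental:

* covariance (Hebbian): `w_ij += ξ_i ξ_j / N`;
* Storkey palimpsest: `w_ij += (ξ_i ξ_j − ξ_i h_j − h_i ξ_j)/N` with the
  local field `h_i = Σ_k w_ik ξ_k` computed from the pre-update weights.
  The field sum deliberately runs over *all* k (the zero diagonal removes the
  self term), i.e. the cross terms include j; this is the form the rest of
  the package is built and tested against.

Population loops (selectionist, elitist, elimination-of-the-worst,
metapopulation demes) are described in the README; the implementation keeps
every loop faithful to one variation/selection event per generation per
population (or per deme), with recall of all `N_A` networks preceding the
event and the output pool shuffled one-to-one into the next generation's
inputs.

An abstract comparison model replaces the network by a FIFO store of at most
`C_fix` patterns that returns the nearest stored pattern (Hamming distance,
ties uniform) plus per-bit noise `mu_O`.  It isolates which results depend on
real attractor dynamics and which only on capacity-bounded nearest-prototype
recall.

## Parameters

| symbol | meaning | default | notes |
| --- | --- | --- | --- |
| `N` | neurons = pattern length | 200 (100 for the alternating/metapopulation runs) | |
| `N_A` | networks per population | 20 (10 per deme; 100 in the full alternating run) | |
| `N_T` | networks retrained per event | 1–4 (8/40 in alternating runs, 5 in demes) | never the same network twice within an event |
| `mu_I` | input-copy mutation, per bit | 0.005 | speed of evolution is least sensitive around 0.003–0.007 |
| `mu_T` | training-copy mutation, per bit | 0.01 | |
| `mu_R` | elimination-step mutation | 1/N | |
| `mu_O` | abstract-store output noise | 0.001 | 0.002 appears in one reported configuration; 0.001 is the default here |
| `C_fix` | abstract-store capacity | 30 | close to the networks' palimpsest capacity at N=200 |
| `T_E`, `T_nolearn` | environment period, learning cut-off | 2000, 12000 | |
| `p_rec`, `p_migr` | recombination, migration prob. | 0.1, 0.004 | one event per deme update |
| `w1`, `w2` | block subfitness weights | 10, 9 | not published for the original test case; any `w1 > w2 > 1` with the same argmax works |
| `pretrain_count` | random patterns stored before a run | 30 at N=200, 20 at N=100 | kept below the 0.25·N palimpsest capacity (a warning fires above it) |

## Numerical and design choices

* **Patterns** are numpy `int8` arrays; weights `float64`.  The recall inner
  loop is a numba kernel that maintains all local fields incrementally (a
  settled sweep costs O(N), a flip O(N)), seeded per call from the caller's
  `numpy.random.Generator` so every run is reproducible from one integer.
* **Zero-field convention**: field ≤ 0 → −1 everywhere (recall, fixed-point
  tests, capacity).  A wiped (all-zero) network therefore relaxes to the
  uniform −1 state.
* **Tie-breaks**: best-of-population selection and nearest-prototype recall
  break ties uniformly at random from the run's generator.
* **Two-point recombination** draws two distinct cut points uniformly from
  the N+1 boundaries of a linear (non-circular) string; both offspring are
  evaluated and the better one is the replacement candidate.
* **Capacity protocols.**  Covariance: train M random patterns jointly,
  sweep M, report the largest M/N with ≥ 90% of patterns retrieved (≥ 20
  replicates).  Storkey: train 2N patterns sequentially, count retrievable
  ones, divide by N.  *Retrieved* means the asynchronous dynamics cued with
  the pattern itself settle within 2% of its bits.  This tolerance is set
  from theory, not fitted: the retrieval fixed point at capacity carries
  ≈ 1.6% wrong bits, and beyond capacity retrieval collapses to ≈ 50%
  error, so any tolerance in roughly 2–10% measures the same transition
  (simulated: 0.142/0.160/0.163 for covariance at 2/5/10%).  Demanding an
  exact fixed point (`tol=0`) instead measures the perfect-stability
  capacity ≈ 1/(2 ln N) per neuron — ≈ 0.094 at N=200 — a different, much
  smaller quantity; it remains available as an option.
* **GBBF normalisation**: relative fitness divides by the raw fitness of the
  configured global-optimum pattern, so the uniform +1 sequence scores
  exactly 1.  (Normalising by the sum of the winning subfitness values alone
  would leave the optimum at ≈ 1.017 because the losing target still
  contributes 1/(1+P/2) per block.)
* **Lattice boundary**: toroidal by default so every deme has exactly eight
  Moore neighbours; a bounded mode (3/5/8 neighbours) is available.
  Migration copies a partner pattern from a neighbour's current pool without
  removing it; demes are scanned row-major, so later demes see earlier demes'
  already-updated pools within a generation.
* **Memory distance** is the Hamming distance from the population's best
  output to the nearest pattern in the *producing* network's training
  history; optional complement matching accounts for the sign-flip symmetry
  of the dynamics (−ξ is an attractor whenever ξ is).  By default a
  complement match does not count as a recall.
* **Memory-wipe ablation**: the control for the alternating-environment
  experiment erases the weights (and the bookkeeping history) at the moment
  learning stops; clearing bookkeeping alone would not change the dynamics.

## What the generated data does and does not show

All inputs are synthetic by design — random ±1 patterns, constructed special
ladders, and parametric landscapes; there is no external data.  The runs
therefore probe the *mechanisms* (palimpsest storage, basin-hopping
selection, retraining-driven replication, memory recall, recombination
across demes) under clean, exchangeable randomness.  They do not say
anything about structured or correlated pattern statistics, graded fitness
functions beyond Hamming-type and block-type scores, or biological noise in
the update dynamics.

## Problem sizes used by the test suite and acceptance script

Simulations are sized so the full suite and the acceptance script each run
in minutes on one core: capacities at N = 200 with 20 replicates; the
retraining/mutation-rate comparisons at N = 200 with caps of 4000
generations (20 seeds for the N_T trend, 10 per mutation rate); the
alternating environment at N = 100, T_E = 300 (the scale reported by the
acceptance script) and additionally at N = 50, T_E = 700 in the suite; the
metapopulation at N = 40 (10×10 demes) with the full N = 100 configuration
available through the CLI.

## Known limitations

* At the scaled alternating-environment setting N = 100, T_E = 300, the
  population does not reach the *exact* optimum within a period: with one
  mutation trial per generation, fixing the last wrong bits alone takes on
  the order of e·N·ln N ≈ 1000–1500 generations, so periods shorter than
  that plateau around fitness 0.7–0.8 and the post-learning recall returns
  that stored near-optimum rather than 1.0.  The full-scale setting
  T_E = 2000 sits above the bound, and the suite demonstrates perfect
  recovery at N = 50 with T_E = 700.  This is a property of the
  elimination-of-the-worst dynamics, not of the memory mechanism.
* The mutation-rate optimum of elitist evolution is shallow relative to
  run-to-run variance at feasible replicate counts; distinguishing the ends
  of the U from the middle reliably needs many more than ten seeds per rate.
* Generations-to-exact-optimum is heavy-tailed: the final bits fix slowly
  because variation must both hit the remaining wrong bits and survive attractor
  denoising; comparisons between configurations use caps and rank tests.
* Full connectivity only; no diluted weights, spiking dynamics or structural
  plasticity.  Pattern length is constant within a run.
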