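# darwinnets

Evolutionary search implemented by populations of binary attractor networks.

Patterns of neural activity — fixed-length vectors over {−1, +1} — are
treated as **units of selection**: a population of Hopfield-type recurrent
networks *generates* candidate patterns by attractor recall, a fitness
function *selects* among the outputs, and (re)training the networks on
selected patterns implements *heritable replication with variation*.  The
package is for computational neuroscientists and evolutionary-computation
researchers who want to simulate and dissect this neuro-evolutionary loop:
how palimpsest memory, attractor basins, spurious (mixture) attractors and
island-style population structure shape search on simple, alternating and
deceptive fitness landscapes.

## The model

**Networks.** Each unit is a fully connected network of `N` binary neurons
with symmetric, zero-diagonal weights.  Recall is asynchronous: neurons
update one at a time in a fresh random order per sweep,

```
x_i(t+1) = sgn( Σ_{j≠i} w_ij x_j(t) )        (zero field → −1)
```

until a fixed point.  Two one-shot, local, incremental learning rules store a
pattern ξ:

```
covariance:  w_ij ← w_ij + ξ_i ξ_j / N
Storkey:     w_ij ← w_ij + (ξ_i ξ_j − ξ_i h_j − h_i ξ_j) / N,   h_i = Σ_k w_ik ξ_k
```

The covariance rule holds ≈ 0.14·N jointly trained patterns but forgets
catastrophically when overloaded sequentially; the Storkey rule is a
*palimpsest* — new patterns gracefully replace the oldest — with capacity
≈ 0.25·N, which is what lets networks keep learning throughout a run.

**Evolutionary loops.**

* *Selectionist search*: no learning; pre-trained attractors with overlapping
  basins form a ladder to the optimum, and pure selection hops along it.
* *Elitist evolution*: the single best output per generation is redistributed
  as μ_I-noisy inputs and retrains `N_T` random networks as μ_T-noisy copies.
* *Elimination of the worst*: one output per generation is mutated (μ_R = 1/N)
  and replaces the pool's worst member only on strict improvement, also
  training `N_T` networks; used with a target that alternates between uniform
  +1 and uniform −1 every `T_E` generations to probe long-term memory.
* *Metapopulation*: demes of networks on a toroidal lattice with Moore
  neighbourhoods; variation events are two-point recombination with
  probability `p_rec` (partner drawn from a neighbouring deme with
  probability `p_migr`) else mutation — enough to solve a deceptive
  building-block landscape where each block scores `w_j` on an exact target
  match and `1/(1+d)` otherwise.

## Worked example

```bash
python examples/01_palimpsest_memory.py
```

prints (seeded, abridged):

```
covariance:   0 of 400 sequentially trained patterns retrievable (0.00 per neuron)
   storkey:  42 of 400 sequentially trained patterns retrievable (0.21 per neuron)
covariance: capacity ratio 0.138 patterns per neuron
   storkey: capacity ratio 0.216 patterns per neuron
```

i.e. a covariance network trained sequentially far past capacity retrieves
*nothing* (catastrophic forgetting), while the Storkey palimpsest always
retains the most recent ≈ 0.2·N patterns; the joint-storage capacity of the
covariance rule simulates at ≈ 0.14 patterns per neuron.  The other examples
walk through each experiment:

```bash
python examples/02_selectionist_ladder.py    # saltatory selection on a ladder
python examples/03_elitist_evolution.py      # retraining speeds up evolution
python examples/04_changing_environment.py   # recall of stored optima
python examples/05_metapopulation_gbbf.py    # demes solve the deceptive landscape
```

`examples/02_selectionist_ladder.py`, for instance, reports a run reaching
the optimum in three generations via ladder ranks #3 → #18 → #20 — selection
leaps across overlapping attractor basins instead of visiting every rung.

## Command line

A thin CLI wraps the same library calls and writes a per-generation
`trajectory.csv` plus a `metadata.json` sidecar (full config echo, seed,
convergence generation):

```bash
darwinnets evolve --seed 1 --n-t 4 --out runs/evolve
darwinnets cycle  --seed 1 --t-e 2000 --out runs/cycle
darwinnets gbbf   --seed 1 --n 100 --out runs/gbbf
darwinnets capacity --rule both --out runs/capacity
darwinnets run config.yaml            # any experiment from a YAML config
```

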