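"""Long-term memory in a periodically alternating environment.

The target pattern flips between uniform +1 and uniform -1 every T_E
generations.  While learning is on, the population finds each optimum by
elimination-of-the-worst; after learning is switched off and the inputs are
randomised at every environment change, high fitness can only come from
recalling the stored optimum — which the networks do immediately.
"""

import numpy as np

from darwinnets import (
    EnvironmentSchedule,
    PopulationConfig,
    VariationParams,
    run_changing_environment,
)

N, T_E = 50, 700
cfg = PopulationConfig(N_A=20, N=N, N_T=8,
                       variation=VariationParams(mu_R=1 / N), pretrain_count=10)
sched = EnvironmentSchedule(N=N, T_E=T_E, T_nolearn=4 * T_E)
recs = run_changing_environment(cfg, sched, np.random.default_rng(2024),
                                n_generations=6 * T_E)
best = np.array([r.best_fitness for r in recs])
md = np.array([r.memory_distance for r in recs], dtype=float)

print("period  phase      peak fitness  peak in first 10 gens  median memory distance")
for p in range(6):
    seg = slice(p * T_E, (p + 1) * T_E)
    phase = "learning" if p < 4 else "recall  "
    print(f"{p:6d}  {phase}  {best[seg].max():12.2f}  "
          f"{best[p * T_E:p * T_E + 10].max():21.2f}  "
          f"{np.nanmedian(md[seg]):22.1f}")

print("\nDuring the recall phase each period starts from random inputs, yet "
      "the best output hits fitness 1.0 within a few generations with memory "
      "distance 0: the optimum is recalled from the palimpsest memory, not "
      "rediscovered.")
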