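"""Evolve a small population on the behavioural-preference task.

A demonstration-scale genetic algorithm (8 agents, 6 generations; the study
scale is 20 agents for ~100 generations, see scripts/evolve_fixture.py).
Each agent is scored on 12 runs - 3 for each of the 4 tasks (single light A,
single light B, and the two blinking-distractor tasks) - with fitness
F_trial = (F_D + F_p) * F_H.  Prints the fitness trajectory: elitism makes
the best score non-decreasing whenever evaluation seeds are frozen.
"""

import numpy as np

from kurasoc.evolution import GAConfig, decode_genome, evolve

config = GAConfig(population=8, generations=6, elite=2, frozen_eval_seed=7)
result = evolve(config, np.random.default_rng(1))

for gen, (best, mean) in enumerate(zip(result.best_per_generation,
                                       result.mean_per_generation)):
    print(f"generation {gen}: best fitness {best:.3f}, mean {mean:.3f}")

agent = decode_genome(result.best_genome)
print("\nbest agent natural frequencies (rad/s):", np.round(agent.net.omega, 2))
print("best agent sensor gains [rA lA rB lB]:", np.round(agent.body.sensor_gains, 2))
print("(fitness ~2 is the theoretical ceiling: sitting on the light with "
      "silent plasticity)")
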