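"""Regenerate the packaged evolved reference agent.

Runs the behavioural-preference GA from a given seed and writes the best
agent of the final generation (with its provenance) to
``src/kurasoc/data/evolved_agent.json``.  Usage::

    python scripts/evolve_fixture.py --seed 1 --generations 120 \
        [--out src/kurasoc/data/evolved_agent.json]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from kurasoc.evolution import GAConfig, decode_genome, evolve


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--generations", type=int, default=120)
    ap.add_argument("--population", type=int, default=20)
    ap.add_argument("--out", default="src/kurasoc/data/evolved_agent.json")
    ap.add_argument("--log", default=None, help="optional CSV fitness log")
    args = ap.parse_args()

    config = GAConfig(population=args.population, generations=args.generations)
    rng = np.random.default_rng(args.seed)
    result = evolve(config, rng, keep_final_population=True)

    # best agent of the final generation
    best = result.final_population[0]
    agent = decode_genome(best)
    agent.meta.update(
        {
            "provenance": "behavioural-preference GA",
            "ga_seed": args.seed,
            "generations": args.generations,
            "population": args.population,
            "final_generation_best_fitness": float(result.final_fitness[0]),
            "best_fitness_overall": result.best_fitness,
        }
    )
    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    agent.save(out)
    print(f"wrote {out} (final-generation best fitness {result.final_fitness[0]:.4f})")

    if args.log:
        import pandas as pd

        pd.DataFrame(
            {
                "generation": np.arange(result.best_per_generation.size),
                "best_fitness": result.best_per_generation,
                "mean_fitness": result.mean_per_generation,
            }
        ).to_csv(args.log, index=False)
        print(f"wrote {args.log}")


if __name__ == "__main__":
    main()
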