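"""Genome encoding and the elitist genetic algorithm.

Each of the agent's 22 evolvable parameters is a 5-bit gene decoding
linearly into its range (value = lo + int/31 * (hi - lo)).  A population of
20 agents is evolved on the four-task behavioural-preference suite: a single
light A, a single light B, and the two two-light tasks where the distractor
light blinks.  Per generation the best 4 agents pass unchanged (elitism);
the remaining slots are filled by fitness-proportional parent selection,
uniform per-gene crossover and a 3% per-gene mutation (one random bit of the
mutated gene flips).

Fitness per trial is F_trial = (F_D + F_p) * F_H: the fractional approach to
the target light, the fraction of time spent within 16 units of it, and the
mean degree of homeostasis 1 - p (so plastic turmoil is penalized
multiplicatively).  Each agent is scored on 12 runs (3 per task) of 8 trials
of 125 s; only the last 3 trials of each run count, so slow plastic
convergence is not penalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .agents import Agent
from .embodiment import (
    BodyParams,
    TASK_KINDS,
    TrialRecord,
    run_trial,
    spawn_trial,
    target_index,
)
from .network import NetworkParams

__all__ = [
    "BITS_PER_GENE",
    "N_GENES",
    "GENOME_BITS",
    "GENE_TABLE",
    "decode_genome",
    "encode_agent",
    "FitnessBreakdown",
    "trial_fitness",
    "evaluate_agent",
    "GAConfig",
    "EvolutionResult",
    "evolve",
    "random_genome",
]

BITS_PER_GENE = 5
GENE_MAX = 2 ** BITS_PER_GENE - 1  # 31

#: (name, count, low, high) in genome order
GENE_TABLE = (
    ("omega", 3, 0.0, 5.0),
    ("sensor_gain", 4, -8.0, 8.0),
    ("alpha", 3, 0.0, 5.0),
    ("eta", 6, 0.0, 0.9),
    ("phi_r", 1, 0.0, 2.0 * np.pi),
    ("phi_l", 1, 0.0, 2.0 * np.pi),
    ("phi0", 3, -np.pi / 2, np.pi / 2),
)
N_GENES = sum(c for _, c, _, _ in GENE_TABLE)  # 22
GENOME_BITS = N_GENES * BITS_PER_GENE  # 110

_OFFDIAG = [(i, j) for i in range(3) for j in range(3) if i != j]


def _bits_to_ints(bits: np.ndarray) -> np.ndarray:
    b = bits.reshape(N_GENES, BITS_PER_GENE)
    weights = 2 ** np.arange(BITS_PER_GENE - 1, -1, -1)
    return b @ weights


def _ints_to_bits(ints: np.ndarray) -> np.ndarray:
    out = np.zeros((N_GENES, BITS_PER_GENE), dtype=np.uint8)
    for k in range(BITS_PER_GENE):
        out[:, BITS_PER_GENE - 1 - k] = (ints >> k) & 1
    return out.ravel()


def decode_genome(bits: np.ndarray) -> Agent:
    """Decode a 110-bit genome into an Agent (5 bits per parameter)."""
    bits = np.asarray(bits, dtype=np.uint8).ravel()
    if bits.size != GENOME_BITS:
        raise ValueError(f"genome must have {GENOME_BITS} bits, got {bits.size}")
    ints = _bits_to_ints(bits)
    values = {}
    pos = 0
    for name, count, lo, hi in GENE_TABLE:
        g = ints[pos: pos + count]
        values[name] = lo + g / GENE_MAX * (hi - lo)
        pos += count
    eta = np.zeros((3, 3))
    for k, (i, j) in enumerate(_OFFDIAG):
        eta[i, j] = values["eta"][k]
    net = NetworkParams(
        omega=values["omega"],
        phi0=values["phi0"],
        eta=eta,
        alpha=values["alpha"],
    )
    body = BodyParams(
        sensor_gains=values["sensor_gain"],
        phi_r=float(values["phi_r"][0]),
        phi_l=float(values["phi_l"][0]),
    )
    return Agent(net=net, body=body, meta={"genome": bits.tolist()})


def encode_agent(agent: Agent) -> np.ndarray:
    """Quantize agent parameters back to the nearest 110-bit genome."""
    flat = np.concatenate([
        agent.net.omega,
        agent.body.sensor_gains,
        agent.net.alpha,
        [agent.net.eta[i, j] for i, j in _OFFDIAG],
        [agent.body.phi_r, agent.body.phi_l],
        agent.net.phi0,
    ])
    ints = np.empty(N_GENES, dtype=np.int64)
    pos = 0
    for name, count, lo, hi in GENE_TABLE:
        v = flat[pos: pos + count]
        ints[pos: pos + count] = np.clip(np.round((v - lo) / (hi - lo) * GENE_MAX), 0, GENE_MAX)
        pos += count
    return _ints_to_bits(ints)


def random_genome(rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 2, GENOME_BITS, dtype=np.uint8)


# --------------------------------------------------------------------------
# fitness
# --------------------------------------------------------------------------

@dataclass
class FitnessBreakdown:
    """Per-trial fitness terms: F_trial = (F_D + F_p) * F_H."""

    f_d: float
    f_p: float
    f_h: float

    @property
    def f_trial(self) -> float:
        return (self.f_d + self.f_p) * self.f_h


def trial_fitness(record: TrialRecord) -> FitnessBreakdown:
    """Fitness terms of one trial.

    F_D = max(0, 1 - d_f/d_i) rewards approaching the target light (clamped
    at 0 so proportional selection stays non-negative); F_p is the fraction
    of steps spent within 16 units of it; F_H the time-and-oscillator mean
    of 1 - p.
    """
    if record.d_init <= 0:
        raise ValueError("degenerate trial: initial distance to target is zero")
    f_d = max(0.0, 1.0 - record.d_final / record.d_init)
    return FitnessBreakdown(f_d=f_d, f_p=record.near_fraction, f_h=record.homeo_mean)


def evaluate_agent(
    agent: Agent,
    rng: np.random.Generator,
    dt: float = 0.05,
    runs_per_task: int = 3,
    trials_per_run: int = 8,
    eval_last: int = 3,
) -> float:
    """Mean fitness over 12 independent runs (3 per task, 8 trials each).

    Weights are re-randomized at the start of every run; only the last
    ``eval_last`` trials of a run are scored.  Simulation failures degrade
    to zero fitness with a warning.
    """
    tasks = [k for k in TASK_KINDS if k != "AB"]
    run_scores = []
    for task in tasks:
        tgt = target_index(task)
        for _ in range(runs_per_task):
            state = agent.initial_state(rng)
            world = spawn_trial(rng, task)
            scores = []
            try:
                for trial in range(trials_per_run):
                    if trial > 0:
                        world = spawn_trial(rng, task, pose=world.pose)
                    rec = run_trial(
                        agent, world, mode="fixed125", dt=dt, rng=rng,
                        state=state, target=tgt, record="summary",
                    )
                    if trial >= trials_per_run - eval_last:
                        scores.append(trial_fitness(rec).f_trial)
            except FloatingPointError as err:
                warnings.warn(f"run aborted ({err}); scoring 0", stacklevel=2)
                scores = [0.0]
            run_scores.append(float(np.mean(scores)))
    return float(np.mean(run_scores))


# --------------------------------------------------------------------------
# genetic algorithm
# --------------------------------------------------------------------------

@dataclass
class GAConfig:
    population: int = 20
    generations: int = 100
    elite: int = 4
    mutation_per_gene: float = 0.03
    crossover: bool = True
    selection: str = "fitness"  # or "rank"
    dt: float = 0.05
    frozen_eval_seed: int | None = None  # same trial seeds every generation


@dataclass
class EvolutionResult:
    best_genome: np.ndarray
    best_fitness: float
    best_per_generation: np.ndarray
    mean_per_generation: np.ndarray
    best_genomes: list = field(repr=False, default_factory=list)
    final_population: np.ndarray | None = field(repr=False, default=None)
    final_fitness: np.ndarray | None = field(repr=False, default=None)


def _mutate(genome: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """With probability ``rate`` per gene, flip one random bit of its 5."""
    g = genome.copy()
    hit = np.flatnonzero(rng.random(N_GENES) < rate)
    for gene in hit:
        bit = gene * BITS_PER_GENE + rng.integers(BITS_PER_GENE)
        g[bit] ^= 1
    return g


def _crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform per-gene mixing of two parents."""
    from_a = rng.random(N_GENES) < 0.5
    mask = np.repeat(from_a, BITS_PER_GENE)
    return np.where(mask, a, b)


def evolve(
    config: GAConfig,
    rng: np.random.Generator,
    fitness_fn=None,
    keep_final_population: bool = False,
) -> EvolutionResult:
    """Rank-ordered elitist GA over 110-bit genomes.

    ``fitness_fn(genome, rng) -> float`` defaults to decoding the genome and
    running the behavioural evaluation; surrogate functions are accepted for
    benchmarking the optimizer itself.  Parent selection is proportional to
    fitness over the rank-ordered population (``selection='rank'`` switches
    to rank-proportional weights); an all-zero-fitness generation falls back
    to uniform selection.
    """
    if fitness_fn is None:
        def fitness_fn(genome, frng):
            return evaluate_agent(decode_genome(genome), frng, dt=config.dt)

    pop = np.array([random_genome(rng) for _ in range(config.population)])
    best_hist, mean_hist, best_genomes = [], [], []
    eval_pop, fits = pop, np.zeros(config.population)
    for gen in range(config.generations):
        if config.frozen_eval_seed is not None:
            eval_rngs = [
                np.random.default_rng(config.frozen_eval_seed) for _ in range(config.population)
            ]
        else:
            eval_rngs = [np.random.default_rng(rng.integers(2 ** 31)) for _ in range(config.population)]
        fits = np.array([fitness_fn(g, r) for g, r in zip(pop, eval_rngs)])
        order = np.argsort(fits)[::-1]
        pop, fits = pop[order], fits[order]
        eval_pop = pop
        best_hist.append(fits[0])
        mean_hist.append(fits.mean())
        best_genomes.append(pop[0].copy())

        elite = pop[: config.elite]
        if config.selection == "rank":
            weights = np.arange(config.population, 0, -1, dtype=float)
        else:
            weights = fits.astype(float)
        if weights.sum() <= 0:
            weights = np.ones(config.population)
        probs = weights / weights.sum()
        children = []
        for _ in range(config.population - config.elite):
            pa, pb = rng.choice(config.population, size=2, replace=False, p=probs)
            child = _crossover(pop[pa], pop[pb], rng) if config.crossover else pop[pa].copy()
            children.append(_mutate(child, config.mutation_per_gene, rng))
        pop = np.vstack([elite, np.array(children, dtype=np.uint8)])
    return EvolutionResult(
        best_genome=best_genomes[int(np.argmax(best_hist))],
        best_fitness=float(np.max(best_hist)),
        best_per_generation=np.array(best_hist),
        mean_per_generation=np.array(mean_hist),
        best_genomes=best_genomes,
        final_population=eval_pop if keep_final_population else None,
        final_fitness=fits if keep_final_population else None,
    )
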