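"""End-to-end analysis pipeline: conditions -> envelope -> fractal report.

Reusable building blocks (`phi_run`, `analyze_run`, `condition_battery`) and
the `full_pipeline` driver that reproduces the whole diagnostic table — DFA
and Welch exponents plus multifractal width for the situated, decoupled,
committed and pliable agents, and DFA exponents under the six parameter
perturbations for the situated and decoupled agents.

Every random draw descends from the single configured seed through
``numpy``'s SeedSequence spawning, so identical configurations reproduce
identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .agents import Agent, load_reference_agent
from .conditions import (
    ConditionSpec,
    PERTURBATION_KINDS,
    find_frozen_variants,
    run_condition,
)
from .fractal import EnvelopeSeries, FractalReport, dfa, multifractal_spectrum, welch_slope

__all__ = ["RunConfig", "phi_run", "analyze_run", "condition_battery", "full_pipeline"]

DFA_FIT_WIDE = (1.0, 10 ** 3.5)  # s, situated single-run fit
DFA_FIT_SHORT = (10.0, 10 ** 2.5)  # s, restricted situated fit
DFA_FIT_FROZEN = (100.0, 10 ** 3.5)  # s, committed / pliable fit
DFA_FIT_PERTURBED = (10.0, 10 ** 3.5)  # s, robustness runs
WELCH_BAND = (10 ** -3.5, 10 ** -1)  # Hz
MF_DECIMATION = 10


@dataclass
class RunConfig:
    """Scales and settings of the full diagnostic battery."""

    seed: int = 0
    dt: float = 0.05
    duration_s: float = 125000.0
    n_runs: int = 25
    welch_runs: int = 10
    perturbation_runs: int = 3
    noise_sd: float = 1.0
    outdir: str | None = None


def phi_run(
    agent: Agent,
    kind: str,
    seed: int,
    duration_s: float = 125000.0,
    dt: float = 0.05,
    noise_sd: float = 1.0,
    perturbation: str = "none",
) -> EnvelopeSeries:
    """One long run of a condition, returning the 10 Hz envelope Phi.

    ``kind`` is ``situated`` or ``decoupled``; frozen variants are plain
    situated runs of an agent whose plasticity rates are zero.  Situated
    runs chain capture-terminated trials.
    """
    cond = "decoupled" if kind == "decoupled" else ("frozen" if kind == "frozen" else "situated")
    spec = ConditionSpec(
        kind=cond,
        duration_s=duration_s,
        trial_mode="capture",
        noise_sd=noise_sd,
        dt=dt,
        perturbation=perturbation,
    )
    return run_condition(agent, spec, np.random.default_rng(seed)).envelope


def analyze_run(
    env: EnvelopeSeries,
    dfa_fit: tuple[float, float] = DFA_FIT_WIDE,
    welch_band: tuple[float, float] = WELCH_BAND,
    multifractal: bool = True,
    condition: str = "",
) -> FractalReport:
    """DFA exponent, Welch slope, and (optionally) multifractal width of Phi.

    The multifractal spectrum is computed on the series decimated by 10,
    over moment orders q in (0, 10].
    """
    rep = FractalReport(condition=condition)
    d = dfa(env, fit_range=dfa_fit)
    rep.dfa_alpha, rep.beta_dfa, rep.dfa_r2, rep.dfa_fit_range = d.alpha, d.beta, d.r2, dfa_fit
    w = welch_slope(env, fit_band=welch_band)
    rep.beta_psd, rep.psd_r2, rep.psd_fit_band = w.beta, w.r2, welch_band
    if multifractal:
        dec = env.decimated(MF_DECIMATION)
        m = multifractal_spectrum(dec)
        rep.h_q, rep.q_grid, rep.delta_h = m.h, m.q, m.delta_h
    return rep


def condition_battery(
    agent: Agent,
    kind: str,
    seeds: list[int],
    dfa_fit: tuple[float, float],
    duration_s: float = 125000.0,
    dt: float = 0.05,
    noise_sd: float = 1.0,
    multifractal: bool = True,
) -> dict:
    """Repeat one condition across seeds; per-run and mean exponents."""
    envs = [phi_run(agent, kind, s, duration_s, dt, noise_sd) for s in seeds]
    reps = [analyze_run(e, dfa_fit=dfa_fit, multifractal=multifractal, condition=kind) for e in envs]
    w = welch_slope(envs, fit_band=WELCH_BAND)
    return {
        "condition": kind,
        "n_runs": len(seeds),
        "beta_dfa": [r.beta_dfa for r in reps],
        "beta_dfa_mean": float(np.mean([r.beta_dfa for r in reps])),
        "beta_psd_run_averaged": float(w.beta),
        "delta_h": [r.delta_h for r in reps] if multifractal else None,
        "delta_h_mean": float(np.mean([r.delta_h for r in reps])) if multifractal else None,
    }


def full_pipeline(config: RunConfig, agent: Agent | None = None) -> dict:
    """The whole diagnostic table for the four agent variants plus the
    parameter-perturbation robustness runs.

    Returns (and optionally writes) a JSON-serializable report with one
    (beta_dfa, beta_psd, delta_h) triple per condition and the perturbation
    DFA exponents for the situated and decoupled agents.
    """
    if agent is None:
        agent = load_reference_agent()
    ss = np.random.SeedSequence(config.seed)

    def seeds(n):
        return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]

    variants_rng = np.random.default_rng(seeds(1)[0])
    frozen = find_frozen_variants(agent, variants_rng)
    agents = {
        "situated": (agent, "situated", DFA_FIT_SHORT),
        "decoupled": (agent, "decoupled", DFA_FIT_SHORT),
        "committed": (frozen["committed"], "frozen", DFA_FIT_FROZEN),
        "pliable": (frozen["pliable"], "frozen", DFA_FIT_FROZEN),
    }
    report = {"config": asdict(config), "conditions": {}, "perturbations": {}}
    for name, (ag, kind, fit) in agents.items():
        if ag is None:
            report["conditions"][name] = None
            continue
        report["conditions"][name] = condition_battery(
            ag, kind, seeds(config.n_runs), fit,
            duration_s=config.duration_s, dt=config.dt, noise_sd=config.noise_sd,
        )
    for kind in PERTURBATION_KINDS:
        for cond in ("situated", "decoupled"):
            envs = [
                phi_run(agent, cond, s, config.duration_s, config.dt,
                        config.noise_sd, perturbation=kind)
                for s in seeds(config.perturbation_runs)
            ]
            betas = [dfa(e, fit_range=DFA_FIT_PERTURBED).beta for e in envs]
            report["perturbations"].setdefault(kind, {})[cond] = {
                "beta_dfa": betas,
                "beta_dfa_mean": float(np.mean(betas)),
            }
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
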