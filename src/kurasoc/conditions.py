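"""Experimental conditions: situated, decoupled, frozen-plasticity, perturbed.

The analysis protocols of the study:

* **situated** — the closed sensorimotor loop with two equal-intensity
  lights (A and B) per trial.  Long fractal runs chain capture-terminated
  trials (capture radius 16, timeout 1250 s) back to back; behavioural /
  pattern analyses use fixed 125 s trials.
* **decoupled** — the same controller with the environment removed; each of
  the four sensor channels receives i.i.d. Gaussian(0, sigma) noise every
  control step (before the evolved gains), sigma = 1 by default.
* **frozen** — plasticity rates zeroed, either at a stated time inside a
  situated run or from a weight snapshot taken at the midpoint of a chosen
  trial of a reference run.  Frozen agents split into *committed* (always
  the same light) and *pliable* (choice depends on initial conditions);
  pliable agents frozen at a preference switch are the *undecided* case.
* **parameter perturbations** — random permutations of phi0, omega or eta,
  or scaling of alpha or H1 by 2^r with r ~ U[-1, 1], used to test whether
  1/f scaling is robust (self-organized) or tuned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .agents import Agent
from .embodiment import run_trial, spawn_trial, TRIAL_S
from .fractal import EnvelopeSeries, amplitude_envelope
from .network import NetworkParams

__all__ = [
    "ConditionSpec",
    "ConditionResult",
    "run_condition",
    "classify_frozen_agent",
    "reference_run",
    "find_frozen_variants",
    "perturb_params",
    "PERTURBATION_KINDS",
]

PERTURBATION_KINDS = ("none", "permute_phi0", "permute_omega", "permute_eta", "scale_alpha", "scale_h1")


@dataclass
class ConditionSpec:
    """What to simulate and for how long."""

    kind: str = "situated"  # situated | decoupled | frozen
    duration_s: float = 125000.0
    trial_mode: str = "capture"  # capture | fixed125
    noise_sd: float = 1.0
    freeze_time_s: float | None = None
    perturbation: str = "none"
    dt: float = 0.05
    record_theta: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("situated", "decoupled", "frozen"):
            raise ValueError(f"unknown condition kind {self.kind!r}")
        if self.perturbation not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation {self.perturbation!r}")
        if self.kind == "decoupled" and self.noise_sd <= 0:
            raise ValueError("decoupled condition needs noise_sd > 0")
        if self.freeze_time_s is not None and not 0 <= self.freeze_time_s <= self.duration_s:
            raise ValueError("freeze_time must lie within the run duration")


@dataclass
class ConditionResult:
    envelope: EnvelopeSeries
    decisions: np.ndarray
    meansin: np.ndarray = field(repr=False, default=None)
    theta: np.ndarray | None = field(repr=False, default=None)
    theta_fs: float = 10.0
    trial_lengths_s: np.ndarray | None = None


def run_condition(agent: Agent, spec: ConditionSpec, rng: np.random.Generator) -> ConditionResult:
    """Simulate one condition and return the envelope signal Phi plus the
    per-trial decision series (+1 light A, -1 light B).

    Phi is the Hilbert amplitude envelope of the mean activation
    (1/3) sum_i sin(theta_i), recorded at the control rate and delivered at
    10 Hz.
    """
    if spec.perturbation != "none":
        agent = perturb_params(agent, spec.perturbation, rng)
    dt = spec.dt
    total_steps = int(round(spec.duration_s / dt))
    fs = 1.0 / dt

    if spec.kind == "decoupled":
        meansin, theta = _run_decoupled(agent, spec, rng, total_steps)
        decisions = np.array([], dtype=int)
        lengths = None
    else:
        meansin, decisions, theta, lengths = _run_situated(agent, spec, rng, total_steps)
    env = amplitude_envelope(meansin, fs=fs, out_fs=10.0, source=spec.kind)
    return ConditionResult(
        envelope=env,
        decisions=np.asarray(decisions, dtype=int),
        meansin=meansin,
        theta=theta,
        theta_fs=fs / 2.0,
        trial_lengths_s=None if lengths is None else np.asarray(lengths),
    )


def _run_decoupled(agent, spec, rng, total_steps):
    state = agent.initial_state(rng)
    net, body = agent.net, agent.body
    meansin = np.empty(total_steps)
    rec = spec.record_theta
    theta_out = np.empty(((total_steps + 1) // 2, 3)) if rec else np.empty((0, 3))
    _kernels.run_decoupled_kernel(
        net.omega, net.phi0, net.eta, net.alpha, net.h1, net.h2,
        body.sensor_gains, spec.noise_sd, int(rng.integers(2 ** 31)),
        state.theta, state.dk, state.phi, state.p,
        total_steps, spec.dt,
        meansin, theta_out, rec, 2,
    )
    if not np.all(np.isfinite(state.theta)):
        raise FloatingPointError("non-finite network state in decoupled run")
    return meansin, (theta_out if rec else None)


def _run_situated(agent, spec, rng, total_steps):
    dt = spec.dt
    freeze_step = (
        None if spec.freeze_time_s is None or spec.kind != "frozen"
        else int(round(spec.freeze_time_s / dt))
    )
    frozen_net = replace(agent.net, eta=np.zeros((3, 3)))
    state = agent.initial_state(rng)
    world = spawn_trial(rng, "AB")
    pieces, thetas, decisions, lengths = [], [], [], []
    steps_done = 0
    record = "theta" if spec.record_theta else "summary"
    while steps_done < total_steps:
        if spec.trial_mode == "fixed125":
            trial_steps = int(round(TRIAL_S / dt))
        else:
            trial_steps = None  # capture mode: up to the 1250 s timeout
        live_agent = agent
        split_at = None
        if freeze_step is not None and steps_done < freeze_step:
            budget = trial_steps if trial_steps is not None else int(round(1250.0 / dt))
            if steps_done + budget > freeze_step:
                split_at = freeze_step - steps_done
        elif freeze_step is not None:
            live_agent = Agent(net=frozen_net, body=agent.body)

        if split_at is not None and split_at > 0 and spec.trial_mode == "fixed125":
            # run the pre-freeze part of this trial, then freeze mid-trial
            rec = run_trial(live_agent, world, mode="fixed125", dt=dt, rng=rng,
                            state=state, record=record, n_steps=split_at)
            _collect(rec, pieces, thetas, spec)
            steps_done += rec.steps
            live_agent = Agent(net=frozen_net, body=agent.body)
            rec = run_trial(live_agent, world, mode="fixed125", dt=dt, rng=rng,
                            state=state, record=record,
                            n_steps=int(round(TRIAL_S / dt)) - split_at)
            freeze_step = 0  # frozen from now on
        else:
            mode = "fixed125" if spec.trial_mode == "fixed125" else "capture"
            rec = run_trial(live_agent, world, mode=mode, dt=dt, rng=rng,
                            state=state, record=record)
        _collect(rec, pieces, thetas, spec)
        steps_done += rec.steps
        decisions.append(rec.decision)
        lengths.append(rec.duration)
        world = spawn_trial(rng, "AB", pose=world.pose)
    meansin = np.concatenate(pieces)[:total_steps]
    theta = np.vstack(thetas)[: total_steps // 2] if spec.record_theta else None
    return meansin, decisions, theta, lengths


def _collect(rec, pieces, thetas, spec):
    if rec.steps:
        pieces.append(rec.meansin)
        if spec.record_theta:
            thetas.append(rec.theta)


# --------------------------------------------------------------------------
# frozen-plasticity variants
# --------------------------------------------------------------------------

def classify_frozen_agent(decisions: np.ndarray, threshold: float = 0.95, min_trials: int = 100) -> str:
    """'committed' if one light is chosen in >= ``threshold`` of the trials,
    otherwise 'pliable'."""
    d = np.asarray(decisions)
    if d.size < min_trials:
        raise ValueError(f"need >= {min_trials} trials to classify, got {d.size}")
    frac_a = np.mean(d == 1)
    return "committed" if max(frac_a, 1.0 - frac_a) >= threshold else "pliable"


@dataclass
class ReferenceRun:
    """A fixed-trial situated run with mid-trial weight snapshots."""

    decisions: np.ndarray
    snapshots_theta: np.ndarray  # (n_trials, 3) at each trial midpoint
    snapshots_dk: np.ndarray  # (n_trials, 3, 3)
    final_distances: np.ndarray  # (n_trials, 2)


def reference_run(agent: Agent, rng: np.random.Generator, n_trials: int = 60, dt: float = 0.05) -> ReferenceRun:
    """Present ``n_trials`` pairs of equal lights for 125 s each, recording
    the decision and the (theta, dK) snapshot at the midpoint of every trial."""
    state = agent.initial_state(rng)
    world = spawn_trial(rng, "AB")
    half = int(round(TRIAL_S / dt)) // 2
    dec, th, dk, dists = [], [], [], []
    for trial in range(n_trials):
        if trial > 0:
            world = spawn_trial(rng, "AB", pose=world.pose)
        run_trial(agent, world, mode="fixed125", dt=dt, rng=rng, state=state, n_steps=half)
        th.append(state.theta.copy())
        dk.append(state.dk.copy())
        rec = run_trial(agent, world, mode="fixed125", dt=dt, rng=rng, state=state,
                        n_steps=int(round(TRIAL_S / dt)) - half)
        dec.append(rec.decision)
        dists.append([rec.d_final_a, rec.d_final_b])
    return ReferenceRun(
        decisions=np.array(dec),
        snapshots_theta=np.array(th),
        snapshots_dk=np.array(dk),
        final_distances=np.array(dists),
    )


def _streak_midpoints(decisions: np.ndarray, min_len: int = 4) -> list[int]:
    """Trial indices at the middle of long same-decision streaks, longest first."""
    d = np.asarray(decisions)
    streaks = []
    start = 0
    for i in range(1, d.size + 1):
        if i == d.size or d[i] != d[start]:
            if i - start >= min_len:
                streaks.append((i - start, start + (i - start) // 2))
            start = i
    return [mid for _, mid in sorted(streaks, reverse=True)]


def _switch_trials(decisions: np.ndarray) -> list[int]:
    d = np.asarray(decisions)
    return [i for i in range(1, d.size) if d[i] != d[i - 1]]


def _verify(agent: Agent, seed: int, n_trials: int, dt: float) -> np.ndarray:
    rng = np.random.default_rng(seed)
    state = agent.initial_state(rng)
    world = spawn_trial(rng, "AB")
    dec = []
    for trial in range(n_trials):
        if trial > 0:
            world = spawn_trial(rng, "AB", pose=world.pose)
        rec = run_trial(agent, world, mode="fixed125", dt=dt, rng=rng, state=state)
        dec.append(rec.decision)
    return np.array(dec)


def find_frozen_variants(
    agent: Agent,
    rng: np.random.Generator,
    n_trials: int = 60,
    verify_trials: int = 100,
    dt: float = 0.05,
) -> dict:
    """Build verified committed and pliable frozen-plasticity agents.

    Runs the reference fixed-trial simulation, then freezes the weights at
    candidate trial midpoints: mid-streak candidates should yield committed
    agents, preference-switch candidates pliable ones.  Each candidate is
    verified over ``verify_trials`` fresh trials.  A committed variant must
    choose the *same* light on every verification trial (committed agents
    always go to the same light — near-committed snapshots that defect on a
    few trials retain residual slow dynamics and belong to neither class);
    a pliable variant must fall below the standard classification
    threshold.  The first candidate of each class that verifies is returned
    together with the reference run.
    """
    ref = reference_run(agent, rng, n_trials=n_trials, dt=dt)
    out = {"reference": ref, "committed": None, "pliable": None}
    verify_seed = int(rng.integers(2 ** 31))
    for label, candidates in (
        ("committed", _streak_midpoints(ref.decisions)),
        ("pliable", _switch_trials(ref.decisions)),
    ):
        for trial in candidates:
            frozen = agent.with_frozen_plasticity(
                ref.snapshots_dk[trial], label=f"{label} (frozen at trial {trial})"
            )
            dec = _verify(frozen, verify_seed, verify_trials, dt)
            frac_a = float(np.mean(dec == 1))
            if label == "committed":
                ok = frac_a in (0.0, 1.0)
            else:
                ok = classify_frozen_agent(dec, min_trials=verify_trials) == "pliable"
            if ok:
                frozen.meta["freeze_trial"] = int(trial)
                frozen.meta["verified_fraction_A"] = frac_a
                out[label] = frozen
                break
    return out


# --------------------------------------------------------------------------
# parameter perturbations
# --------------------------------------------------------------------------

def perturb_params(agent: Agent, kind: str, rng: np.random.Generator) -> Agent:
    """Randomly perturb one parameter group, leaving everything else intact.

    Permutation kinds shuffle the 3-vectors phi0 / omega or the 6 directed
    plasticity rates; scaling kinds multiply all alpha_i, or H1, by 2^r with
    r ~ U[-1, 1].  When the scaled H1 exceeds H2 the upper threshold follows
    it, so the plastic function stays a valid step at the scaled threshold.
    """
    if kind not in PERTURBATION_KINDS:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    net = agent.net
    if kind == "none":
        return agent
    if kind == "permute_phi0":
        net = replace(net, phi0=rng.permutation(net.phi0))
    elif kind == "permute_omega":
        net = replace(net, omega=rng.permutation(net.omega))
    elif kind == "permute_eta":
        off = [(i, j) for i in range(3) for j in range(3) if i != j]
        vals = rng.permutation([net.eta[i, j] for i, j in off])
        eta = np.zeros((3, 3))
        for (i, j), v in zip(off, vals):
            eta[i, j] = v
        net = replace(net, eta=eta)
    elif kind == "scale_alpha":
        k = 2.0 ** rng.uniform(-1.0, 1.0)
        net = replace(net, alpha=net.alpha * k, check_ranges=False)
    else:  # scale_h1
        k = 2.0 ** rng.uniform(-1.0, 1.0)
        h1 = net.h1 * k
        net = replace(net, h1=h1, h2=max(net.h2, h1))
    return Agent(net=net, body=agent.body, init_theta=agent.init_theta,
                 init_dk=agent.init_dk, meta={**agent.meta, "perturbation": kind})
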