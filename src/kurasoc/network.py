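"""Plastic Kuramoto oscillator network with relational homeostasis.

Three phase oscillators are fully connected (no self-coupling).  Each
oscillator i carries a phase theta_i evolving as

    dtheta_i/dt = omega_i + I_i + sum_j K_ij sin(theta_j - theta_i)

and monitors its *relational phase* phi_i, the angle of the coupling-weighted
complex sum of phase differences to its neighbours.  A homeostatic rule
compares phi_i with a preferred relation phi0_i: when the wrapped error
leaves the homeostatic band (thresholds H1 <= H2) a plasticity level
p in [0, 1] switches on and drives the raw weights

    d(dK_ij)/dt = eta_ij * p(phi_i - phi0_i) * sin((theta_j - theta_i) - phi0_i).

Raw weights dK are mapped to effective couplings K_ij = alpha_i * F(dK_ij)
through a bounded, periodic, non-monotonic function F whose flat-zero lobes
make total disconnection reachable.

This module is the readable reference implementation; long simulations run
through the numerically identical compiled kernels in
:mod:`kurasoc._kernels`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkParams",
    "NetworkState",
    "wrap_angle",
    "weight_mapping",
    "WEIGHT_PERIOD",
    "relational_phase",
    "plasticity_level",
    "step_network",
]

N_OSC = 3
H_DEFAULT = 0.2 * np.pi
#: period of the weight-mapping function F (sinusoid gated by a half-frequency
#: positive square wave)
WEIGHT_PERIOD = 4.0 * np.pi
#: forward-Euler steps with dt above this get a stability warning
DT_STABILITY_BOUND = 0.2

PARAM_RANGES = {
    "omega": (0.0, 5.0),
    "phi0": (-np.pi / 2, np.pi / 2),
    "eta": (0.0, 0.9),
    "alpha": (0.0, 5.0),
}


def wrap_angle(x):
    """Wrap an angle (or array) to [-pi, pi)."""
    return (np.asarray(x) + np.pi) % (2.0 * np.pi) - np.pi


@dataclass
class NetworkParams:
    """Evolvable parameters of the 3-oscillator plastic Kuramoto controller.

    omega: natural frequencies (rad/s), range [0, 5].
    phi0: preferred phase relations (rad), range [-pi/2, pi/2].
    eta: plasticity rates (1/s), 3x3 with zero diagonal, range [0, 0.9].
    alpha: per-oscillator coupling gains scaling incoming weights, range
        [0, 5].  A scalar is broadcast to all three oscillators (shared-gain
        variant).
    h1, h2: homeostatic activation thresholds (rad), both fixed at 0.2*pi by
        default; H1 <= H2 required.  With H1 = H2 the plastic function is a
        step.
    """

    omega: np.ndarray
    phi0: np.ndarray
    eta: np.ndarray
    alpha: np.ndarray
    h1: float = H_DEFAULT
    h2: float = H_DEFAULT
    #: perturbation experiments scale parameters beyond the evolvable ranges
    check_ranges: bool = True

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.phi0 = np.asarray(self.phi0, dtype=float)
        self.alpha = np.broadcast_to(np.asarray(self.alpha, dtype=float), (N_OSC,)).copy()
        self.eta = np.asarray(self.eta, dtype=float)
        if self.eta.shape == (6,):
            m = np.zeros((N_OSC, N_OSC))
            m[~np.eye(N_OSC, dtype=bool)] = self.eta
            self.eta = m
        self.validate()

    def validate(self) -> None:
        if self.omega.shape != (N_OSC,) or self.phi0.shape != (N_OSC,):
            raise ValueError("omega and phi0 must have 3 entries")
        if self.eta.shape != (N_OSC, N_OSC):
            raise ValueError("eta must be 3x3 (or the 6 off-diagonal entries)")
        if np.any(np.diag(self.eta) != 0):
            raise ValueError("no self-coupling: eta diagonal must be zero")
        if self.h1 > self.h2:
            raise ValueError(f"H1={self.h1} must not exceed H2={self.h2}")
        if not self.check_ranges:
            return
        for name, (lo, hi) in PARAM_RANGES.items():
            v = getattr(self, name)
            if np.any(v < lo - 1e-9) or np.any(v > hi + 1e-9):
                raise ValueError(f"{name} outside range [{lo}, {hi}]: {v}")

    def couplings(self, raw_weights: np.ndarray) -> np.ndarray:
        """Effective coupling matrix K_ij = alpha_i * F(dK_ij), zero diagonal."""
        k = self.alpha[:, None] * weight_mapping(raw_weights)
        np.fill_diagonal(k, 0.0)
        return k


@dataclass
class NetworkState:
    """Dynamic state: phases, raw weights, and derived quantities."""

    theta: np.ndarray
    dk: np.ndarray
    phi: np.ndarray = field(default=None)
    p: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float) % (2.0 * np.pi)
        self.dk = np.asarray(self.dk, dtype=float)
        if self.phi is None:
            self.phi = np.zeros(N_OSC)
        if self.p is None:
            self.p = np.zeros(N_OSC)

    @classmethod
    def random(cls, params: NetworkParams, rng: np.random.Generator) -> "NetworkState":
        """Random initial condition: theta ~ U[0, 2pi); dK ~ U over one full
        period of the weight mapping."""
        theta = rng.uniform(0.0, 2.0 * np.pi, N_OSC)
        dk = rng.uniform(0.0, WEIGHT_PERIOD, (N_OSC, N_OSC))
        np.fill_diagonal(dk, 0.0)
        state = cls(theta=theta, dk=dk)
        k = params.couplings(dk)
        state.phi = relational_phase(theta, k, fallback=np.zeros(N_OSC))
        state.p = plasticity_level(wrap_angle(state.phi - params.phi0), params.h1, params.h2)
        return state

    def copy(self) -> "NetworkState":
        return NetworkState(self.theta.copy(), self.dk.copy(), self.phi.copy(), self.p.copy())


def weight_mapping(raw_weight, gain=1.0):
    """Map raw weights dK to coupling strengths K = gain * F(dK).

    F(x) = (1 - cos x)/2 gated by a positive square wave of half the
    frequency (sin(x/2) > 0): sinusoidal lobes in [0, 1] alternating with
    flat-zero half-periods, so full disconnection is reachable.  The lobe
    rises from 0 at each gate boundary, keeping F continuous.  Period 4*pi.
    """
    x = np.asarray(raw_weight, dtype=float)
    gate = np.sin(x / 2.0) > 0.0
    return gain * gate * (1.0 - np.cos(x)) / 2.0


def relational_phase(
    phases: np.ndarray,
    couplings: np.ndarray,
    fallback: np.ndarray | None = None,
    tol: float = 1e-12,
) -> np.ndarray:
    """Relational phase phi_i = angle(sum_j K_ij exp(i(theta_j - theta_i))).

    When the complex sum for an oscillator has modulus below ``tol`` (e.g.
    all incoming couplings are zero) its angle is undefined; the entry from
    ``fallback`` (the previous relational phase) is kept instead.
    """
    phases = np.asarray(phases, dtype=float)
    k = np.asarray(couplings, dtype=float)
    if not np.all(np.isfinite(phases)):
        raise ValueError("non-finite phases")
    if np.any(k < 0) or np.any(np.diag(k) != 0):
        raise ValueError("couplings must be non-negative with zero diagonal")
    diff = phases[None, :] - phases[:, None]
    z = np.sum(k * np.exp(1j * diff), axis=1)
    phi = np.angle(z)
    degenerate = np.abs(z) < tol
    if np.any(degenerate):
        fb = np.zeros_like(phi) if fallback is None else np.asarray(fallback, dtype=float)
        phi = np.where(degenerate, fb, phi)
    return phi


def plasticity_level(phase_error, h1: float = H_DEFAULT, h2: float = H_DEFAULT):
    """Plastic activation p(x) in [0, 1] from the wrapped phase error.

    p = 0 for |x| < H1 (homeostatic region), ramps linearly on (H1, H2), and
    is 1 for |x| > H2.  With H1 = H2 the ramp degenerates to a step.
    """
    if h1 > h2:
        raise ValueError(f"H1={h1} must not exceed H2={h2}")
    x = np.abs(np.asarray(phase_error, dtype=float))
    if h2 == h1:
        return (x >= h1).astype(float)
    return np.clip((x - h1) / (h2 - h1), 0.0, 1.0)


def step_network(
    state: NetworkState,
    params: NetworkParams,
    inputs: np.ndarray,
    dt: float,
) -> NetworkState:
    """One forward-Euler step of the phase and weight dynamics.

    ``inputs`` are the sensory drives (I_3 must be 0: input reaches only the
    sensory oscillators).  Returns a new state with theta re-wrapped and phi,
    p recomputed; weights are exactly unchanged wherever p_i = 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > DT_STABILITY_BOUND:
        warnings.warn(
            f"dt={dt} exceeds the Euler stability bound {DT_STABILITY_BOUND}",
            stacklevel=2,
        )
    inputs = np.asarray(inputs, dtype=float)
    if not np.all(np.isfinite(inputs)):
        raise ValueError("non-finite sensory input")
    if inputs.shape != (N_OSC,) or inputs[2] != 0.0:
        raise ValueError("inputs must be length 3 with I_3 = 0")

    theta, dk = state.theta, state.dk
    k = params.couplings(dk)
    phi = relational_phase(theta, k, fallback=state.phi)
    p = plasticity_level(wrap_angle(phi - params.phi0), params.h1, params.h2)

    diff = theta[None, :] - theta[:, None]  # diff[i, j] = theta_j - theta_i
    dtheta = params.omega + inputs + np.sum(k * np.sin(diff), axis=1)
    ddk = params.eta * p[:, None] * np.sin(diff - params.phi0[:, None])

    new = NetworkState(
        theta=(theta + dt * dtheta) % (2.0 * np.pi),
        dk=np.where(p[:, None] > 0.0, dk + dt * ddk, dk),
    )
    k_new = params.couplings(new.dk)
    new.phi = relational_phase(new.theta, k_new, fallback=phi)
    new.p = plasticity_level(wrap_angle(new.phi - params.phi0), params.h1, params.h2)
    return new
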