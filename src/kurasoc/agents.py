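"""Agent container and parameter-document serialization.

An :class:`Agent` bundles the evolved controller (:class:`NetworkParams`)
and body (:class:`BodyParams`), plus optional *fixed* initial conditions
(used by the frozen-plasticity variants, whose weight configuration is a
snapshot rather than a random draw).  Agents round-trip through a JSON
parameter document with explicit field names; the package ships one evolved
reference agent under ``kurasoc/data`` so every analysis can run without
re-evolving.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .embodiment import BodyParams
from .network import NetworkParams, NetworkState

__all__ = ["Agent", "load_reference_agent"]


@dataclass
class Agent:
    net: NetworkParams
    body: BodyParams
    init_theta: np.ndarray | None = None
    init_dk: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def initial_state(self, rng: np.random.Generator) -> NetworkState:
        """Random initial network state, honouring any fixed components."""
        state = NetworkState.random(self.net, rng)
        if self.init_theta is not None:
            state = NetworkState(np.array(self.init_theta, dtype=float), state.dk)
        if self.init_dk is not None:
            state = NetworkState(state.theta, np.array(self.init_dk, dtype=float))
        return state

    def with_frozen_plasticity(
        self,
        dk: np.ndarray,
        theta: np.ndarray | None = None,
        label: str = "frozen",
    ) -> "Agent":
        """Copy with all plasticity rates zeroed and weights fixed to ``dk``."""
        net = replace(self.net, eta=np.zeros((3, 3)))
        meta = dict(self.meta)
        meta["variant"] = label
        return Agent(
            net=net,
            body=self.body,
            init_theta=None if theta is None else np.array(theta, dtype=float),
            init_dk=np.array(dk, dtype=float),
            meta=meta,
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "network": {
                "natural_frequencies_rad_s": self.net.omega.tolist(),
                "preferred_phase_relations_rad": self.net.phi0.tolist(),
                "plasticity_rates_per_s": self.net.eta.tolist(),
                "coupling_gains": self.net.alpha.tolist(),
                "h1_rad": self.net.h1,
                "h2_rad": self.net.h2,
            },
            "body": {
                "sensor_gains_rAlArBlB": self.body.sensor_gains.tolist(),
                "motor_bias_right_rad": self.body.phi_r,
                "motor_bias_left_rad": self.body.phi_l,
                "radius_units": self.body.radius,
            },
            "meta": self.meta,
        }
        if self.init_theta is not None:
            d["init_theta_rad"] = np.asarray(self.init_theta).tolist()
        if self.init_dk is not None:
            d["init_raw_weights"] = np.asarray(self.init_dk).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Agent":
        n, b = d["network"], d["body"]
        net = NetworkParams(
            omega=np.array(n["natural_frequencies_rad_s"]),
            phi0=np.array(n["preferred_phase_relations_rad"]),
            eta=np.array(n["plasticity_rates_per_s"]),
            alpha=np.array(n["coupling_gains"]),
            h1=n.get("h1_rad", 0.2 * np.pi),
            h2=n.get("h2_rad", 0.2 * np.pi),
        )
        body = BodyParams(
            sensor_gains=np.array(b["sensor_gains_rAlArBlB"]),
            phi_r=b["motor_bias_right_rad"],
            phi_l=b["motor_bias_left_rad"],
            radius=b.get("radius_units", 4.0),
        )
        return cls(
            net=net,
            body=body,
            init_theta=np.array(d["init_theta_rad"]) if "init_theta_rad" in d else None,
            init_dk=np.array(d["init_raw_weights"]) if "init_raw_weights" in d else None,
            meta=d.get("meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Agent":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_reference_agent() -> Agent:
    """The packaged evolved agent (GA provenance recorded in its meta)."""
    text = resources.files("kurasoc").joinpath("data/evolved_agent.json").read_text()
    return Agent.from_dict(json.loads(text))
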