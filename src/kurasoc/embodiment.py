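"""Simulated robot body, light environment, and the trial protocol.

The agent is a massless circular robot (radius 4 length-units) with two
diametrically opposed motors and two pairs of light sensors (right/left, one
pair per light type A/B) mounted on the body perimeter at +-pi/3 from the
heading.  Motor speeds are sinusoidal readouts of the effector oscillator's
relational phase; translational speed is the average of the motor speeds and
angular speed their difference over the body diameter.  Lights spawn at a
random distance in [100, 150] from the robot, pairs with a random angular
separation in [pi/2, 3pi/2] as seen from the robot; a blinking light is lit
with probability 0.15 on each control step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .network import NetworkParams, NetworkState, wrap_angle

__all__ = [
    "BodyParams",
    "Light",
    "WorldState",
    "TrialRecord",
    "TASK_KINDS",
    "sensor_inputs",
    "motor_speeds",
    "update_pose",
    "spawn_trial",
    "run_trial",
]

TASK_KINDS = ("A", "B", "A_blinkB", "B_blinkA", "AB")
CAPTURE_RADIUS = 16.0
NEAR_RADIUS = 16.0  # 4 x body radius, the fitness proximity band
TRIAL_S = 125.0
CAPTURE_TIMEOUT_S = 1250.0
SPAWN_DISTANCE = (100.0, 150.0)
SPAWN_SEPARATION = (np.pi / 2, 3 * np.pi / 2)


@dataclass
class BodyParams:
    """Morphology and sensorimotor constants.

    sensor_gains: per-channel gains [right-A, left-A, right-B, left-B],
        range [-8, 8] (evolved).
    phi_r, phi_l: motor bias phases (rad), range [0, 2pi] (evolved).
    The distance-falloff constants a = 0.03 and b = 100 and the motor gain 2
    are fixed.
    """

    sensor_gains: np.ndarray
    phi_r: float
    phi_l: float
    radius: float = 4.0
    sensor_angle: float = np.pi / 3
    motor_gain: float = 2.0
    falloff_a: float = 0.03
    falloff_b: float = 100.0

    def __post_init__(self) -> None:
        self.sensor_gains = np.asarray(self.sensor_gains, dtype=float)
        if self.sensor_gains.shape != (4,):
            raise ValueError("need 4 sensor gains: [rA, lA, rB, lB]")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if np.any(np.abs(self.sensor_gains) > 8 + 1e-9):
            raise ValueError("sensor gains outside [-8, 8]")


@dataclass
class Light:
    kind: str  # "A" or "B"
    x: float
    y: float
    blinking: bool = False
    lit: bool = True

    @property
    def type_index(self) -> int:
        return 0 if self.kind == "A" else 1


@dataclass
class WorldState:
    """Robot pose, lights and trial clock."""

    x: float = 0.0
    y: float = 0.0
    heading: float = 0.0
    lights: list = field(default_factory=list)
    t: float = 0.0

    @property
    def pose(self) -> np.ndarray:
        return np.array([self.x, self.y, self.heading])

    def light_distance(self, kind: str) -> float:
        for li in self.lights:
            if li.kind == kind:
                return float(np.hypot(li.x - self.x, li.y - self.y))
        return np.nan


def sensor_inputs(world: WorldState, body: BodyParams) -> np.ndarray:
    """Oscillator drives [I1, I2, 0]: summed per-type sensor activations.

    Each sensor's activation is cosine-tuned in the angle to the light
    (zero beyond |angle| > pi/2), falls off logistically with distance,
    and is scaled by its evolved gain; unlit (blinking-off) lights
    contribute nothing.
    """
    i = np.zeros(3)
    for light in world.lights:
        if not light.lit:
            continue
        t = light.type_index
        for side, sign in ((0, -1.0), (1, 1.0)):  # right, left
            ang = world.heading + sign * body.sensor_angle
            sx = world.x + body.radius * np.cos(ang)
            sy = world.y + body.radius * np.sin(ang)
            dx, dy = light.x - sx, light.y - sy
            d = np.hypot(dx, dy)
            alpha = wrap_angle(np.arctan2(dy, dx) - ang)
            if np.abs(alpha) <= np.pi / 2:
                v = 0.5 * (1.0 + np.cos(alpha)) / (1.0 + np.exp(body.falloff_a * (d - body.falloff_b)))
                i[t] += body.sensor_gains[2 * t + side] * v
    return i


def motor_speeds(phi3: float, body: BodyParams) -> tuple[float, float]:
    """Right/left motor speeds from the effector oscillator's relational phase."""
    mr = body.motor_gain * np.sin(phi3 - body.phi_r)
    ml = body.motor_gain * np.sin(phi3 - body.phi_l)
    return float(mr), float(ml)


def update_pose(pose: np.ndarray, mr: float, ml: float, dt: float, radius: float = 4.0) -> np.ndarray:
    """Massless differential-drive kinematics: v = (Mr+Ml)/2 along heading,
    angular speed (Mr-Ml)/diameter."""
    x, y, h = pose
    v = 0.5 * (mr + ml)
    w = (mr - ml) / (2.0 * radius)
    return np.array([x + dt * v * np.cos(h), y + dt * v * np.sin(h), (h + dt * w) % (2 * np.pi)])


def spawn_trial(
    rng: np.random.Generator,
    task_kind: str = "AB",
    pose: np.ndarray | None = None,
) -> WorldState:
    """New trial world: lights placed randomly relative to the robot pose.

    Distances ~ U[100, 150]; with two lights the angular separation seen
    from the robot is ~ U[pi/2, 3pi/2].  Blinking lights (the 'dummy' in the
    *_blink* tasks) start lit and are re-drawn each control step.
    """
    if task_kind not in TASK_KINDS:
        raise ValueError(f"unknown task kind {task_kind!r}; expected one of {TASK_KINDS}")
    if pose is None:
        pose = np.zeros(3)
    x0, y0 = float(pose[0]), float(pose[1])
    ang1 = rng.uniform(0.0, 2 * np.pi)

    def place(kind: str, ang: float, blinking: bool) -> Light:
        d = rng.uniform(*SPAWN_DISTANCE)
        return Light(kind=kind, x=x0 + d * np.cos(ang), y=y0 + d * np.sin(ang), blinking=blinking)

    lights = []
    if task_kind == "A":
        lights.append(place("A", ang1, False))
    elif task_kind == "B":
        lights.append(place("B", ang1, False))
    else:
        sep = rng.uniform(*SPAWN_SEPARATION)
        first, second = ("A", "B")
        blink_first = task_kind == "B_blinkA"
        blink_second = task_kind == "A_blinkB"
        lights.append(place(first, ang1, blink_first))
        lights.append(place(second, ang1 + sep, blink_second))
    return WorldState(x=x0, y=y0, heading=float(pose[2]), lights=lights, t=0.0)


@dataclass
class TrialRecord:
    """Outcome and (optional) traces of one trial."""

    steps: int
    dt: float
    d_init: float
    d_final: float
    near_fraction: float
    homeo_mean: float
    d_final_a: float
    d_final_b: float
    captured: int  # 0 = light A, 1 = light B, -1 = none
    decision: int  # +1 = light A, -1 = light B
    target: int
    blink_lit_fraction: float = np.nan  # fraction of blink draws that were lit
    meansin: np.ndarray | None = None
    theta: np.ndarray | None = None
    p: np.ndarray | None = None
    pose: np.ndarray | None = None
    dist: np.ndarray | None = None
    rec_stride: int = 1

    @property
    def duration(self) -> float:
        return self.steps * self.dt


def target_index(task_kind: str) -> int:
    """The fitness target light: the only light, or the non-blinking one."""
    return 1 if task_kind in ("B", "B_blinkA") else 0


def run_trial(
    agent,
    world: WorldState,
    mode: str = "fixed125",
    dt: float = 0.05,
    rng: np.random.Generator | None = None,
    state: NetworkState | None = None,
    target: int | None = None,
    record: str = "summary",
    rec_stride: int = 2,
    n_steps: int | None = None,
) -> TrialRecord:
    """Closed-loop simulation of a single trial.

    mode ``fixed125`` runs exactly 125 s; mode ``capture`` runs until the
    robot is within 16 units of a light or 1250 s elapse.  The network state
    is advanced in place (pass ``state`` to chain trials).  ``record`` is
    ``summary`` (aggregates + mean-activation trace), ``theta`` (adds phase
    traces at ``rec_stride``) or ``full`` (adds plasticity, pose and
    distance traces).

    The trial's *decision* is the captured light, otherwise the light type
    closer at trial end (ties broken by ``rng``).
    """
    if mode not in ("fixed125", "capture"):
        raise ValueError(f"unknown trial mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng()
    if state is None:
        state = NetworkState.random(agent.net, rng)
    if target is None:
        target = 0
    net, body = agent.net, agent.body
    if n_steps is None:
        n_steps = int(round((TRIAL_S if mode == "fixed125" else CAPTURE_TIMEOUT_S) / dt))
    capture_radius = 0.0 if mode == "fixed125" else CAPTURE_RADIUS

    nl = len(world.lights)
    lpos = np.array([[li.x, li.y] for li in world.lights], dtype=float).reshape(nl, 2)
    ltype = np.array([li.type_index for li in world.lights], dtype=np.int64)
    lblink = np.array([li.blinking for li in world.lights], dtype=np.bool_)
    blink_seed = int(rng.integers(2 ** 31))

    meansin = np.empty(n_steps)
    n_rec = (n_steps + rec_stride - 1) // rec_stride
    rec_theta = record in ("theta", "full")
    rec_full = record == "full"
    theta_out = np.empty((n_rec, 3)) if rec_theta else np.empty((0, 3))
    p_out = np.empty((n_rec, 3)) if rec_full else np.empty((0, 3))
    pose_out = np.empty((n_rec, 3)) if rec_full else np.empty((0, 3))
    dist_out = np.empty((n_rec, 2)) if rec_full else np.empty((0, 2))

    pose = world.pose.astype(float)
    out = _kernels.run_trial_kernel(
        net.omega, net.phi0, net.eta, net.alpha, net.h1, net.h2,
        body.sensor_gains, body.phi_r, body.phi_l, body.radius,
        body.sensor_angle, body.falloff_a, body.falloff_b, body.motor_gain,
        state.theta, state.dk, state.phi, state.p, pose,
        lpos, ltype, lblink, blink_seed,
        n_steps, dt, capture_radius, NEAR_RADIUS, target,
        meansin, theta_out, rec_theta, rec_stride,
        p_out, pose_out, dist_out, rec_full,
    )
    steps, d0, df, near, homeo, dfa_, dfb_, captured, blink_lit, blink_draws = out
    if not np.all(np.isfinite(state.theta)) or not np.all(np.isfinite(state.dk)):
        raise FloatingPointError("non-finite network state: simulation aborted")
    world.x, world.y, world.heading = pose
    world.t += steps * dt

    if captured >= 0:
        decision = +1 if captured == 0 else -1
    elif nl < 2 or dfb_ < 0:
        decision = +1 if ltype[0] == 0 else -1
    elif dfa_ < dfb_:
        decision = +1
    elif dfb_ < dfa_:
        decision = -1
    else:
        decision = int(rng.choice([-1, 1]))

    used = max(steps, 1)
    n_rec_used = (steps + rec_stride - 1) // rec_stride if steps else 0
    return TrialRecord(
        steps=steps,
        dt=dt,
        d_init=d0,
        d_final=df,
        near_fraction=near / used if steps else float(d0 < NEAR_RADIUS),
        homeo_mean=homeo / used if steps else 1.0,
        d_final_a=dfa_,
        d_final_b=dfb_,
        captured=captured,
        decision=decision,
        target=target,
        blink_lit_fraction=blink_lit / blink_draws if blink_draws else np.nan,
        meansin=meansin[:steps],
        theta=theta_out[:n_rec_used] if rec_theta else None,
        p=p_out[:n_rec_used] if rec_full else None,
        pose=pose_out[:n_rec_used] if rec_full else None,
        dist=dist_out[:n_rec_used] if rec_full else None,
        rec_stride=rec_stride,
    )
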