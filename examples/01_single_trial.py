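"""Run a short sequence of behavioural trials of the packaged evolved agent.

Spawns pairs of equal-intensity lights (types A and B) around the robot and
simulates the closed sensorimotor loop in capture mode: a trial ends when
the robot comes within 16 units of a light (or after 1250 s).  The network
state chains from trial to trial; early trials are exploratory while the
plastic weights settle, then the agent reaches its chosen light reliably.
"""

import numpy as np

import kurasoc as ks

rng = np.random.default_rng(0)
agent = ks.load_reference_agent()
state = agent.initial_state(rng)
world = ks.spawn_trial(rng, "AB")

for trial in range(8):
    if trial:
        world = ks.spawn_trial(rng, "AB", pose=world.pose)
    rec = ks.run_trial(agent, world, mode="capture", rng=rng, state=state)
    chosen = "A" if rec.decision == 1 else "B"
    outcome = f"captured after {rec.duration:6.1f} s" if rec.captured >= 0 \
        else "timed out"
    print(f"trial {trial}: chose {chosen}, {outcome} "
          f"(homeostasis {rec.homeo_mean:.2f})")

print("\nHomeostasis is the time-mean of 1 - p; it approaches 1 once a "
      "preference is in\nplace and plasticity falls silent - the state the "
      "fitness function selects for.")
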