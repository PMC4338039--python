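"""Sliding-window clustering of neurodynamic patterns.

Records the oscillator phases of a 60-trial situated run (7500 s), carves
them into 125 s windows slid by 25 s, summarizes each window by the joint
density of (sin(theta_1 - theta_3), sin(theta_2 - theta_3)) - an averaged
shifted histogram with 100 bins and 8 shifts - and correlates every window
pair.  Windows sharing a behavioural preference correlate strongly (block
structure); the decoupled network shows no such differentiated patterns.
"""

import numpy as np

import kurasoc as ks
from kurasoc.conditions import ConditionSpec, run_condition
from kurasoc.fractal import pattern_correlation

agent = ks.load_reference_agent()
for kind in ("situated", "decoupled"):
    spec = ConditionSpec(kind=kind, duration_s=7500.0, trial_mode="fixed125",
                         record_theta=True)
    res = run_condition(agent, spec, np.random.default_rng(4))
    starts, corr = pattern_correlation(res.theta, fs=res.theta_fs)
    off = corr[np.triu_indices_from(corr, k=1)]
    print(f"{kind:10s}: {corr.shape[0]} windows; off-diagonal pattern "
          f"correlation mean {off.mean():.2f}, sd {off.std():.2f}")
    if kind == "situated" and res.decisions.size:
        pref = res.decisions[np.minimum((starts // 125).astype(int),
                                        res.decisions.size - 1)]
        same = np.equal.outer(pref, pref)[np.triu_indices_from(corr, k=1)]
        print(f"            within-preference mean {off[same].mean():.2f} vs "
              f"between-preference {off[~same].mean():.2f} (block structure)")
print("\nA spread of strongly and weakly correlated windows = distinct "
      "transient patterns; uniformly similar windows = a single "
      "undifferentiated regime.")
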