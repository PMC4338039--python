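"""The SOC diagnostic battery on situated vs decoupled dynamics.

Simulates the evolved agent for 25000 s (a fifth of the study scale, for a
quick demonstration) in two conditions - the closed sensorimotor loop and
the decoupled network fed Gaussian sensor noise - and applies DFA, the Welch
spectral slope and the Morlet-CWT multifractal spectrum to the amplitude
envelope Phi of the mean network activation.  A situated agent shows a pink
noise exponent (beta near 1) together with a wide multifractal spectrum;
the decoupled network can mimic the 1/f slope but its spectrum width
collapses, exposing the false positive.
"""

import numpy as np

import kurasoc as ks
from kurasoc.pipeline import analyze_run, phi_run

agent = ks.load_reference_agent()
for kind in ("situated", "decoupled"):
    env = phi_run(agent, kind, seed=0, duration_s=25000.0)
    rep = analyze_run(env, dfa_fit=(10.0, 10 ** 2.5), welch_band=(1e-3, 1e-1),
                      condition=kind)
    print(f"{kind:10s}: beta_DFA = {rep.beta_dfa:+.2f}  "
          f"beta_PSD = {rep.beta_psd:+.2f}  delta_h = {rep.delta_h:.2f}")
print("\nbeta ~ 1 means 1/f (pink) noise; delta_h is the multifractal "
      "spectrum width - wide for interaction-dominant dynamics, near zero "
      "for a linear/component-dominant impostor.")
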