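"""Validate the fractal estimators on surrogates with known exponents.

White noise must give DFA alpha = 0.5 (beta = 0), its cumulative sum
alpha = 1.5 (brown, beta = 2); spectrally shaped 1/f noise must return its
target Welch slope; fractional Gaussian noise with Hurst H must give
alpha = H; and a binomial cascade must reproduce the closed-form
multifractal exponents h(q) = (tau(q)+1)/q with tau(q) = -log2(p^q+(1-p)^q).
"""

import numpy as np

from kurasoc.fractal import dfa, multifractal_spectrum, welch_slope
from kurasoc.surrogates import (
    binomial_cascade,
    cascade_hurst,
    fractional_gaussian_noise,
    powerlaw_noise,
    white_noise,
)

rng = np.random.default_rng(0)

w = white_noise(2 ** 18, rng)
print(f"white noise:        DFA alpha = {dfa(w, (10, 10**3)).alpha:.3f}   (theory 0.5)")
print(f"integrated white:   DFA alpha = {dfa(np.cumsum(w), (10, 10**3)).alpha:.3f}   (theory 1.5)")

p = powerlaw_noise(2 ** 18, 1.0, rng)
print(f"shaped 1/f noise:   Welch beta = {welch_slope(p, (1e-3, 1e-1)).beta:.3f}  (target 1.0)")

g = fractional_gaussian_noise(2 ** 17, 0.7, rng)
print(f"fGn (H = 0.7):      DFA alpha = {dfa(g, (10, 10**3)).alpha:.3f}   (theory 0.7)")
mono = multifractal_spectrum(g)
print(f"fGn spectrum width: delta_h = {mono.delta_h:.3f}        (monofractal: ~0)")

c = binomial_cascade(14, 0.75, rng)
mf = multifractal_spectrum(c)
theory = cascade_hurst(mf.q, 0.75)
err = np.max(np.abs(mf.h - theory)[(mf.q >= 1) & (mf.q <= 5)])
print(f"binomial cascade:   delta_h = {mf.delta_h:.3f}, max |h(q) - theory| = {err:.3f} for q in [1, 5]")
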