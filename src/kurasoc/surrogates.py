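"""Synthetic benchmark series with known scaling exponents.

These generators exist to validate the fractal estimators: every estimator in
:mod:`kurasoc.fractal` is required to recover the construction parameter of
the matching surrogate (white noise -> DFA alpha 0.5, shaped 1/f^beta noise ->
Welch slope beta, fractional Gaussian noise with Hurst exponent H -> alpha = H,
binomial cascades -> the closed-form multifractal exponents).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurrogateSpec",
    "white_noise",
    "powerlaw_noise",
    "fractional_gaussian_noise",
    "binomial_cascade",
    "cascade_tau",
    "cascade_hurst",
    "generate_surrogate",
]


def white_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. standard Gaussian samples (spectral exponent beta = 0)."""
    return rng.standard_normal(n)


def powerlaw_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^beta via spectral shaping.

    White noise is transformed in the Fourier domain by multiplying each
    positive-frequency amplitude by f^(-beta/2); the zero-frequency bin is
    nulled so the series has zero mean. beta = 1 gives pink noise, beta = 2
    brown noise. The output is rescaled to unit variance.
    """
    x = rng.standard_normal(n)
    xf = np.fft.rfft(x)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    y = np.fft.irfft(xf * shape, n=n)
    sd = y.std()
    if sd > 0:
        y /= sd
    return y


def fractional_gaussian_noise(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding (Davies-Harte).

    Returns a stationary Gaussian series whose cumulative sum is fractional
    Brownian motion with Hurst exponent ``hurst`` in (0, 1). Unit variance.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"Hurst exponent must be in (0,1), got {hurst}")
    k = np.arange(n + 1, dtype=float)
    # autocovariance of fGn increments, r(0) = 1
    r = 0.5 * (np.abs(k - 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + (k + 1) ** (2 * hurst))
    row = np.concatenate([r, r[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(row).real
    # tiny negative eigenvalues can appear from round-off; clip them
    lam = np.clip(lam, 0.0, None)
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam / (2.0 * m)) * z)
    return x.real[:n]


def binomial_cascade(depth: int, p: float = 0.75, rng: np.random.Generator | None = None) -> np.ndarray:
    """Conservative binomial multiplicative cascade of length 2**depth.

    Starting from unit mass, each interval is split in half and its mass is
    divided into fractions ``p`` and ``1-p``; which half receives the larger
    fraction is chosen at random (deterministic left-heavy split when ``rng``
    is None). The returned series is the mass per finest-level cell, so it
    sums to 1 at every depth.
    """
    if not 0.5 <= p < 1.0:
        raise ValueError(f"cascade weight p must be in [0.5, 1), got {p}")
    mass = np.array([1.0])
    for _ in range(depth):
        left = np.full(mass.size, p)
        if rng is not None:
            flip = rng.random(mass.size) < 0.5
            left[flip] = 1.0 - p
        out = np.empty(mass.size * 2)
        out[0::2] = mass * left
        out[1::2] = mass * (1.0 - left)
        mass = out
    return mass


def cascade_tau(q: np.ndarray | float, p: float = 0.75) -> np.ndarray:
    """Closed-form mass exponents tau(q) = -log2(p^q + (1-p)^q) of the cascade."""
    q = np.asarray(q, dtype=float)
    return -np.log2(p ** q + (1.0 - p) ** q)


def cascade_hurst(q: np.ndarray | float, p: float = 0.75) -> np.ndarray:
    """Generalized Hurst exponents h(q) = (tau(q) + 1)/q of the cascade."""
    q = np.asarray(q, dtype=float)
    return (cascade_tau(q, p) + 1.0) / q


@dataclass
class SurrogateSpec:
    """Declarative description of a benchmark series.

    kind: one of ``white``, ``pink``, ``brown``, ``fgn``, ``cascade``.
    length: number of samples (a power of two for spectral kinds; for
        ``cascade`` it must be an exact power of two and sets the depth).
    """

    kind: str
    length: int = 2 ** 16
    seed: int = 0
    hurst: float = 0.7
    cascade_p: float = 0.75
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"white", "pink", "brown", "fgn", "cascade"}:
            raise ValueError(f"unknown surrogate kind {self.kind!r}")
        if self.kind in {"pink", "brown", "cascade"} and (
            self.length & (self.length - 1) or self.length <= 0
        ):
            raise ValueError("length must be a power of two for spectral/cascade kinds")


def generate_surrogate(spec: SurrogateSpec) -> np.ndarray:
    """Generate the series described by ``spec`` (seeded, reproducible)."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "white":
        return white_noise(spec.length, rng)
    if spec.kind == "pink":
        return powerlaw_noise(spec.length, spec.beta if spec.beta is not None else 1.0, rng)
    if spec.kind == "brown":
        return powerlaw_noise(spec.length, spec.beta if spec.beta is not None else 2.0, rng)
    if spec.kind == "fgn":
        return fractional_gaussian_noise(spec.length, spec.hurst, rng)
    depth = int(np.log2(spec.length))
    return binomial_cascade(depth, spec.cascade_p, rng)
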