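"""Fractal / self-organized-criticality diagnostic battery.

The signal under analysis is the amplitude envelope Phi of the mean network
activation, Phi = |analytic((1/3) sum_i sin(theta_i))|.  The battery applies,
in tandem, estimators that together separate genuine scale-free dynamics from
false positives:

* detrended fluctuation analysis (DFA) -> scaling exponent alpha and the
  spectral equivalent beta = 2*alpha - 1;
* run-averaged Welch power spectra -> log-log slope beta;
* a Morlet continuous-wavelet multifractal spectrum -> generalized Hurst
  exponents h(q) and the spectrum width delta_h = h_max - h_min, the
  indicator of interaction-dominant (multiplicative) dynamics;
* the autocorrelation of the trial-by-trial decision series;
* sliding-window correlation of neurodynamic phase-portrait densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "EnvelopeSeries",
    "DFAResult",
    "SlopeResult",
    "MultifractalResult",
    "FractalReport",
    "amplitude_envelope",
    "dfa",
    "welch_psd",
    "welch_slope",
    "cwt_morlet",
    "multifractal_spectrum",
    "decision_autocorrelation",
    "preference_span",
    "ash_density_2d",
    "pattern_correlation",
]


# --------------------------------------------------------------------------
# envelope
# --------------------------------------------------------------------------

@dataclass
class EnvelopeSeries:
    """Amplitude envelope Phi with its sampling rate (Hz)."""

    values: np.ndarray
    fs: float
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("envelope must be one-dimensional")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    def decimated(self, factor: int) -> "EnvelopeSeries":
        """Anti-aliased decimation by an integer factor."""
        out = sps.decimate(self.values, factor, zero_phase=True)
        return EnvelopeSeries(out, self.fs / factor, self.source)


def amplitude_envelope(
    activation: np.ndarray,
    fs: float,
    out_fs: float | None = None,
    source: str = "",
) -> EnvelopeSeries:
    """Hilbert amplitude envelope of the mean network activation.

    Parameters
    ----------
    activation:
        Either the mean activation series (1/3) sum_i sin(theta_i) (1-D) or
        the raw phase traces theta with shape (n_samples, n_oscillators), in
        which case the mean of sin(theta) is taken first.
    fs:
        Sampling rate of ``activation`` in Hz.
    out_fs:
        Optional lower output rate; the envelope is computed at full
        resolution and then decimated (anti-aliased) by the integer factor
        fs/out_fs.
    """
    x = np.asarray(activation, dtype=float)
    if x.ndim == 2:
        x = np.mean(np.sin(x), axis=1)
    if x.ndim != 1:
        raise ValueError("activation must be 1-D or (n_samples, n_oscillators)")
    if x.size < 16:
        raise ValueError("series too short for envelope extraction")
    env = np.abs(sps.hilbert(x))
    series = EnvelopeSeries(env, fs, source)
    if out_fs is not None and out_fs < fs:
        q = fs / out_fs
        if abs(q - round(q)) > 1e-9:
            raise ValueError("fs/out_fs must be an integer decimation factor")
        series = series.decimated(int(round(q)))
    return series


# --------------------------------------------------------------------------
# DFA
# --------------------------------------------------------------------------

@dataclass
class DFAResult:
    alpha: float
    beta: float
    r2: float
    box_sizes: np.ndarray = field(repr=False)
    fluctuations: np.ndarray = field(repr=False)
    fit_range: tuple[float, float] = (0.0, 0.0)


def _loglog_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of log10 y vs log10 x -> (slope, intercept, R^2)."""
    lx, ly = np.log10(x), np.log10(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), float(r2)


def dfa(
    series: np.ndarray | EnvelopeSeries,
    fit_range: tuple[float, float],
    fs: float = 1.0,
    n_per_decade: int = 20,
    order: int = 1,
    min_boxes: int = 4,
) -> DFAResult:
    """Detrended fluctuation analysis with least-squares detrending.

    The series is integrated (cumulative sum of its mean-removed values) and
    divided into non-overlapping boxes of n samples; in each box the trend is
    a least-squares polynomial of the given order, and F(n) is the RMS
    deviation from it.  alpha is the slope of log F(n) vs log n over
    ``fit_range`` (given in seconds); beta = 2*alpha - 1.
    """
    if isinstance(series, EnvelopeSeries):
        fs = series.fs
        series = series.values
    x = np.asarray(series, dtype=float)
    n = x.size
    if np.ptp(x) == 0:
        raise ValueError("constant series: DFA slope undefined")
    lo_s, hi_s = fit_range
    lo = max(int(round(lo_s * fs)), order + 2)
    hi = int(round(hi_s * fs))
    if n // hi < min_boxes:
        raise ValueError(
            f"series too short: largest box {hi} samples needs >= {min_boxes} boxes"
        )
    n_decades = np.log10(hi / lo)
    sizes = np.unique(
        np.round(np.logspace(np.log10(lo), np.log10(hi), max(int(n_decades * n_per_decade), 2))).astype(int)
    )
    y = np.cumsum(x - x.mean())
    fluct = np.empty(sizes.size)
    for k, s in enumerate(sizes):
        nb = n // s
        seg = y[: nb * s].reshape(nb, s)
        t = np.arange(s, dtype=float)
        # vandermonde solve for all boxes at once
        v = np.vander(t, order + 1)
        coef, *_ = np.linalg.lstsq(v, seg.T, rcond=None)
        resid = seg.T - v @ coef
        fluct[k] = np.sqrt(np.mean(resid ** 2))
    slope, _, r2 = _loglog_fit(sizes / fs, fluct)
    return DFAResult(
        alpha=slope,
        beta=2.0 * slope - 1.0,
        r2=r2,
        box_sizes=sizes / fs,
        fluctuations=fluct,
        fit_range=fit_range,
    )


# --------------------------------------------------------------------------
# Welch spectral slope
# --------------------------------------------------------------------------

@dataclass
class SlopeResult:
    beta: float
    r2: float
    freqs: np.ndarray = field(repr=False)
    psd: np.ndarray = field(repr=False)
    fit_band: tuple[float, float] = (0.0, 0.0)


def welch_psd(
    series: np.ndarray | EnvelopeSeries,
    fs: float = 1.0,
    nperseg_frac: float = 1.0 / 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram (Hann window, 50% overlap, segments = frac of series)."""
    if isinstance(series, EnvelopeSeries):
        fs = series.fs
        series = series.values
    x = np.asarray(series, dtype=float)
    nperseg = max(int(x.size * nperseg_frac), 64)
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def welch_slope(
    runs: np.ndarray | EnvelopeSeries | list,
    fit_band: tuple[float, float],
    fs: float = 1.0,
    nperseg_frac: float = 1.0 / 8.0,
) -> SlopeResult:
    """Spectral exponent beta from a (run-averaged) Welch power spectrum.

    ``runs`` may be a single series or a list of independent runs; the
    periodograms are averaged across runs before the log-log fit.  beta is
    the negated slope over ``fit_band`` (Hz).
    """
    if isinstance(runs, (np.ndarray, EnvelopeSeries)):
        runs = [runs]
    psds = []
    f = None
    for run in runs:
        fi, pi = welch_psd(run, fs=fs, nperseg_frac=nperseg_frac)
        if f is None:
            f = fi
        elif fi.size != f.size or not np.allclose(fi, f):
            raise ValueError("runs must share length and sampling rate")
        psds.append(pi)
    psd = np.mean(psds, axis=0)
    lo, hi = fit_band
    if lo < f[1] or hi > f[-1]:
        raise ValueError(
            f"fit band [{lo}, {hi}] Hz outside resolvable range [{f[1]:.2e}, {f[-1]:.2e}]"
        )
    sel = (f >= lo) & (f <= hi) & (psd > 0)
    slope, _, r2 = _loglog_fit(f[sel], psd[sel])
    return SlopeResult(beta=-slope, r2=r2, freqs=f, psd=psd, fit_band=fit_band)


# --------------------------------------------------------------------------
# multifractal spectrum (Morlet CWT moments)
# --------------------------------------------------------------------------

def cwt_morlet(x: np.ndarray, scales: np.ndarray, omega0: float = 6.0) -> np.ndarray:
    """Continuous wavelet transform with the analytic Morlet mother wavelet.

    FFT implementation with L2 normalization: the wavelet at scale ``a`` (in
    samples) is psi_a(t) = a^(-1/2) psi(t/a), so the coefficient modulus of a
    self-affine signal with local exponent h scales as a^(h + 1/2).  Returns
    complex coefficients with shape (n_scales, n_samples).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    xf = np.fft.fft(x)
    w = 2.0 * np.pi * np.fft.fftfreq(n)
    out = np.empty((len(scales), n), dtype=complex)
    for i, a in enumerate(scales):
        psi_hat = np.pi ** -0.25 * np.exp(-0.5 * (a * w - omega0) ** 2) * (w > 0)
        out[i] = np.fft.ifft(xf * np.sqrt(a) * psi_hat)
    return out


@dataclass
class MultifractalResult:
    """Multifractal scaling estimates.

    h: generalized Hurst exponents h(q) = zeta(q)/q - 1/2 (q-order scaling
        of the structure functions; the quantity with closed-form cascade
        values).
    h_sing: local singularity exponents from the Legendre-consistent
        transform, d zeta/dq - 1/2; their spread across q measures how much
        the scaling of intermittent (large-|W|, low q ... high q) and
        laminar periods differ.
    delta_h: spectrum width h_sing_max - h_sing_min.
    """

    q: np.ndarray
    h: np.ndarray
    h_sing: np.ndarray
    delta_h: float
    r2: np.ndarray = field(repr=False)
    scales: np.ndarray = field(repr=False)

    @property
    def delta_h_hurst(self) -> float:
        """Width of the generalized-Hurst curve (always <= delta_h)."""
        return float(self.h.max() - self.h.min())


def multifractal_spectrum(
    series: np.ndarray | EnvelopeSeries,
    q_grid: np.ndarray | None = None,
    fs: float = 1.0,
    scale_range: tuple[float, float] | None = None,
    n_scales: int = 30,
    omega0: float = 6.0,
) -> MultifractalResult:
    """Multifractal spectrum of a series from Morlet-CWT moment scaling.

    The series is integrated to its profile, wavelet-transformed, and for
    each moment order q > 0 the structure function S_q(a) = mean_b |W(a,b)|^q
    is regressed against scale: S_q(a) ~ a^(zeta(q)).  Two families of
    exponents follow (both corrected by 1/2 for the L2 normalization): the
    generalized Hurst exponents h(q) = zeta(q)/q - 1/2 — a monofractal fGn
    with Hurst H yields h(q) = H for all q and a binomial cascade yields
    h(q) = (tau(q) + 1)/q — and the local singularity exponents from the
    Legendre-consistent transform, d zeta/dq - 1/2, whose spread over the q
    grid is the multifractal spectrum width delta_h.  For a monofractal both
    families are flat and delta_h ~ 0.

    Negative moments are excluded: CWT moduli near zeros of the transform
    make q < 0 estimates unstable.
    """
    if isinstance(series, EnvelopeSeries):
        fs = series.fs
        series = series.values
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant series: multifractal spectrum undefined")
    if q_grid is None:
        q_grid = np.arange(0.5, 10.01, 0.5)
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(q_grid <= 0):
        raise ValueError("q grid must be strictly positive")
    n = x.size
    if scale_range is None:
        a_min, a_max = 4.0, n / 16.0
    else:
        a_min, a_max = scale_range[0] * fs, scale_range[1] * fs
    if a_max <= a_min or a_max > n / 4:
        raise ValueError("series too short for the requested largest scale")
    scales = np.exp(np.linspace(np.log(a_min), np.log(a_max), n_scales))
    profile = np.cumsum(x - x.mean())
    coeffs = cwt_morlet(profile, scales, omega0=omega0)
    log_sq = np.empty((q_grid.size, scales.size))
    for i, a in enumerate(scales):
        edge = int(np.ceil(2.0 * a))
        mod = np.abs(coeffs[i, edge: n - edge])
        if mod.size < 8:
            raise ValueError("series too short for the largest scale after edge trim")
        lm = np.log(mod + 1e-300)
        for j, q in enumerate(q_grid):
            # moments via log-sum-exp for numerical range safety
            m = np.max(lm)
            log_sq[j, i] = m * q + np.log(np.mean(np.exp(q * (lm - m))))
    la = np.log(scales)
    zeta = np.empty(q_grid.size)
    r2 = np.empty(q_grid.size)
    for j, q in enumerate(q_grid):
        slope, intercept = np.polyfit(la, log_sq[j], 1)
        resid = log_sq[j] - (slope * la + intercept)
        ss = np.sum((log_sq[j] - log_sq[j].mean()) ** 2)
        r2[j] = 1.0 - np.sum(resid ** 2) / ss if ss > 0 else 0.0
        zeta[j] = slope
    h = zeta / q_grid - 0.5
    h_sing = np.gradient(zeta, q_grid) - 0.5  # Legendre-consistent local exponents
    return MultifractalResult(
        q=q_grid,
        h=h,
        h_sing=h_sing,
        delta_h=float(h_sing.max() - h_sing.min()),
        r2=r2,
        scales=scales / fs,
    )


# --------------------------------------------------------------------------
# decision autocorrelation
# --------------------------------------------------------------------------

def decision_autocorrelation(decisions: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Autocorrelation gamma(n) = sum_tau D(tau) D(tau+n) of a +-1 series.

    Returns ``(lags, gamma, gamma_norm)`` where lags runs from -(N-1) to N-1,
    gamma is the raw overlap sum (gamma(0) = N for +-1 series) and gamma_norm
    divides by the number of overlapping terms N - |n|.
    """
    d = np.asarray(decisions, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least two decisions")
    gamma = np.correlate(d, d, mode="full")
    lags = np.arange(-(n - 1), n)
    gamma_norm = gamma / (n - np.abs(lags))
    return lags, gamma, gamma_norm


def preference_span(decisions: np.ndarray, z: float = 2.0) -> int:
    """Longest initial run of lags with autocorrelation above the i.i.d. null.

    For an uncorrelated +-1 series the normalized autocorrelation at lag n
    has standard deviation ~ 1/sqrt(N - n); the null band is z times that.
    Returns the largest L such that gamma_norm(n) exceeds the band for every
    lag 1 <= n <= L — the average duration (in trials) of a behavioural
    preference.
    """
    d = np.asarray(decisions, dtype=float)
    n = d.size
    lags, _, gnorm = decision_autocorrelation(d)
    pos = gnorm[lags > 0]
    band = z / np.sqrt(n - np.arange(1, n))
    above = pos > band
    if not above[0]:
        return 0
    return int(np.argmin(above)) if not above.all() else int(above.size)


# --------------------------------------------------------------------------
# sliding-window neurodynamic pattern correlation
# --------------------------------------------------------------------------

def ash_density_2d(
    x: np.ndarray,
    y: np.ndarray,
    bins: int = 100,
    shifts: int = 8,
    extent: tuple[float, float] = (-1.0, 1.0),
) -> np.ndarray:
    """Averaged-shifted-histogram density estimate on a 2-D grid.

    The ASH averages ``shifts`` histograms whose bin origins are offset by
    bin_width/shifts, which is equivalent to a fine histogram with
    bins*shifts cells smoothed by a triangular kernel.  The fine estimate is
    block-averaged back to a ``bins`` x ``bins`` grid.
    """
    lo, hi = extent
    fine = bins * shifts
    hist, _, _ = np.histogram2d(x, y, bins=fine, range=[[lo, hi], [lo, hi]])
    kernel = 1.0 - np.abs(np.arange(-(shifts - 1), shifts)) / shifts
    kernel /= kernel.sum()
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 0, hist)
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, sm)
    coarse = sm.reshape(bins, shifts, bins, shifts).mean(axis=(1, 3))
    total = coarse.sum()
    if total > 0:
        cell = ((hi - lo) / bins) ** 2
        coarse = coarse / (total * cell)
    return coarse


def pattern_correlation(
    theta: np.ndarray,
    fs: float,
    window_s: float = 125.0,
    slide_s: float = 25.0,
    bins: int = 100,
    shifts: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix of sliding-window neurodynamic patterns.

    Each window of the phase traces is summarized by the joint density (ASH)
    of (sin(theta_1 - theta_3), sin(theta_2 - theta_3)) on [-1, 1]^2 — the
    phase portrait of the sensory oscillators relative to the effector.  The
    Pearson correlation between flattened densities of every window pair is
    returned together with the window start times (s).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[1] < 3:
        raise ValueError("theta must have shape (n_samples, >=3 oscillators)")
    w = int(round(window_s * fs))
    s = int(round(slide_s * fs))
    n = theta.shape[0]
    if n < w or w == 0:
        raise ValueError("traces shorter than one window")
    x = np.sin(theta[:, 0] - theta[:, 2])
    y = np.sin(theta[:, 1] - theta[:, 2])
    starts = np.arange(0, n - w + 1, s)
    dens = np.empty((starts.size, bins * bins))
    for i, st in enumerate(starts):
        dens[i] = ash_density_2d(x[st: st + w], y[st: st + w], bins, shifts).ravel()
    corr = np.corrcoef(dens)
    return starts / fs, corr


# --------------------------------------------------------------------------
# report container
# --------------------------------------------------------------------------

@dataclass
class FractalReport:
    """DFA / spectral / multifractal estimates for one condition."""

    condition: str
    dfa_alpha: float = np.nan
    beta_dfa: float = np.nan
    dfa_r2: float = np.nan
    dfa_fit_range: tuple[float, float] = (np.nan, np.nan)
    beta_psd: float = np.nan
    psd_r2: float = np.nan
    psd_fit_band: tuple[float, float] = (np.nan, np.nan)
    h_q: np.ndarray | None = None
    q_grid: np.ndarray | None = None
    delta_h: float = np.nan

    def to_dict(self) -> dict:
        d = {
            "condition": self.condition,
            "dfa_alpha": self.dfa_alpha,
            "beta_dfa": self.beta_dfa,
            "dfa_r2": self.dfa_r2,
            "dfa_fit_range": list(self.dfa_fit_range),
            "beta_psd": self.beta_psd,
            "psd_r2": self.psd_r2,
            "psd_fit_band": list(self.psd_fit_band),
            "delta_h": self.delta_h,
        }
        if self.h_q is not None:
            d["h_q"] = list(np.asarray(self.h_q))
            d["q_grid"] = list(np.asarray(self.q_grid))
        return d
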