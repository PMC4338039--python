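"""Optional matplotlib figures for the diagnostic battery.

Thin helpers over the analysis results; matplotlib is imported lazily so the
core package has no hard plotting dependency (install the ``plot`` extra).
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_loglog_fit(result, path: str, title: str = "") -> None:
    """DFA fluctuation curve (or Welch spectrum) with its power-law fit."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    if hasattr(result, "box_sizes"):
        x, y = result.box_sizes, result.fluctuations
        label = f"DFA alpha={result.alpha:.2f} (beta={result.beta:.2f})"
        ax.set_xlabel("box size n (s)")
        ax.set_ylabel("F(n)")
    else:
        sel = result.psd > 0
        x, y = result.freqs[sel], result.psd[sel]
        label = f"Welch beta={result.beta:.2f}"
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("power")
    ax.loglog(x, y, ".", ms=3, label=label)
    ax.legend()
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_multifractal(result, path: str, title: str = "") -> None:
    """Generalized Hurst exponents h(q) with the spectrum width annotated."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(result.q, result.h, "o-", ms=4)
    ax.set_xlabel("moment order q")
    ax.set_ylabel("h(q)")
    ax.set_title(title or f"delta_h = {result.delta_h:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pattern_matrix(starts: np.ndarray, corr: np.ndarray, path: str, title: str = "") -> None:
    """Window-by-window neurodynamic pattern correlation heatmap."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(corr, vmin=0, vmax=1, cmap="gray",
                   extent=[starts[0], starts[-1], starts[-1], starts[0]])
    ax.set_xlabel("window start (s)")
    ax.set_ylabel("window start (s)")
    fig.colorbar(im, ax=ax, label="pattern correlation")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectory(record, path: str, title: str = "") -> None:
    """Robot path of a fully recorded trial, with the light positions."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(record.pose[:, 0], record.pose[:, 1], lw=0.8)
    ax.plot(record.pose[0, 0], record.pose[0, 1], "ko", ms=5, label="start")
    ax.set_aspect("equal")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
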