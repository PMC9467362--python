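"""Convenience plots: band-speed / settling-window traces and settlement bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["plot_band_speed", "plot_settlement"]


def plot_band_speed(times, series, windows=None, threshold=4.0, path=None):
    """Band speed over one period with settling windows highlighted."""
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(times, series, color="k", lw=1.5, label="band speed")
    ax.axhline(threshold, color="0.4", ls="--", lw=1,
               label=f"threshold {threshold:g} mm/s")
    if windows is not None:
        for a, b in windows.intervals:
            ax.axvspan(a, b, color="gold", alpha=0.35)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("mean |U| in band [mm/s]")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_settlement(fractions: dict, path=None):
    """Bar chart of settlement percentage per substrate."""
    fig, ax = plt.subplots(figsize=(4, 3))
    names = list(fractions)
    vals = [fractions[n] for n in names]
    ax.bar(np.arange(len(names)), vals, color="steelblue")
    ax.set_xticks(np.arange(len(names)), names, rotation=20)
    ax.set_ylabel("settlement [%]")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
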