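"""Diagnostic polar histograms (phases: 18 bins; directions: 6 bins)."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def polar_histogram(angles, n_bins: int = 18, path=None, title: str = ""):
    """Polar histogram of angles on [-π, π); saves to ``path`` if given."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(np.angle(np.exp(1j * np.asarray(angles))), bins=edges)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = (edges[:-1] + edges[1:]) / 2
    ax.bar(centers, counts, width=np.diff(edges), bottom=0.0,
           edgecolor="k", alpha=0.7)
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
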