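"""Figure helpers: per-cell profile tracings with their average, and the
two-group DAPI intensity histogram."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .nucleus import GroupComparison
from .profiles import AxialProfile, ProfileEnsemble


def plot_profiles(
    profiles: list[AxialProfile],
    ensemble: ProfileEnsemble | None = None,
    path: str | Path | None = None,
    color: str = "k",
    title: str = "",
):
    """Overlay normalized per-cell tracings; optionally add the average."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for p in profiles:
        ax.plot(p.positions, p.values_norm, color=color, alpha=0.15, lw=0.6)
    if ensemble is not None:
        ax.plot(ensemble.positions, ensemble.mean, color=color, lw=2.0,
                label=f"average (n={ensemble.n})")
        ax.legend(frameon=False, fontsize=8)
    ax.axhline(1.0, color="0.6", ls="--", lw=0.8)
    ax.set_xlabel("position along cell (fraction of length)")
    ax.set_ylabel("GFP intensity / initial-end intensity")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_dapi_histogram(cmp: GroupComparison, path: str | Path | None = None):
    """Side-by-side histogram of per-cell mean nucleus DAPI intensities."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    centers = (cmp.bin_edges[:-1] + cmp.bin_edges[1:]) / 2.0
    width = (cmp.bin_edges[1] - cmp.bin_edges[0]) * 0.42
    ax.bar(centers - width / 2, cmp.counts[0], width=width,
           label=f"{cmp.labels[0]} (n={cmp.n[0]})")
    ax.bar(centers + width / 2, cmp.counts[1], width=width,
           label=f"{cmp.labels[1]} (n={cmp.n[1]})")
    ax.set_xlabel("mean nucleus DAPI intensity (counts)")
    ax.set_ylabel("cells")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
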