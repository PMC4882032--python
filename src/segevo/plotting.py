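"""Figure export: evolutionary pathway panels and kymographs.

Rendering follows the conventions of the pathway figures: one panel per
saved stage; gap-gene profiles drawn at scale, each pair-rule module's
output normalized to unit maximum — except a lost module, which is drawn
unnormalized so it visibly dips below the loss threshold.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .network import Network, GAP_MODULES, EVE_MODULES, FTZ_MODULES
from .phenotype import module_is_lost
from .solver import solve_profiles

__all__ = ["plot_pathway", "plot_kymograph"]

_GAP_COLORS = {
    "hb_ant": "tab:blue", "hb_post": "tab:blue", "Kr": "tab:green",
    "kni": "tab:red", "gt_ant": "tab:orange", "gt_post": "tab:orange",
}
_PR_COLORS = {
    "eve2": "#444444", "eve37": "#7a0177", "eve46": "#0570b0", "eve5": "#cc4c02",
    "ftz15": "#66c2a4", "ftz27": "#41ae76", "ftz36": "#238b45", "ftz4zebra": "#005824",
}


def _draw_stage(ax_gap, ax_pr, network: Network, label: str) -> None:
    profiles, _ = solve_profiles(network)
    x = network.grid.positions
    for m in GAP_MODULES:
        ax_gap.plot(x, profiles[m].values, color=_GAP_COLORS[m], lw=1.5,
                    label=m if m not in ("hb_post", "gt_post") else None)
    ax_gap.set_ylabel("gap level")
    ax_gap.set_title(label, fontsize=9)

    modules = list(EVE_MODULES) + (list(FTZ_MODULES) if network.include_ftz else [])
    for m in modules:
        prof = profiles[m]
        lost = module_is_lost(prof, network.loss_threshold)
        v = prof.values if lost or prof.max == 0 else prof.values / prof.max
        ax_pr.plot(x, v, color=_PR_COLORS[m], lw=1.2,
                   ls="--" if m.startswith("ftz") else "-",
                   alpha=0.5 if lost else 1.0, label=m)
    ax_pr.axhline(network.loss_threshold, color="0.8", lw=0.8)
    ax_pr.set_ylabel("module (norm.)")
    ax_pr.set_xlabel("x (fraction EL)")


def plot_pathway(stages: Sequence[tuple[str, Network]], path: str | Path) -> Path:
    """Render one column of (gap, pair-rule) panels per stage.

    ``stages`` is a sequence of ``(label, network)`` pairs, typically the
    snapshots of a :class:`~segevo.evolution.Trajectory` reconstructed with
    :func:`segevo.io.network_from_dict`.
    """
    stages = list(stages)
    if not stages:
        raise ValueError("no stages to plot")
    n = len(stages)
    fig, axes = plt.subplots(2, n, figsize=(3.2 * n, 4.6), sharex=True, squeeze=False)
    for k, (label, net) in enumerate(stages):
        _draw_stage(axes[0, k], axes[1, k], net, label)
    axes[1, -1].legend(fontsize=6, ncol=2, loc="upper right")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_kymograph(kymo, path: str | Path) -> Path:
    """Heat-map panels (time vs position) for each pair-rule gene."""
    genes = list(kymo.values)
    fig, axes = plt.subplots(1, len(genes), figsize=(3.0 * len(genes), 3.2),
                             sharey=True, squeeze=False)
    for k, g in enumerate(genes):
        ax = axes[0, k]
        ax.imshow(kymo.values[g], aspect="auto", origin="lower",
                  extent=(kymo.x[0], kymo.x[-1], kymo.times[0], kymo.times[-1]),
                  cmap="viridis")
        ax.set_title(g, fontsize=9)
        ax.set_xlabel("x (fraction EL)")
    axes[0, 0].set_ylabel("time")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
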