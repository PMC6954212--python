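"""Plot the data K function against the null-model simulation bands."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .spatial_stats import Envelope, KEstimate

__all__ = ["plot_k_with_envelopes"]

_BAND_COLORS = {
    "csr_ball": "tab:gray",
    "sphere": "tab:blue",
    "ring": "tab:orange",
    "two_rings": "tab:green",
}


def plot_k_with_envelopes(
    k: KEstimate,
    envelopes: Mapping[str, Envelope],
    path: str | Path,
    title: str | None = None,
) -> Path:
    """One panel per null model: its band (shaded) with the data K overlaid."""
    n_panels = max(len(envelopes), 1)
    fig, axes = plt.subplots(
        1, n_panels, figsize=(4.0 * n_panels, 3.4), sharey=True, squeeze=False
    )
    for ax, (kind, env) in zip(axes[0], envelopes.items()):
        color = _BAND_COLORS.get(kind, "tab:purple")
        ax.fill_between(
            env.r_grid, env.lo, env.hi, alpha=0.3, color=color,
            label=f"{env.level:.0%} band ({env.m_sims} sims)",
        )
        ax.plot(k.r_grid, k.k_hat, "k-", lw=1.5, label="data $\\hat{K}(r)$")
        ax.set_title(kind)
        ax.set_xlabel("r (nm)")
        ax.legend(fontsize=8)
    axes[0][0].set_ylabel("$K(r)$ (nm$^3$)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
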