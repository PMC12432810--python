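"""Minimal plotting helpers (tabular outputs are the primary interface)."""

from __future__ import annotations

import numpy as np

from .attenuation import AttenuationMatrix


def attenuation_heatmap(att: AttenuationMatrix, path) -> None:
    """Effect-size heatmap of the attenuation screen, stars at q < 0.05."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    eff = att.effects
    sig = att.significant
    fig, ax = plt.subplots(
        figsize=(1 + 0.5 * eff.shape[1], 1 + 0.25 * eff.shape[0])
    )
    vmax = np.nanmax(np.abs(eff.to_numpy())) or 1.0
    im = ax.imshow(eff.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(eff.shape[1]), eff.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(eff.shape[0]), eff.index, fontsize=7)
    for i in range(eff.shape[0]):
        for j in range(eff.shape[1]):
            if bool(sig.iloc[i, j]):
                ax.text(j, i, "*", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="non-O effect (log2)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
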