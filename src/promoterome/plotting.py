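"""Basic plot helpers for positional densities and correlation heat maps."""

from __future__ import annotations

import pandas as pd

from .positional_enrichment import PositionalDensityResult


def plot_positional_density(result: PositionalDensityResult, path) -> None:
    """Foreground/background density curves with confidence bands and the
    called robust/permissive windows."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.fill_between(result.grid, result.fg_lo, result.fg_hi, alpha=0.3,
                    color="tab:blue")
    ax.fill_between(result.grid, result.bg_lo, result.bg_hi, alpha=0.3,
                    color="tab:red")
    ax.plot(result.grid, result.fg_fit, color="tab:blue", label="foreground")
    ax.plot(result.grid, result.bg_fit, color="tab:red", label="background")
    if result.permissive_window:
        ax.axvspan(*result.permissive_window, color="gold", alpha=0.15,
                   label="permissive")
    if result.robust_window:
        ax.axvspan(*result.robust_window, color="green", alpha=0.15,
                   label="robust")
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel("hits / window / bp")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_heatmap(corr: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(corr.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(corr.shape[1]), corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(corr.shape[0]), corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
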