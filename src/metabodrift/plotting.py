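"""Optional figure export: correlation heatmaps and sample-size curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stats import CorrelationResult


def plot_correlation_heatmap(result: CorrelationResult, path=None, cmap="RdBu_r"):
    """Cluster-ordered correlation heatmap; writes to ``path`` if given."""
    data = result.reordered()
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * data.shape[1]), max(4, 0.3 * data.shape[0]))
    )
    im = ax.imshow(data.to_numpy(dtype=float), vmin=-1, vmax=1, cmap=cmap)
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(data.shape[0]), data.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_sample_size_curve(curve, path=None):
    """Median accuracy with 95 % CI band per classifier versus sample size."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, sub in curve.groupby("classifier"):
        sub = sub.sort_values("size")
        ax.plot(sub["size"], sub["median"], marker="o", label=name)
        ax.fill_between(sub["size"], sub["ci_lo"], sub["ci_hi"], alpha=0.2)
    ax.set_xlabel("sample size")
    ax.set_ylabel("classification accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
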