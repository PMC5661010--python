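"""Score plots, contribution bars and group boxplots (matplotlib, Agg)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dapc import DAPCModel, _project
from .data_model import BucketTable

__all__ = ["plot_scores", "plot_contributions", "plot_group_boxes"]


def plot_scores(
    model: DAPCModel,
    table: BucketTable,
    labels: Mapping[str, str],
    path: str | Path,
    axes: tuple[int, int] = (0, 1),
) -> None:
    """Scatter of samples on two discriminant axes, one marker set per group."""
    Z = _project(model, table)
    a, b = axes
    fig, ax = plt.subplots(figsize=(5, 4.2))
    for grp in model.groups:
        idx = [i for i, s in enumerate(table.samples) if labels[s] == grp]
        if Z.shape[1] > 1:
            ax.scatter(Z[idx, a], Z[idx, b], label=grp, s=28, alpha=0.85)
        else:
            ax.scatter(Z[idx, a], np.zeros(len(idx)), label=grp, s=28, alpha=0.85)
    ax.set_xlabel(f"LD{a + 1}")
    ax.set_ylabel(f"LD{b + 1}" if Z.shape[1] > 1 else "")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_contributions(
    model: DAPCModel,
    annotation: Mapping[str, str],
    path: str | Path,
    n_top: int = 25,
) -> None:
    """Horizontal bar chart of the highest-contributing buckets."""
    order = np.argsort(model.var_contrib_total)[::-1][:n_top]
    names = []
    for i in order:
        bid = model.bucket_ids[i]
        met = annotation.get(bid)
        names.append(f"{bid} ({met})" if met else bid)
    fig, ax = plt.subplots(figsize=(6, 0.28 * len(order) + 1))
    ax.barh(range(len(order)), model.var_contrib_total[order][::-1])
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(names[::-1], fontsize=6)
    ax.set_xlabel("contribution to discrimination")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_group_boxes(
    table: BucketTable,
    labels: Mapping[str, str],
    bucket_id: str,
    path: str | Path,
) -> None:
    """Boxplot of one bucket per group: 25–75% box, 5–95% whiskers, median."""
    j = table.bucket_ids.index(bucket_id)
    groups = sorted(set(labels[s] for s in table.samples))
    data = [
        [table.values[i, j] for i, s in enumerate(table.samples) if labels[s] == g]
        for g in groups
    ]
    fig, ax = plt.subplots(figsize=(5, 3.6))
    ax.boxplot(data, tick_labels=groups, whis=(5, 95), showfliers=False)
    for k, vals in enumerate(data, start=1):
        ax.plot(np.full(len(vals), k), vals, "ks", ms=3, alpha=0.6)
    ax.set_ylabel("normalized intensity")
    ax.set_title(bucket_id, fontsize=9)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
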