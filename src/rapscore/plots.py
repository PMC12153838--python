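"""Basic figures: prevalence bars, Kaplan-Meier curves, co-occurrence graph."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .cohort import CohortSummary, SurvivalComparison, cooccurrence_graph


def prevalence_bars(control: CohortSummary, aberrant: CohortSummary, path) -> None:
    codes = list(aberrant.per_feature.index)
    x = np.arange(len(codes))
    fig, ax = plt.subplots(figsize=(11, 4))
    ax.bar(x - 0.2, control.per_feature["prevalence"], width=0.4, label=control.label or "control")
    ax.bar(x + 0.2, aberrant.per_feature["prevalence"], width=0.4, label=aberrant.label or "aberrant")
    ax.set_xticks(x, codes, rotation=60, fontsize=8)
    ax.set_ylabel("prevalence")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_plot(comparison: SurvivalComparison, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in comparison.km_curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=label)
    ax.set_xlabel("harvest age (years)")
    ax.set_ylabel("survival fraction")
    ax.set_ylim(0, 1.02)
    ax.legend(title=f"log-rank p = {comparison.p_value:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cooccurrence_plot(cooc, path, min_count: int = 1) -> None:
    g = cooccurrence_graph(cooc, min_count=min_count)
    pos = nx.circular_layout(g)
    sizes = [60 + 12 * g.nodes[n]["count"] for n in g]
    widths = [0.15 * g.edges[e]["weight"] for e in g.edges]
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx(g, pos=pos, ax=ax, node_size=sizes, width=widths, font_size=7)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
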