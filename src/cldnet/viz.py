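"""Static plotting helper: centrality point estimates with IQR error bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .robustness import RobustnessSummary


def plot_centrality_errorbars(
    point_estimates: dict[str, float],
    summary: RobustnessSummary,
    measure: str = "betweenness",
    path: str | None = None,
):
    """Horizontal bar chart of a centrality measure, variables sorted by
    value, with the mutation ensemble's interquartile range as error bars."""
    quartiles = summary.per_variable[measure]
    order = sorted(point_estimates, key=point_estimates.get)
    values = [point_estimates[v] for v in order]
    lower = [max(0.0, point_estimates[v] - quartiles[v][0]) for v in order]
    upper = [max(0.0, quartiles[v][2] - point_estimates[v]) for v in order]

    fig, ax = plt.subplots(figsize=(7, 0.28 * len(order) + 1.5))
    ax.barh(range(len(order)), values, xerr=[lower, upper], capsize=2,
            color="#4878a8", error_kw={"lw": 0.8})
    ax.set_yticks(range(len(order)), order, fontsize=7)
    ax.set_xlabel(f"{measure} centrality")
    ax.set_title(f"{measure} with IQR over {summary.n_replicates} mutated "
                 f"diagrams ({summary.n_mutations} mutations each)", fontsize=9)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
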