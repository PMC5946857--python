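"""Model/Results interface over the two-step marker discovery procedure.

``NSForest`` holds the data and parameters; ``fit()`` runs, for every
cluster, the instrumented one-vs-all random forest ranking followed by
stepwise single-tree selection, and returns an ``NSForestResults`` carrying
the marker sets, per-cluster rankings, failures, and reporting helpers
(summary table, marker heatmap, definition building).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ClusterAssignment,
    ClusterUnresolvableError,
    ExpressionMatrix,
    ForestParams,
    MarkerSet,
    SelectionParams,
    ValidationError,
    derive_cluster_seed,
)
from .definitions import CellTypeDefinition, SpecimenContext, build_definition
from .ranking import GeneRanking, rank_genes
from .selection import stepwise_select

__all__ = ["NSForest", "NSForestResults", "plot_marker_heatmap"]


class NSForest:
    """Necessary-and-sufficient marker discovery model for clustered
    expression data.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Non-negative genes x cells expression values (any consistent scale).
    clusters : ClusterAssignment
        One label per cell; >= 2 clusters of >= 2 cells.
    forest_params, selection_params
        Ranking-forest and stepwise-selection settings.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        clusters: ClusterAssignment,
        forest_params: ForestParams | None = None,
        selection_params: SelectionParams | None = None,
    ):
        ClusterAssignment.from_mapping(clusters.labels, matrix)  # cross-validate
        self.matrix = matrix
        self.clusters = clusters
        self.forest_params = forest_params or ForestParams()
        self.selection_params = selection_params or SelectionParams()

    @classmethod
    def from_dataframe(
        cls,
        expression: pd.DataFrame,
        clusters: Mapping[str, str] | pd.Series,
        **params,
    ) -> "NSForest":
        """Build from a genes x cells DataFrame and a cell -> label mapping."""
        matrix = ExpressionMatrix.from_frame(expression)
        if isinstance(clusters, pd.Series):
            clusters = clusters.astype(str).to_dict()
        assignment = ClusterAssignment.from_mapping(dict(clusters), matrix)
        return cls(matrix, assignment, **params)

    def fit(self, clusters: Sequence[str] | None = None) -> "NSForestResults":
        """Rank and select markers per cluster (sorted label order).

        Each cluster's forest seed derives from the base seed and the
        cluster label, so per-cluster results are independent of which
        other clusters are processed.
        """
        targets = list(clusters) if clusters is not None else self.clusters.cluster_ids
        unknown = set(targets) - set(self.clusters.cluster_ids)
        if unknown:
            raise ValidationError(f"unknown cluster(s): {sorted(unknown)}")
        marker_sets: dict[str, MarkerSet] = {}
        rankings: dict[str, GeneRanking] = {}
        failures: dict[str, ClusterUnresolvableError] = {}
        for cluster in sorted(targets):
            fp = ForestParams(
                n_trees=self.forest_params.n_trees,
                mtry=self.forest_params.mtry,
                bootstrap_size=self.forest_params.bootstrap_size,
                max_rank_levels=self.forest_params.max_rank_levels,
                seed=derive_cluster_seed(self.forest_params.seed, cluster),
            )
            ranking = rank_genes(self.matrix, self.clusters, cluster, fp)
            rankings[cluster] = ranking
            try:
                marker_sets[cluster] = stepwise_select(
                    self.matrix, self.clusters, cluster, ranking, self.selection_params
                )
            except ClusterUnresolvableError as exc:
                failures[cluster] = exc
        return NSForestResults(self, marker_sets, rankings, failures)


@dataclass
class NSForestResults:
    """Fitted marker sets with diagnostics and reporting."""

    model: NSForest
    marker_sets: dict[str, MarkerSet]
    rankings: dict[str, GeneRanking]
    failures: dict[str, ClusterUnresolvableError]

    def to_list(self) -> list[MarkerSet]:
        return [self.marker_sets[c] for c in sorted(self.marker_sets)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in sorted(self.marker_sets):
            m = self.marker_sets[c]
            rows.append(
                {
                    "cluster": c,
                    "n_markers": len(m.markers),
                    "positive_markers": ";".join(m.positive_markers),
                    "negative_markers": ";".join(m.negative_markers),
                    "score": m.score,
                    "genes_tested": m.n_candidates_tested,
                }
            )
        for c in sorted(self.failures):
            rows.append(
                {
                    "cluster": c,
                    "n_markers": 0,
                    "positive_markers": "",
                    "negative_markers": "",
                    "score": self.failures[c].best_score,
                    "genes_tested": self.failures[c].n_tested,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable per-cluster marker table."""
        df = self.to_frame()
        lines = [
            "Necessary-and-sufficient marker selection",
            f"  clusters resolved: {len(self.marker_sets)}"
            f" / {len(self.marker_sets) + len(self.failures)}",
            f"  total marker mentions: "
            f"{sum(len(m.markers) for m in self.marker_sets.values())}",
            "",
            df.to_string(index=False),
        ]
        if self.failures:
            lines.append("")
            lines.append(
                "unresolved clusters: "
                + ", ".join(f"{c} (best {e.best_score:.3f})" for c, e in sorted(self.failures.items()))
            )
        return "\n".join(lines)

    def build_definitions(
        self,
        contexts: Mapping[str, SpecimenContext],
        list_style: str = "all_and",
        colloquial_names: Mapping[str, str] | None = None,
    ) -> list[CellTypeDefinition]:
        """Assemble ontology-ready definitions for every resolved cluster.

        Clusters whose minimal set contains no positive marker are skipped:
        the naming grammar leads with a positively expressed gene, so an
        absence-only cluster cannot be named.
        """
        out = []
        for c in sorted(self.marker_sets):
            if not self.marker_sets[c].positive_markers:
                continue
            out.append(
                build_definition(
                    self.marker_sets[c],
                    contexts[c],
                    list_style=list_style,
                    colloquial_name=(colloquial_names or {}).get(c),
                )
            )
        return out

    def plot_marker_heatmap(self, path: str | None = None, ax=None):
        """Marker-by-cell heatmap, cells grouped by cluster, markers grouped
        by owning cluster (display uses log1p of expression)."""
        return plot_marker_heatmap(
            self.model.matrix, self.model.clusters, self.to_list(), path=path, ax=ax
        )


def plot_marker_heatmap(
    matrix: ExpressionMatrix,
    assignment: ClusterAssignment,
    marker_sets: Sequence[MarkerSet],
    path: str | None = None,
    ax=None,
):
    """Block-structured heatmap of selected markers across all cells.

    Cells are ordered by sorted cluster label; marker rows are grouped by
    owning cluster in the same order (a marker owned by two clusters is
    drawn once per owner).  Colour is log1p expression, display only.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    marker_rows: list[tuple[str, str]] = []
    for m in sorted(marker_sets, key=lambda m: m.target_cluster):
        for g in m.markers:
            if g not in matrix.gene_ids:
                raise ValidationError(f"marker {g!r} not present in matrix")
            marker_rows.append((m.target_cluster, g))
    if not marker_rows:
        raise ValidationError("no markers to plot")
    cell_order = sorted(matrix.cell_ids, key=lambda c: (assignment.labels[c], c))
    col_idx = [matrix.cell_index(c) for c in cell_order]
    row_idx = [matrix.gene_index(g) for _, g in marker_rows]
    data = np.log1p(matrix.values[np.ix_(row_idx, col_idx)])

    if ax is None:
        fig, ax = plt.subplots(
            figsize=(max(6, len(cell_order) / 60), max(4, len(marker_rows) / 4))
        )
    else:
        fig = ax.figure
    im = ax.imshow(data, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_yticks(range(len(marker_rows)))
    ax.set_yticklabels([f"{c}: {g}" for c, g in marker_rows], fontsize=6)
    boundaries = []
    labels_sorted = [assignment.labels[c] for c in cell_order]
    for i in range(1, len(labels_sorted)):
        if labels_sorted[i] != labels_sorted[i - 1]:
            boundaries.append(i - 0.5)
    for b in boundaries:
        ax.axvline(b, color="white", linewidth=0.5)
    ax.set_xlabel("cells (grouped by cluster)")
    ax.set_ylabel("markers (grouped by owning cluster)")
    fig.colorbar(im, ax=ax, label="log1p(expression)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
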