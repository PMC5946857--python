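"""Step 1: rank genes per cluster by split usage relative to candidacy.

For every target cluster, a one-vs-all random forest is trained and each
gene is scored by how often it was chosen as the branching criterion
divided by how often it was available as a sampled candidate, aggregated
jointly over the first ``max_rank_levels`` branching levels.  The score
lives in [0, 1]: a perfectly discriminative gene wins every impure node at
which it is drawn and scores 1.0.
"""
from __future__ import annotations

from dataclasses import dataclass

from .datatypes import (
    BinaryTarget,
    ClusterAssignment,
    ExpressionMatrix,
    ForestParams,
    ValidationError,
)
from .trees import count_feature_usage, fit_random_forest

__all__ = ["RankEntry", "GeneRanking", "binarize_labels", "rank_genes"]


@dataclass(frozen=True)
class RankEntry:
    gene: str
    usage_count: int
    candidacy_count: int
    score: float


@dataclass
class GeneRanking:
    """Ordered per-cluster gene ranking with its provenance parameters."""

    target_cluster: str
    entries: list[RankEntry]
    params: ForestParams

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.usage_count > e.candidacy_count:
                raise ValidationError(
                    f"gene {e.gene}: usage {e.usage_count} exceeds candidacy "
                    f"{e.candidacy_count}"
                )

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def top(self, k: int) -> list[str]:
        return self.genes[:k]

    def to_dict(self) -> dict:
        return {
            "target_cluster": self.target_cluster,
            "entries": [
                {
                    "gene": e.gene,
                    "usage": e.usage_count,
                    "candidacy": e.candidacy_count,
                    "score": e.score,
                }
                for e in self.entries
            ],
        }


def binarize_labels(assignment: ClusterAssignment, target: str) -> BinaryTarget:
    """One-vs-all partition: target-cluster cells vs everything else."""
    if target not in assignment.cluster_ids:
        raise ValidationError(
            f"unknown target cluster {target!r}; known: {assignment.cluster_ids}"
        )
    pos = tuple(c for c, lab in assignment.labels.items() if lab == target)
    neg = tuple(c for c, lab in assignment.labels.items() if lab != target)
    return BinaryTarget(target_cluster=target, positive_cells=pos, negative_cells=neg)


def rank_genes(
    matrix: ExpressionMatrix,
    assignment: ClusterAssignment,
    target: str,
    params: ForestParams,
) -> GeneRanking:
    """Train the instrumented one-vs-all forest and rank all genes.

    Ordering is score descending, then candidacy count descending (more
    evidence first), then gene id ascending — a total order, so rankings
    are bit-identical across runs with the same seed.

    The forest is grown only to ``params.max_rank_levels`` deep: nodes below
    the counted levels can never contribute to the usage statistics, so
    deeper growth would only add cost.
    """
    binary = binarize_labels(assignment, target)
    trees = fit_random_forest(
        matrix, binary, params, max_depth=params.max_rank_levels
    )
    counts = count_feature_usage(trees, params.max_rank_levels)
    entries = []
    for gene in matrix.gene_ids:
        usage, cand = counts.get(gene, (0, 0))
        score = usage / cand if cand else 0.0
        entries.append(RankEntry(gene, usage, cand, score))
    entries.sort(key=lambda e: (-e.score, -e.candidacy_count, e.gene))
    return GeneRanking(target_cluster=target, entries=entries, params=params)
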