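"""Core domain types: expression matrices, cluster assignments, parameter bundles.

The in-memory container for expression data is a dense genes x cells numpy
array with explicit identifier axes.  Values are whatever scale the caller
supplies (TPM, log counts, ...); the algorithms are scale-agnostic because
thresholds are learned from the data itself.  The only hard requirement is
non-negativity.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ClusterUnresolvableError",
    "ExpressionMatrix",
    "ClusterAssignment",
    "ForestParams",
    "SelectionParams",
    "BinaryTarget",
    "MarkerSet",
    "derive_cluster_seed",
]


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class ClusterUnresolvableError(RuntimeError):
    """No gene prefix produced a tree with a positive leaf for this cluster."""

    def __init__(self, cluster: str, best_score: float, n_tested: int):
        self.cluster = cluster
        self.best_score = best_score
        self.n_tested = n_tested
        super().__init__(
            f"cluster {cluster!r} not classifiable: best target score "
            f"{best_score:.4f} after testing {n_tested} ranked genes"
        )


def derive_cluster_seed(base_seed: int, cluster: str) -> int:
    """Per-cluster seed: base seed plus a stable 32-bit hash of the label.

    Stable across processes and platforms (CRC32, not Python's salted hash),
    so adding or removing one cluster never perturbs the others' results.
    """
    return int(base_seed + zlib.crc32(str(cluster).encode("utf-8"))) % (2**31)


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of non-negative expression values.

    Parameters
    ----------
    gene_ids : sequence of unique gene identifiers (rows)
    cell_ids : sequence of unique cell/nucleus identifiers (columns)
    values : array of shape (n_genes, n_cells), non-negative
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for axis_name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate {axis_name} ids: {dup[:5]}")
        if self.values.size and float(self.values.min()) < 0:
            g, c = np.unravel_index(int(np.argmin(self.values)), self.values.shape)
            raise ValidationError(
                f"negative expression value {self.values[g, c]} at gene "
                f"{self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}
        # cells x genes view used by the tree builders (C-contiguous copy)
        self._X = np.ascontiguousarray(self.values.T)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def cells_by_genes(self) -> np.ndarray:
        """(n_cells, n_genes) float array; the orientation the learners use."""
        return self._X

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def cell_index(self, cell_id: str) -> int:
        try:
            return self._cell_index[cell_id]
        except KeyError:
            raise KeyError(f"unknown cell id {cell_id!r}") from None

    def drop_constant_genes(self) -> "ExpressionMatrix":
        """Remove genes with zero variance across all cells (speed only)."""
        keep = self.values.max(axis=1) > self.values.min(axis=1)
        return ExpressionMatrix(
            [g for g, k in zip(self.gene_ids, keep) if k],
            list(self.cell_ids),
            self.values[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ClusterAssignment:
    """Mapping of every cell to exactly one cluster label.

    Labels are opaque text; at least two clusters, each with at least two
    member cells, are required for one-vs-all classification to be defined.
    """

    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}
        counts = pd.Series(list(self.labels.values())).value_counts()
        if len(counts) < 2:
            raise ValidationError("at least 2 distinct clusters are required")
        singletons = sorted(counts[counts < 2].index)
        if singletons:
            raise ValidationError(
                f"cluster(s) with fewer than 2 cells: {singletons}"
            )
        self.cluster_ids: list[str] = sorted(counts.index)

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, str], matrix: ExpressionMatrix
    ) -> "ClusterAssignment":
        """Validate a cell -> label mapping against a companion matrix."""
        missing = [c for c in matrix.cell_ids if c not in mapping]
        if missing:
            raise ValidationError(
                f"{len(missing)} cell(s) have no cluster label: "
                f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
            )
        known = set(matrix.cell_ids)
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValidationError(
                f"labels refer to unknown cell id(s): {unknown[:10]}"
            )
        return cls({c: mapping[c] for c in matrix.cell_ids})

    def members(self, cluster: str) -> list[str]:
        return [c for c, lab in self.labels.items() if lab == cluster]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out


@dataclass
class ForestParams:
    """Bagging and ranking parameters for the one-vs-all random forest.

    mtry and bootstrap_size default to the forest conventions: square root of
    the number of genes, and a bootstrap equal to the training-set size.  The
    ranking counts split usage and candidacy over the first
    ``max_rank_levels`` branching levels (root = level 1).
    """

    n_trees: int = 1000
    mtry: int | None = None
    bootstrap_size: int | None = None
    max_rank_levels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.max_rank_levels < 1:
            raise ValidationError("max_rank_levels must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValidationError("mtry must be >= 1")
        if self.bootstrap_size is not None and self.bootstrap_size < 1:
            raise ValidationError("bootstrap_size must be >= 1")

    def resolved_mtry(self, n_genes: int) -> int:
        m = self.mtry if self.mtry is not None else math.ceil(math.sqrt(n_genes))
        if m > n_genes:
            raise ValidationError(f"mtry={m} exceeds number of genes ({n_genes})")
        return m

    def resolved_bootstrap(self, n_cells: int) -> int:
        return self.bootstrap_size if self.bootstrap_size is not None else n_cells


@dataclass
class SelectionParams:
    """Stopping and scoring parameters for stepwise marker selection.

    The target-cluster score is the F_beta measure.  The ranked-gene prefix
    grows until the score reaches 1.0, fails to improve by more than
    ``epsilon`` for ``patience`` consecutive additions, or ``max_genes`` is
    reached; the returned set comes from the smallest prefix attaining the
    best recorded score.
    """

    beta: float = 1.0
    epsilon: float = 0.01
    patience: int = 2
    max_genes: int = 10
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValidationError("beta must be positive")
        if self.epsilon < 0:
            raise ValidationError("epsilon must be >= 0")
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.max_genes < 1:
            raise ValidationError("max_genes must be >= 1")

    def resolved_max_depth(self) -> int:
        return self.max_depth if self.max_depth is not None else self.max_genes


@dataclass
class BinaryTarget:
    """One-vs-all partition of cells for a single target cluster."""

    target_cluster: str
    positive_cells: tuple[str, ...]
    negative_cells: tuple[str, ...]

    def __post_init__(self) -> None:
        pos, neg = set(self.positive_cells), set(self.negative_cells)
        if pos & neg:
            raise ValidationError("positive and negative cell sets overlap")
        if not pos:
            raise ValidationError("target cluster has no cells")

    def mask(self, matrix: ExpressionMatrix) -> np.ndarray:
        """Boolean per-cell membership mask in matrix cell order."""
        pos = set(self.positive_cells)
        return np.fromiter(
            (c in pos for c in matrix.cell_ids), dtype=bool, count=matrix.n_cells
        )


@dataclass
class MarkerSet:
    """Minimal necessary-and-sufficient markers for one cluster.

    positive_markers are genes the cluster selectively expresses (decision
    path takes the "> threshold" side); negative_markers are genes it lacks
    ("<= threshold" side).  ``score`` is the target-cluster F-measure of the
    winning decision tree on the training data.
    """

    target_cluster: str
    positive_markers: list[str]
    negative_markers: list[str]
    thresholds: dict[str, float]
    score: float
    n_candidates_tested: int

    def __post_init__(self) -> None:
        overlap = set(self.positive_markers) & set(self.negative_markers)
        if overlap:
            raise ValidationError(f"markers with both directions: {sorted(overlap)}")
        if not self.positive_markers and not self.negative_markers:
            raise ValidationError("a marker set must contain at least one gene")
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError("score must lie in [0, 1]")

    @property
    def markers(self) -> list[str]:
        return list(self.positive_markers) + list(self.negative_markers)

    def to_dict(self) -> dict:
        return {
            "target_cluster": self.target_cluster,
            "positive_markers": list(self.positive_markers),
            "negative_markers": list(self.negative_markers),
            "thresholds": {g: float(t) for g, t in self.thresholds.items()},
            "score": float(self.score),
            "n_candidates_tested": int(self.n_candidates_tested),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MarkerSet":
        return cls(
            target_cluster=str(d["target_cluster"]),
            positive_markers=list(d["positive_markers"]),
            negative_markers=list(d["negative_markers"]),
            thresholds={str(g): float(t) for g, t in d["thresholds"].items()},
            score=float(d["score"]),
            n_candidates_tested=int(d["n_candidates_tested"]),
        )
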