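"""Planted-marker synthetic datasets for end-to-end validation.

The generator emulates the structure the method is designed to recover: a
clustered population of cells in which each cluster owns a small set (one
to five) of marker genes that are strongly expressed inside the cluster
and near-silent outside, on a background of exchangeable noise genes.
Counts are negative-binomial, the standard overdispersed family for
RNA-seq-like data, emitted on linear scale.

Two difficulty axes mirror what is seen in real cortical data:

* conjunctive clusters — transcriptomically similar subtypes that no single
  gene separates: each of the cluster's first two markers is shared with a
  distinct confounder cluster, so only the two-gene conjunction is
  perfectly specific;
* negative markers — genes expressed everywhere *except* the owning
  cluster, defining it by absence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ClusterAssignment, ExpressionMatrix, ValidationError

__all__ = ["SimulationConfig", "simulate_dataset", "permute_labels"]


@dataclass
class SimulationConfig:
    """Study conditions for the planted-marker simulator.

    markers_per_cluster may be an int (same for all clusters), an explicit
    per-cluster list, or a (lo, hi) tuple drawn uniformly per cluster.
    marker_mu_on / marker_mu_off are negative-binomial means inside/outside
    the owning cluster; dispersion is the NB size parameter (math.inf gives
    the Poisson limit).
    """

    n_clusters: int = 16
    cells_per_cluster: int | list[int] = 50
    n_noise_genes: int = 500
    markers_per_cluster: int | list[int] | tuple[int, int] = (1, 5)
    marker_mu_on: float = 50.0
    marker_mu_off: float = 1.0
    dispersion: float = 10.0
    conjunctive_fraction: float = 0.25
    negative_marker_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValidationError("need at least 2 clusters")
        if self.marker_mu_on <= self.marker_mu_off:
            raise ValidationError("marker_mu_on must exceed marker_mu_off")
        if self.marker_mu_off < 0:
            raise ValidationError("marker_mu_off must be >= 0")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if not 0 <= self.conjunctive_fraction <= 1:
            raise ValidationError("conjunctive_fraction must be in [0, 1]")
        if not 0 <= self.negative_marker_fraction <= 1:
            raise ValidationError("negative_marker_fraction must be in [0, 1]")
        if self.conjunctive_fraction > 0 and self.n_clusters < 3:
            raise ValidationError(
                "conjunctive clusters need n_clusters >= 3 (two confounders)"
            )

    def resolved_cells(self) -> list[int]:
        if isinstance(self.cells_per_cluster, int):
            sizes = [self.cells_per_cluster] * self.n_clusters
        else:
            sizes = list(self.cells_per_cluster)
        if len(sizes) != self.n_clusters or min(sizes) < 2:
            raise ValidationError("need >= 2 cells in each cluster")
        return sizes


def _nb_draw(
    rng: np.random.Generator, mu: float, size: float, shape: tuple[int, ...]
) -> np.ndarray:
    if mu == 0:
        return np.zeros(shape)
    if math.isinf(size):
        return rng.poisson(mu, size=shape).astype(float)
    p = size / (size + mu)
    return rng.negative_binomial(size, p, size=shape).astype(float)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ClusterAssignment, dict[str, dict[str, list[str]]]]:
    """Generate a planted-marker dataset.

    Returns the expression matrix (planted + noise genes), the cluster
    assignment, and the ground truth: for each cluster, its signed planted
    markers as ``{"positive": [...], "negative": [...]}``.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.resolved_cells()
    width = len(str(config.n_clusters))
    clusters = [f"C{i + 1:0{width}d}" for i in range(config.n_clusters)]

    mk = config.markers_per_cluster
    if isinstance(mk, int):
        n_markers = [mk] * config.n_clusters
    elif isinstance(mk, tuple):
        lo, hi = mk
        n_markers = [int(rng.integers(lo, hi + 1)) for _ in clusters]
    else:
        n_markers = list(mk)
        if len(n_markers) != config.n_clusters:
            raise ValidationError("markers_per_cluster list length mismatch")
    if min(n_markers) < 1:
        raise ValidationError("every cluster needs at least one marker")

    n_conj = int(round(config.conjunctive_fraction * config.n_clusters))
    conj = set(clusters[:n_conj])  # deterministic choice: first clusters
    for c in conj:  # a conjunction needs two genes
        n_markers[clusters.index(c)] = max(2, n_markers[clusters.index(c)])
    n_negm = int(round(config.negative_marker_fraction * config.n_clusters))
    # negative-marker clusters taken from the non-conjunctive tail
    neg_owners = set(clusters[config.n_clusters - n_negm :]) - conj

    cell_ids: list[str] = []
    labels: dict[str, str] = {}
    for c, n in zip(clusters, sizes):
        for j in range(n):
            cid = f"{c}_cell{j + 1:03d}"
            cell_ids.append(cid)
            labels[cid] = c
    cluster_of = np.repeat(np.arange(config.n_clusters), sizes)
    n_cells = len(cell_ids)

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth: dict[str, dict[str, list[str]]] = {c: {"positive": [], "negative": []} for c in clusters}

    others = {c: [d for d in clusters if d != c] for c in clusters}
    for ci, c in enumerate(clusters):
        # confounder clusters that co-express the first two markers
        confounders: list[str] = []
        if c in conj:
            pool = others[c]
            pick = rng.choice(len(pool), size=2, replace=False)
            confounders = [pool[int(p)] for p in pick]
        for j in range(n_markers[ci]):
            gene = f"MK_{c}_{j + 1}"
            gene_ids.append(gene)
            is_negative = c in neg_owners and j == n_markers[ci] - 1 and n_markers[ci] > 1
            on_clusters = {c}
            if c in conj and j < 2:
                on_clusters.add(confounders[j])
            if is_negative:
                # expressed everywhere except the owning cluster
                on = ~np.isin(cluster_of, [clusters.index(c)])
                truth[c]["negative"].append(gene)
            else:
                on = np.isin(cluster_of, [clusters.index(x) for x in on_clusters])
                truth[c]["positive"].append(gene)
            vals = np.empty(n_cells)
            vals[on] = _nb_draw(rng, config.marker_mu_on, config.dispersion, (int(on.sum()),))
            vals[~on] = _nb_draw(
                rng, config.marker_mu_off, config.dispersion, (int((~on).sum()),)
            )
            rows.append(vals)

    # exchangeable noise genes: per-gene mean, identical across clusters
    noise_mu = rng.uniform(0.1, 10.0, size=config.n_noise_genes)
    for g in range(config.n_noise_genes):
        gene_ids.append(f"NOISE_{g + 1:04d}")
        rows.append(_nb_draw(rng, float(noise_mu[g]), config.dispersion, (n_cells,)))

    matrix = ExpressionMatrix(gene_ids, cell_ids, np.vstack(rows))
    assignment = ClusterAssignment.from_mapping(labels, matrix)
    return matrix, assignment, truth


def permute_labels(assignment: ClusterAssignment, seed: int) -> ClusterAssignment:
    """Uniformly permute labels over cells; cluster sizes are preserved."""
    rng = np.random.default_rng(seed)
    cells = list(assignment.labels.keys())
    labs = list(assignment.labels.values())
    perm = rng.permutation(len(labs))
    return ClusterAssignment({c: labs[perm[i]] for i, c in enumerate(cells)})
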