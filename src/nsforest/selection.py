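"""Step 2: stepwise single-tree evaluation of ranked-gene prefixes.

Single decision trees are built on the top-1, top-2, top-3, ... ranked
genes, trained and scored on the full data (no bootstrap, no candidate
subsampling).  Two constraints distinguish these evaluation trees from
plain CART: each gene may be used by at most one internal node anywhere in
the tree, and the tree is scored on the target cluster only, via the
F_beta measure, rather than on overall accuracy.  The smallest prefix
attaining the best recorded score yields the necessary-and-sufficient
marker set; markers are the genes actually used by that winning tree, with
a sign per gene — positive ("selectively expresses") when the path toward
the target's cells takes the "> threshold" side, negative ("lacks
expression of") when it takes the "<= threshold" side.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    BinaryTarget,
    ClusterAssignment,
    ClusterUnresolvableError,
    ExpressionMatrix,
    ForestParams,
    MarkerSet,
    SelectionParams,
    ValidationError,
    derive_cluster_seed,
)
from .ranking import GeneRanking, binarize_labels, rank_genes
from .trees import DecisionNode, _choose_candidate, best_split_per_gene

__all__ = [
    "EvaluationTree",
    "f_measure",
    "build_constrained_tree",
    "evaluate_tree",
    "extract_marker_directions",
    "stepwise_select",
    "select_all_clusters",
]


@dataclass
class EvaluationTree:
    """A one-use-per-gene decision tree built from a ranked-gene prefix."""

    root: DecisionNode
    genes_available: tuple[str, ...]

    def __post_init__(self) -> None:
        used = [n.gene for n in self.root.walk() if not n.is_leaf]
        if len(used) != len(set(used)):
            raise ValidationError("a gene occurs in two internal nodes")
        stray = set(used) - set(self.genes_available)
        if stray:
            raise ValidationError(f"tree uses genes outside its prefix: {stray}")

    @property
    def genes_used(self) -> list[str]:
        """Genes at internal nodes, in the order of the ranked prefix."""
        used = {n.gene for n in self.root.walk() if not n.is_leaf}
        return [g for g in self.genes_available if g in used]


def f_measure(tp: int, fp: int, fn: int, beta: float = 1.0) -> float:
    """F_beta = (1+beta^2) tp / ((1+beta^2) tp + beta^2 fn + fp); 0 when tp=0."""
    if min(tp, fp, fn) < 0:
        raise ValidationError("confusion counts must be non-negative")
    if tp + fn < 1:
        raise ValidationError("target cluster is empty (tp + fn = 0)")
    if tp == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * tp / ((1 + b2) * tp + b2 * fn + fp)


def _grow_constrained(
    X: np.ndarray,
    y: np.ndarray,
    rows: np.ndarray,
    gene_ids: list[str],
    gene_pos: dict[str, int],
    unused: list[str],
    level: int,
    max_depth: int,
) -> DecisionNode:
    # `unused` is shared across the whole tree (one-use constraint is
    # tree-wide); depth-first growth consumes genes left subtree first.
    n_pos = int(y[rows].sum())
    n_neg = len(rows) - n_pos
    node = DecisionNode(level=level, class_counts=(n_pos, n_neg))
    if n_pos == 0 or n_neg == 0 or len(rows) < 2 or not unused or level > max_depth:
        return node
    cand_ids = list(unused)
    cand_idx = np.array([gene_pos[g] for g in cand_ids])
    best_gr, best_thr = best_split_per_gene(X[np.ix_(rows, cand_idx)], y[rows])
    chosen = _choose_candidate(best_gr, best_thr, cand_ids)
    if chosen is None:
        return node
    j, thr = chosen
    node.gene = cand_ids[j]
    node.threshold = thr
    node.candidates = tuple(cand_ids)
    unused.remove(node.gene)
    go_left = X[rows, cand_idx[j]] <= thr
    node.left = _grow_constrained(
        X, y, rows[go_left], gene_ids, gene_pos, unused, level + 1, max_depth
    )
    node.right = _grow_constrained(
        X, y, rows[~go_left], gene_ids, gene_pos, unused, level + 1, max_depth
    )
    return node


def build_constrained_tree(
    matrix: ExpressionMatrix,
    target: BinaryTarget,
    genes: list[str],
    params: SelectionParams,
) -> EvaluationTree:
    """Greedy gain-ratio tree on all cells with the one-use-per-gene rule.

    Every still-unused gene of ``genes`` is a candidate at every node.
    Leaves predict positive iff a strict majority of the training cells
    reaching them belong to the target cluster (ties predict negative).
    """
    if not genes:
        raise ValidationError("gene prefix must be non-empty")
    gene_pos = {g: matrix.gene_index(g) for g in genes}
    X = matrix.cells_by_genes
    y = target.mask(matrix)
    rows = np.arange(matrix.n_cells)
    root = _grow_constrained(
        X, y, rows, list(genes), gene_pos, list(genes), 1,
        params.resolved_max_depth(),
    )
    return EvaluationTree(root=root, genes_available=tuple(genes))


def _leaf_predicts_positive(node: DecisionNode) -> bool:
    n_pos, n_neg = node.class_counts
    return n_pos > n_neg


def _route(root: DecisionNode, x: np.ndarray, gene_pos: dict[str, int]) -> DecisionNode:
    node = root
    while not node.is_leaf:
        node = node.left if x[gene_pos[node.gene]] <= node.threshold else node.right
    return node


def evaluate_tree(
    tree: EvaluationTree,
    matrix: ExpressionMatrix,
    target: BinaryTarget,
    beta: float = 1.0,
) -> tuple[float, int, int, int]:
    """Route every cell; return (target F_beta, tp, fp, fn) on training data."""
    gene_pos = {
        n.gene: matrix.gene_index(n.gene) for n in tree.root.walk() if not n.is_leaf
    }
    X = matrix.cells_by_genes
    y = target.mask(matrix)
    pred = np.empty(matrix.n_cells, dtype=bool)
    for i in range(matrix.n_cells):
        pred[i] = _leaf_predicts_positive(_route(tree.root, X[i], gene_pos))
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    return f_measure(tp, fp, fn, beta), tp, fp, fn


def extract_marker_directions(
    tree: EvaluationTree,
) -> tuple[list[str], list[str], dict[str, float]]:
    """Signed markers from the paths to positively-predicting leaves.

    A gene on a root-to-positive-leaf path is a positive marker when the
    path takes the "> threshold" side at its node, negative when it takes
    the "<= threshold" side.  If positive leaves sit on both sides of a
    gene's node, the direction of the side covering the most positive
    training cells wins.  Marker order follows the ranked prefix.
    """
    # (gene, direction) -> positive training cells covered
    weight: dict[tuple[str, bool], int] = {}
    thresholds: dict[str, float] = {}
    found_positive_leaf = False

    def descend(node: DecisionNode, path: list[tuple[str, bool, float]]) -> None:
        nonlocal found_positive_leaf
        if node.is_leaf:
            if _leaf_predicts_positive(node):
                found_positive_leaf = True
                n_pos = node.class_counts[0]
                for gene, greater, thr in path:
                    key = (gene, greater)
                    weight[key] = weight.get(key, 0) + n_pos
                    thresholds[gene] = thr
            return
        descend(node.left, path + [(node.gene, False, node.threshold)])
        descend(node.right, path + [(node.gene, True, node.threshold)])

    descend(tree.root, [])
    if not found_positive_leaf:
        raise ClusterUnresolvableError("<tree>", 0.0, len(tree.genes_available))
    if not thresholds and found_positive_leaf:
        # root itself is a positive leaf: no decision was made at all
        raise ValidationError("tree has a positive leaf but no internal node")

    positive: list[str] = []
    negative: list[str] = []
    for gene in tree.genes_available:
        w_pos = weight.get((gene, True), 0)
        w_neg = weight.get((gene, False), 0)
        if w_pos == 0 and w_neg == 0:
            continue
        (positive if w_pos >= w_neg else negative).append(gene)
    return positive, negative, {g: thresholds[g] for g in positive + negative}


def stepwise_select(
    matrix: ExpressionMatrix,
    assignment: ClusterAssignment,
    target: str,
    ranking: GeneRanking,
    params: SelectionParams | None = None,
) -> MarkerSet:
    """Grow the ranked prefix until the target score is optimal and stable.

    For k = 1, 2, ...: build the constrained tree on the top-k genes and
    score it.  Stop at a perfect score, after ``patience`` consecutive
    additions that fail to improve the best score by more than ``epsilon``,
    or at ``max_genes``.  Return the marker set of the smallest k attaining
    the best recorded score.
    """
    params = params or SelectionParams()
    if ranking.target_cluster != target:
        raise ValidationError(
            f"ranking was computed for {ranking.target_cluster!r}, not {target!r}"
        )
    binary = binarize_labels(assignment, target)
    history: list[tuple[int, float, EvaluationTree]] = []
    best = -1.0
    stall = 0
    k_final = 0
    for k in range(1, params.max_genes + 1):
        prefix = ranking.top(k)
        if len(prefix) < k:
            break  # ranking exhausted
        tree = build_constrained_tree(matrix, binary, prefix, params)
        score, *_ = evaluate_tree(tree, matrix, binary, params.beta)
        history.append((k, score, tree))
        k_final = k
        if score > best + params.epsilon:
            best = score
            stall = 0
        else:
            stall += 1
        if score == 1.0 or stall >= params.patience:
            break
    best_score = max(s for _, s, _ in history)
    if best_score <= 0.0:
        raise ClusterUnresolvableError(target, best_score, k_final)
    k_win, score_win, tree_win = next(
        (k, s, t) for k, s, t in history if s == best_score
    )
    positive, negative, thresholds = extract_marker_directions(tree_win)
    return MarkerSet(
        target_cluster=target,
        positive_markers=positive,
        negative_markers=negative,
        thresholds=thresholds,
        score=score_win,
        n_candidates_tested=k_final,
    )


def select_all_clusters(
    matrix: ExpressionMatrix,
    assignment: ClusterAssignment,
    forest_params: ForestParams | None = None,
    selection_params: SelectionParams | None = None,
) -> tuple[list[MarkerSet], dict[str, ClusterUnresolvableError]]:
    """Rank and select markers for every cluster, in sorted label order.

    Per-cluster forests use seeds derived deterministically from the base
    seed and the cluster label, so results for one cluster are unaffected
    by the presence of others.  Unresolvable clusters are collected into
    the returned failure mapping rather than aborting the run.
    """
    forest_params = forest_params or ForestParams()
    selection_params = selection_params or SelectionParams()
    results: list[MarkerSet] = []
    failures: dict[str, ClusterUnresolvableError] = {}
    for cluster in assignment.cluster_ids:
        per_cluster = ForestParams(
            n_trees=forest_params.n_trees,
            mtry=forest_params.mtry,
            bootstrap_size=forest_params.bootstrap_size,
            max_rank_levels=forest_params.max_rank_levels,
            seed=derive_cluster_seed(forest_params.seed, cluster),
        )
        ranking = rank_genes(matrix, assignment, cluster, per_cluster)
        try:
            results.append(
                stepwise_select(matrix, assignment, cluster, ranking, selection_params)
            )
        except ClusterUnresolvableError as exc:
            failures[cluster] = exc
    return results, failures
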