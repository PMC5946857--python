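import numpy as np
import pytest
from hypothesis import settings

import nsforest as nf

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_sim():
    """Small planted dataset: 3 clusters x 20 cells, 30 noise genes."""
    config = nf.SimulationConfig(
        n_clusters=3,
        cells_per_cluster=20,
        n_noise_genes=30,
        markers_per_cluster=1,
        conjunctive_fraction=0.0,
        negative_marker_fraction=0.0,
        seed=42,
    )
    return nf.simulate_dataset(config)


@pytest.fixture(scope="session")
def conjunctive_data():
    """Hand-constructed conjunction: target = (A high AND B high).

    Four equal clusters of 15 cells: target T (A=10, B=10), confounder D1
    (A=10, B=0), confounder D2 (A=0, B=10), background D3 (A=0, B=0), plus
    four weakly-structured noise genes with values in {0, 5}.  No single
    gene separates T; the pair {A, B} does, perfectly.
    """
    rng = np.random.default_rng(7)
    blocks = {"T": (10.0, 10.0), "D1": (10.0, 0.0), "D2": (0.0, 10.0), "D3": (0.0, 0.0)}
    cell_ids, labels, a_vals, b_vals = [], {}, [], []
    for lab, (a, b) in blocks.items():
        for j in range(15):
            cid = f"{lab}_{j:02d}"
            cell_ids.append(cid)
            labels[cid] = lab
            a_vals.append(a)
            b_vals.append(b)
    noise = (rng.integers(0, 2, size=(4, 60)) * 5.0)
    values = np.vstack([a_vals, b_vals, noise])
    matrix = nf.ExpressionMatrix(
        ["A", "B", "N1", "N2", "N3", "N4"], cell_ids, values
    )
    assignment = nf.ClusterAssignment.from_mapping(labels, matrix)
    return matrix, assignment


def oracle_achievable(X, y, rows, avail):
    """All (tp, fp) pairs reachable by any one-use-per-gene tree over
    ``avail`` genes on the given cells, with freely chosen leaf labels.

    Exhaustive: every split gene, every midpoint threshold, every
    allocation of the remaining genes between the two subtrees.  Feasible
    only for tiny gene sets / few distinct values; serves as an
    independent optimum against which stepwise selection is compared.
    """
    n_pos = int(y[rows].sum())
    n_neg = len(rows) - n_pos
    results = {(0, 0), (n_pos, n_neg)}
    if n_pos + n_neg == 0:
        return {(0, 0)}
    for gi in avail:
        vals = np.unique(X[rows, gi])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            go_left = X[rows, gi] <= thr
            left, right = rows[go_left], rows[~go_left]
            rest = [g for g in avail if g != gi]
            for mask in range(1 << len(rest)):
                left_set = [g for k, g in enumerate(rest) if mask >> k & 1]
                right_set = [g for k, g in enumerate(rest) if not mask >> k & 1]
                for ltp, lfp in oracle_achievable(X, y, left, left_set):
                    for rtp, rfp in oracle_achievable(X, y, right, right_set):
                        results.add((ltp + rtp, lfp + rfp))
    return results


def oracle_best_f1(matrix, assignment, target, genes, max_size=3):
    """Best target-cluster F1 over all gene subsets of size <= max_size,
    and the minimal subset size attaining a perfect score (None if never)."""
    from itertools import combinations

    X = matrix.cells_by_genes
    y = nf.binarize_labels(assignment, target).mask(matrix)
    rows = np.arange(matrix.n_cells)
    idx = [matrix.gene_index(g) for g in genes]
    best = 0.0
    min_perfect = None
    for size in range(1, max_size + 1):
        for subset in combinations(idx, size):
            for tp, fp in oracle_achievable(X, y, rows, list(subset)):
                if tp == 0:
                    continue
                f1 = nf.f_measure(tp, fp, int(y.sum()) - tp)
                best = max(best, f1)
                if f1 == 1.0 and min_perfect is None:
                    min_perfect = size
        if min_perfect is not None:
            break
    return best, min_perfect
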