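import numpy as np
import pytest

import nsforest as nf
from nsforest.trees import DecisionNode, best_split_per_gene
from nsforest.trees import _choose_candidate


class TestFMeasure:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [(3, 1, 1, 0.75), (5, 0, 0, 1.0), (0, 0, 5, 0.0)],
    )
    def test_hand_computed(self, tp, fp, fn, expected):
        assert nf.f_measure(tp, fp, fn, beta=1.0) == pytest.approx(expected)

    def test_beta_weights_recall(self):
        # beta > 1 favours recall: fewer fn outweigh more fp
        assert nf.f_measure(8, 4, 0, beta=2.0) > nf.f_measure(8, 0, 4, beta=2.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(nf.ValidationError):
            nf.f_measure(-1, 0, 2)

    def test_empty_target_rejected(self):
        with pytest.raises(nf.ValidationError):
            nf.f_measure(0, 3, 0)


def separable_matrix():
    values = np.array([[9.0] * 5 + [1.0] * 7])
    cells = [f"c{i}" for i in range(12)]
    m = nf.ExpressionMatrix(["G"], cells, values)
    a = nf.ClusterAssignment({c: ("X" if i < 5 else "Y") for i, c in enumerate(cells)})
    return m, a


class TestBuildConstrainedTree:
    def test_single_separable_gene(self):
        m, a = separable_matrix()
        target = nf.binarize_labels(a, "X")
        tree = nf.build_constrained_tree(m, target, ["G"], nf.SelectionParams())
        assert not tree.root.is_leaf and tree.root.gene == "G"
        assert tree.root.left.is_leaf and tree.root.right.is_leaf
        score, tp, fp, fn = nf.evaluate_tree(tree, m, target)
        assert (score, tp, fp, fn) == (1.0, 5, 0, 0)

    def test_conjunction_needs_both_genes(self, conjunctive_data):
        matrix, assignment = conjunctive_data
        target = nf.binarize_labels(assignment, "T")
        pair = nf.build_constrained_tree(matrix, target, ["A", "B"], nf.SelectionParams())
        score2, *_ = nf.evaluate_tree(pair, matrix, target)
        assert score2 == 1.0
        assert sorted(pair.genes_used) == ["A", "B"]
        single = nf.build_constrained_tree(matrix, target, ["A"], nf.SelectionParams())
        score1, *_ = nf.evaluate_tree(single, matrix, target)
        assert score1 < 1.0

    def test_one_use_constraint_vs_unconstrained(self):
        # positives live in a middle band of gene A: plain CART reaches a
        # perfect classifier by splitting on A twice; the one-use rule cannot
        cells = [f"c{i}" for i in range(30)]
        vals = np.array([[0.0] * 10 + [50.0] * 10 + [100.0] * 10])
        m = nf.ExpressionMatrix(["A"], cells, vals)
        a = nf.ClusterAssignment(
            {c: ("X" if 10 <= i < 20 else "Y") for i, c in enumerate(cells)}
        )
        target = nf.binarize_labels(a, "X")
        constrained = nf.build_constrained_tree(m, target, ["A"], nf.SelectionParams())
        used = [n.gene for n in constrained.root.walk() if not n.is_leaf]
        assert used.count("A") == 1
        score_c, *_ = nf.evaluate_tree(constrained, m, target)

        def grow_unconstrained(rows, level):
            y = target.mask(m)
            n_pos = int(y[rows].sum())
            node = DecisionNode(level=level, class_counts=(n_pos, len(rows) - n_pos))
            if n_pos in (0, len(rows)) or len(rows) < 2 or level > 5:
                return node
            gr, thr = best_split_per_gene(m.cells_by_genes[rows][:, [0]], y[rows])
            chosen = _choose_candidate(gr, thr, ["A"])
            if chosen is None:
                return node
            node.gene, node.threshold = "A", chosen[1]
            go_left = m.cells_by_genes[rows, 0] <= node.threshold
            node.left = grow_unconstrained(rows[go_left], level + 1)
            node.right = grow_unconstrained(rows[~go_left], level + 1)
            return node

        unroot = grow_unconstrained(np.arange(30), 1)
        reuse = [n.gene for n in unroot.walk() if not n.is_leaf]
        assert reuse.count("A") == 2  # CART would reuse the gene
        assert score_c < 1.0  # the constrained tree cannot reach perfection


class TestEvaluateTree:
    def test_single_leaf_negative_tree(self):
        m, a = separable_matrix()
        target = nf.binarize_labels(a, "X")
        leaf = DecisionNode(level=1, class_counts=(5, 7))
        tree = nf.EvaluationTree(root=leaf, genes_available=("G",))
        score, tp, fp, fn = nf.evaluate_tree(tree, m, target)
        assert (score, tp, fp, fn) == (0.0, 0, 0, 5)

    def test_confusion_counts_reported(self):
        # threshold at 5 on a gene that misses one positive, catches one negative
        values = np.array([[9.0, 9.0, 9.0, 1.0, 9.0, 1.0, 1.0, 1.0]])
        cells = [f"c{i}" for i in range(8)]
        m = nf.ExpressionMatrix(["G"], cells, values)
        a = nf.ClusterAssignment({c: ("X" if i < 4 else "Y") for i, c in enumerate(cells)})
        target = nf.binarize_labels(a, "X")
        root = DecisionNode(
            level=1, class_counts=(4, 4), gene="G", threshold=5.0,
            left=DecisionNode(level=2, class_counts=(1, 3)),
            right=DecisionNode(level=2, class_counts=(3, 1)),
        )
        tree = nf.EvaluationTree(root=root, genes_available=("G",))
        score, tp, fp, fn = nf.evaluate_tree(tree, m, target)
        assert (tp, fp, fn) == (3, 1, 1)
        assert score == pytest.approx(0.75)


class TestExtractMarkerDirections:
    def test_positive_direction(self):
        m, a = separable_matrix()
        target = nf.binarize_labels(a, "X")
        tree = nf.build_constrained_tree(m, target, ["G"], nf.SelectionParams())
        pos, neg, thr = nf.extract_marker_directions(tree)
        assert pos == ["G"] and neg == []
        assert 1.0 < thr["G"] < 9.0

    def test_negative_direction_on_low_branch(self):
        # positives: SLC17A7 high AND KCNIP1 low
        slc = np.array([9.0] * 6 + [1.0] * 6)
        kcn = np.array([0.0] * 3 + [8.0] * 3 + [0.0] * 6)
        cells = [f"c{i}" for i in range(12)]
        m = nf.ExpressionMatrix(["SLC17A7", "KCNIP1"], cells, np.vstack([slc, kcn]))
        a = nf.ClusterAssignment({c: ("E" if i < 3 else "O") for i, c in enumerate(cells)})
        target = nf.binarize_labels(a, "E")
        tree = nf.build_constrained_tree(
            m, target, ["SLC17A7", "KCNIP1"], nf.SelectionParams()
        )
        pos, neg, thr = nf.extract_marker_directions(tree)
        assert pos == ["SLC17A7"] and neg == ["KCNIP1"]

    def test_positive_leaf_at_root_is_degenerate(self):
        root = DecisionNode(level=1, class_counts=(5, 2))
        tree = nf.EvaluationTree(root=root, genes_available=("G",))
        with pytest.raises(nf.ValidationError):
            nf.extract_marker_directions(tree)

    def test_no_positive_leaf_is_unresolvable(self):
        root = DecisionNode(level=1, class_counts=(2, 5))
        tree = nf.EvaluationTree(root=root, genes_available=("G",))
        with pytest.raises(nf.ClusterUnresolvableError):
            nf.extract_marker_directions(tree)


class TestStepwiseSelect:
    def test_perfect_gene_stops_at_one(self):
        m, a = separable_matrix()
        ranking = nf.rank_genes(m, a, "X", nf.ForestParams(n_trees=20, seed=0))
        ms = nf.stepwise_select(m, a, "X", ranking)
        assert ms.positive_markers == ["G"] and not ms.negative_markers
        assert ms.score == 1.0 and ms.n_candidates_tested == 1

    def test_conjunctive_pair_recovered_at_k2(self, conjunctive_data):
        matrix, assignment = conjunctive_data
        ranking = nf.rank_genes(
            matrix, assignment, "T",
            nf.ForestParams(n_trees=50, mtry=matrix.n_genes, seed=4),
        )
        assert ranking.top(2) == ["A", "B"]
        ms = nf.stepwise_select(matrix, assignment, "T", ranking)
        assert sorted(ms.markers) == ["A", "B"]
        assert ms.score == 1.0 and ms.n_candidates_tested == 2

    def test_mismatched_ranking_rejected(self, conjunctive_data):
        matrix, assignment = conjunctive_data
        ranking = nf.rank_genes(matrix, assignment, "T",
                                nf.ForestParams(n_trees=10, seed=0))
        with pytest.raises(nf.ValidationError):
            nf.stepwise_select(matrix, assignment, "D1", ranking)

    def test_noise_labels_stop_below_perfection(self):
        rng = np.random.default_rng(5)
        n_cells = 48
        values = rng.negative_binomial(5, 0.5, size=(12, n_cells)).astype(float)
        cells = [f"c{i}" for i in range(n_cells)]
        m = nf.ExpressionMatrix([f"G{i:02d}" for i in range(12)], cells, values)
        labels = rng.permutation(np.repeat(["X", "Y", "Z"], 16))
        a = nf.ClusterAssignment(dict(zip(cells, labels)))
        ranking = nf.rank_genes(m, a, "X", nf.ForestParams(n_trees=50, seed=5))
        params = nf.SelectionParams(max_genes=5)
        try:
            ms = nf.stepwise_select(m, a, "X", ranking, params)
            assert ms.score < 1.0
            assert ms.n_candidates_tested <= params.max_genes
        except nf.ClusterUnresolvableError as exc:
            assert exc.best_score < 1.0

    def test_minimality_single_perfect_gene_at_lower_rank(self):
        # the perfect gene enters only at rank 3; the returned set is size 1
        rng = np.random.default_rng(9)
        n = 30
        weak1 = rng.negative_binomial(5, 0.5, n).astype(float)
        weak2 = rng.negative_binomial(5, 0.5, n).astype(float)
        perfect = np.array([40.0] * 10 + [0.0] * 20) + rng.integers(0, 2, n)
        cells = [f"c{i}" for i in range(n)]
        m = nf.ExpressionMatrix(["W1", "W2", "PF"], cells,
                                np.vstack([weak1, weak2, perfect]))
        a = nf.ClusterAssignment({c: ("X" if i < 10 else "Y") for i, c in enumerate(cells)})
        ranking = nf.GeneRanking(
            target_cluster="X",
            entries=[
                nf.RankEntry("W1", 3, 4, 0.75),
                nf.RankEntry("W2", 2, 4, 0.5),
                nf.RankEntry("PF", 1, 4, 0.25),
            ],
            params=nf.ForestParams(n_trees=1, seed=0),
        )
        ms = nf.stepwise_select(m, a, "X", ranking, nf.SelectionParams(patience=3))
        assert ms.score == 1.0
        assert ms.markers == ["PF"]


class TestSelectAllClusters:
    def test_two_cluster_complementary(self):
        values = np.array([[9.0] * 5 + [1.0] * 7])
        cells = [f"c{i}" for i in range(12)]
        m = nf.ExpressionMatrix(["G"], cells, values)
        a = nf.ClusterAssignment({c: ("X" if i < 5 else "Y") for i, c in enumerate(cells)})
        results, failures = nf.select_all_clusters(
            m, a, nf.ForestParams(n_trees=20, seed=0), nf.SelectionParams()
        )
        assert not failures
        by_cluster = {r.target_cluster: r for r in results}
        assert by_cluster["X"].positive_markers == ["G"]
        assert by_cluster["Y"].negative_markers == ["G"]
        assert all(r.score == 1.0 for r in results)

    def test_planted_recovery_and_determinism(self, tiny_sim):
        matrix, assignment, truth = tiny_sim
        fp = nf.ForestParams(n_trees=60, seed=21)
        r1, f1 = nf.select_all_clusters(matrix, assignment, fp, nf.SelectionParams())
        r2, f2 = nf.select_all_clusters(matrix, assignment, fp, nf.SelectionParams())
        assert r1 == r2 and not f1 and not f2
        for ms in r1:
            planted = truth[ms.target_cluster]
            assert set(ms.positive_markers) <= set(planted["positive"])
            assert set(ms.negative_markers) <= set(planted["negative"])
            assert ms.score == 1.0
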