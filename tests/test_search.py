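import numpy as np
import pytest

from rnaphylo.phylo_ml import (
    PartitionedDataset,
    aicc,
    bootstrap,
    build_engine,
    concat_likelihood,
    concat_search,
    log_likelihood,
    majority_consensus,
    make_model,
    ml_search,
    model_select_aicc,
    nj_tree,
    read_newick,
    robinson_foulds,
)
from rnaphylo.synthetic_data import (
    SimulationConfig,
    clamp_min_branch,
    scale_tree,
    simulate_columns,
    simulate_yule_tree,
    tree_height,
)


def _rows_from(tree, model, n_sites, seed):
    codes, _ = simulate_columns(tree, model, n_sites, seed)
    return {k: "".join("ACGU"[c] for c in v) for k, v in codes.items()}


class TestNeighborJoining:
    def test_three_point_formulas(self):
        t = nj_tree(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        lengths = {n.label: n.length for n in t.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_matrix_recovered(self):
        # ((A:1,B:2):1,(C:3,D:4)) as an additive distance matrix
        labels = ["A", "B", "C", "D"]
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0.0],
        ])
        t = nj_tree(labels, D)
        expect = read_newick("((A:1,B:2):1,C:3,D:4);")
        assert robinson_foulds(t, expect) == 0
        # path lengths reproduce the input distances
        assert _path(t, "A", "B") == pytest.approx(3.0)
        assert _path(t, "C", "D") == pytest.approx(7.0)
        assert _path(t, "A", "D") == pytest.approx(6.0)

    def test_zero_matrix_star_like(self):
        t = nj_tree(["A", "B", "C", "D"], np.zeros((4, 4)))
        assert all(n.length == 0.0 for n in t.postorder() if n.length is not None)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(["A", "B"], np.zeros((2, 2)))

    def test_matches_skbio_topology(self, rng):
        """Independent oracle: scikit-bio's neighbour joining."""
        skbio = pytest.importorskip("skbio")
        n = 7
        labels = [f"t{i}" for i in range(n)]
        base = rng.uniform(0.2, 1.0, (n, n))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0.0)
        ours = nj_tree(labels, D)
        sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        sk_splits = set()
        all_leaves = frozenset(labels)
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                sk_splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        assert ours.bipartitions() == sk_splits


def _path(tree, a, b):
    depth = {}
    nodes = {}
    for node in tree.preorder():
        depth[id(node)] = (
            0.0 if node.parent is None
            else depth[id(node.parent)] + (node.length or 0.0)
        )
        if node.is_leaf:
            nodes[node.label] = node
    na, nb = nodes[a], nodes[b]
    anc_a = set()
    cur = na
    while cur is not None:
        anc_a.add(id(cur))
        cur = cur.parent
    cur = nb
    while id(cur) not in anc_a:
        cur = cur.parent
    return depth[id(na)] + depth[id(nb)] - 2 * depth[id(cur)]


class TestMLSearch:
    def test_recovers_clear_topology(self, jc):
        true = simulate_yule_tree(6, 1.0, 42)
        true = clamp_min_branch(
            scale_tree(true, 0.8 / tree_height(true)), 0.2
        )
        rows = _rows_from(true, jc, 1000, 7)
        best, lnl = ml_search(rows, jc, n_starts=2, walk_length=3, seed=1)
        assert robinson_foulds(best, true) == 0

    def test_degenerate_equals_plain_hill_climb(self, jc):
        true = simulate_yule_tree(5, 1.0, 3)
        rows = _rows_from(true, jc, 300, 3)
        t1, l1 = ml_search(rows, jc, n_starts=1, walk_length=0, seed=9)
        from rnaphylo.phylo_ml.search import hill_climb, p_distance_matrix

        labels, pmat = p_distance_matrix(rows)
        centre = nj_tree(labels, pmat)
        engine = build_engine(centre, rows, jc)
        engine.optimize_branch_lengths(max_sweeps=2)
        l2 = hill_climb(engine)
        assert robinson_foulds(t1, engine.tree) == 0
        assert l1 == pytest.approx(l2, abs=1e-6)

    def test_seed_determinism(self, jc):
        true = simulate_yule_tree(6, 1.0, 8)
        rows = _rows_from(true, jc, 400, 2)
        t1, l1 = ml_search(rows, jc, n_starts=3, walk_length=3, seed=5)
        t2, l2 = ml_search(rows, jc, n_starts=3, walk_length=3, seed=5)
        assert t1.to_newick() == t2.to_newick()
        assert l1 == l2

    def test_invalid_starts(self, jc):
        with pytest.raises(ValueError):
            ml_search({"a": "A", "b": "A"}, jc, n_starts=0)


class TestAICc:
    def test_formula(self):
        assert aicc(-1000, 10, 500) == pytest.approx(2020.450, abs=1e-3)

    def test_degenerate_sample_size_infinite(self):
        assert aicc(-10, 10, 11) == np.inf

    def test_jc_data_prefers_jc_family(self, jc):
        wins = 0
        for seed in range(5):
            true = simulate_yule_tree(5, 1.0, 100 + seed)
            true = scale_tree(true, 0.6 / tree_height(true))
            rows = _rows_from(true, jc, 1000, 300 + seed)
            fits = model_select_aicc(
                rows, true, presets=("JC", "GTR"), rate_variants=("+G", "+I+G")
            )
            best = fits[0]
            gtr_ig = next(f for f in fits if f.name == "GTR+I+G")
            wins += best.name.startswith("JC") and best.aicc < gtr_ig.aicc
        assert wins >= 4

    def test_nested_lnl_ordering(self, rng):
        rows = {k: "".join(rng.choice(list("ACGU"), 400)) for k in "ABCDE"}
        t = read_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1,E:0.3);")
        fits = {
            f.name: f
            for f in model_select_aicc(
                rows, t, presets=("HKY", "GTR"), rate_variants=("+G",)
            )
        }
        assert fits["GTR+G"].lnl >= fits["HKY+G"].lnl - 1e-6


class TestPartitioned:
    def test_two_identical_partitions_double_lnl(self, jc):
        rows = {"A": "ACGUACGU", "B": "ACGAACGU", "C": "GCGUACGA", "D": "ACCUACGU"}
        tree = read_newick("((A:0.1,B:0.1):0.1,C:0.2,D:0.15);")
        ds = PartitionedDataset([(rows, jc, 1.0), (rows, jc, 1.0)])
        assert concat_likelihood(ds, tree) == pytest.approx(
            2 * log_likelihood(tree, rows, jc), abs=1e-9
        )

    def test_multiplier_rate_time_identity(self, jc):
        rows1 = {"A": "ACGUACGU", "B": "ACGAACGU", "C": "GCGUACGA", "D": "ACCUACGU"}
        rows2 = {"A": "AAGUACGU", "B": "ACGAACGU", "C": "GCGUACGA", "D": "ACCUAAGU"}
        tree = read_newick("((A:0.1,B:0.1):0.1,C:0.2,D:0.15);")
        ds = PartitionedDataset([(rows1, jc, 2.0), (rows2, jc, 0.5)])
        doubled = _scaled(tree, 2.0)
        halved = _scaled(tree, 0.5)
        expect = log_likelihood(doubled, rows1, jc) + log_likelihood(
            halved, rows2, jc
        )
        assert concat_likelihood(ds, tree) == pytest.approx(expect, abs=1e-9)

    def test_taxon_mismatch_rejected(self, jc):
        rows1 = {"A": "ACGU", "B": "ACGU"}
        rows2 = {"A": "ACGU", "C": "ACGU"}
        with pytest.raises(ValueError, match="taxon"):
            PartitionedDataset([(rows1, jc, 1.0), (rows2, jc, 1.0)])

    def test_concat_search_recovers_shared_topology(self, jc):
        true = simulate_yule_tree(5, 1.0, 21)
        true = clamp_min_branch(scale_tree(true, 0.8 / tree_height(true)), 0.2)
        rows1 = _rows_from(true, jc, 500, 31)
        rows2 = _rows_from(true, jc, 500, 32)
        ds = PartitionedDataset([(rows1, jc, 1.0), (rows2, jc, 1.0)])
        best, lnl = concat_search(ds, n_starts=1, walk_length=0, seed=2)
        assert robinson_foulds(best, true) == 0


class TestBootstrapConsensus:
    def test_consensus_of_identical_trees(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);")
        cons = majority_consensus([t.copy() for _ in range(7)])
        assert robinson_foulds(cons, t) == 0
        supports = [n.support for n in cons.internal_nodes() if n.support]
        assert supports and all(s == 100.0 for s in supports)

    def test_majority_threshold(self):
        t1 = read_newick("((A,B),(C,D),E);")
        t2 = read_newick("((A,B),(C,E),D);")
        t3 = read_newick("((A,B),(D,E),C);")
        cons = majority_consensus([t1, t2, t3])
        assert cons.bipartitions() == {frozenset({"A", "B"})}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_consensus([])

    def test_bootstrap_deterministic_and_supported(self, jc):
        true = read_newick(
            "((A:0.1,B:0.1):0.6,(C:0.1,D:0.1):0.6,(E:0.1,F:0.1):0.6);"
        )
        rows = _rows_from(true, jc, 800, 13)
        t1, s1 = bootstrap(rows, jc, reps=10, seed=3, n_starts=1, walk_length=1)
        t2, s2 = bootstrap(rows, jc, reps=10, seed=3, n_starts=1, walk_length=1)
        assert s1 == s2 and t1.to_newick() == t2.to_newick()
        assert s1[frozenset({"A", "B"})] >= 90

    def test_zero_reps_rejected(self, jc):
        with pytest.raises(ValueError):
            bootstrap({"a": "A", "b": "A"}, jc, reps=0)


def _scaled(tree, factor):
    out = tree.copy()
    for n in out.postorder():
        if n.length is not None:
            n.length *= factor
    return out
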