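import math

import numpy as np
import pytest

from rnaphylo.phylo_ml import (
    build_engine,
    log_likelihood,
    make_gtr12,
    make_model,
    optimize_branch_lengths,
    optimize_model,
    read_newick,
)
from rnaphylo.seqstruct_align import LETTERS12, TwelveStateAlignment
from rnaphylo.synthetic_data import simulate_columns
from oracles import brute_force_log_likelihood, random_model, random_rooted_tree


class TestClosedForms:
    def test_identical_one_site_zero_branches(self, jc):
        t = read_newick("(A:0,B:0);")
        assert log_likelihood(t, {"A": "A", "B": "A"}, jc) == pytest.approx(
            math.log(0.25), abs=1e-12
        )

    def test_two_taxon_path_one(self, jc):
        t = read_newick("(A:0.4,B:0.6);")
        expect = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 / 3)))
        assert log_likelihood(t, {"A": "A", "B": "A"}, jc) == pytest.approx(
            expect, abs=1e-5
        )
        assert expect == pytest.approx(-2.18993, abs=1e-5)

    def test_long_branch_limit_is_product_of_freqs(self, rng):
        """As t -> inf the joint likelihood factorises into pi_x * pi_y."""
        m = random_model(4, rng, gamma=False, pinv=False)
        t = read_newick("(A:10,B:10);")
        rows = {"A": "ACGG", "B": "GUCA"}
        expect = sum(
            math.log(m.freqs["ACGU".index(x)] * m.freqs["ACGU".index(y)])
            for x, y in zip(rows["A"], rows["B"])
        )
        assert log_likelihood(t, rows, m) == pytest.approx(expect, abs=1e-4)


class TestPruningOracle:
    def test_matches_exhaustive_summation(self, rng):
        """Pruning equals brute-force internal-state summation (<=5 leaves)."""
        for i in range(25):
            n_states = 4 if i % 2 == 0 else 12
            n_leaves = int(rng.integers(2, 6 if n_states == 4 else 5))
            labels = [f"t{k}" for k in range(n_leaves)]
            tree = random_rooted_tree(labels, rng)
            model = random_model(n_states, rng)
            alphabet = "ACGU" if n_states == 4 else LETTERS12
            rows = {
                lab: "".join(rng.choice(list(alphabet), 4)) for lab in labels
            }
            assert log_likelihood(tree, rows, model) == pytest.approx(
                brute_force_log_likelihood(tree, rows, model), abs=1e-8
            )

    def test_gaps_and_ambiguity_handled(self, rng):
        tree = random_rooted_tree(["a", "b", "c"], rng)
        model = random_model(4, rng)
        rows = {"a": "A-RN", "b": "ACG-", "c": "AYGU"}
        assert log_likelihood(tree, rows, model) == pytest.approx(
            brute_force_log_likelihood(tree, rows, model), abs=1e-8
        )

    def test_invariant_to_rerooting(self, rng):
        model = random_model(4, rng)
        rows = {k: "".join(rng.choice(list("ACGU"), 30)) for k in "ABCDE"}
        t1 = read_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.25):0.05,E:0.4);")
        # same unrooted tree, different rooting
        t2 = read_newick("((C:0.3,D:0.25):0.05,(A:0.1,B:0.2):0.15,E:0.4);")
        t3 = read_newick("(A:0.1,B:0.2,(E:0.4,(C:0.3,D:0.25):0.05):0.15);")
        l1 = log_likelihood(t1, rows, model)
        assert log_likelihood(t2, rows, model) == pytest.approx(l1, abs=1e-10)
        assert log_likelihood(t3, rows, model) == pytest.approx(l1, abs=1e-10)

    def test_missing_taxon_in_tree_rejected(self, jc):
        t = read_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="missing"):
            log_likelihood(t, {"A": "A", "B": "A", "Z": "A"}, jc)


class TestBranchOptimisation:
    def test_recovers_known_divergence(self, jc):
        hits = 0
        for seed in range(10):
            true = read_newick("(A:0.15,B:0.15);")
            codes, _ = simulate_columns(true, jc, 10000, seed)
            rows = {
                k: "".join("ACGU"[c] for c in v) for k, v in codes.items()
            }
            start = read_newick("(A:0.05,B:0.05);")
            fitted, _ = optimize_branch_lengths(start, rows, jc)
            total = sum(
                n.length for n in fitted.postorder() if n.length is not None
            )
            hits += 0.27 <= total <= 0.33
        assert hits >= 9

    def test_idempotent_at_optimum(self, jc, rng):
        rows = {k: "".join(rng.choice(list("ACGU"), 200)) for k in "ABCD"}
        t = read_newick("((A:0.1,B:0.2):0.1,C:0.3,D:0.2);")
        t1, l1 = optimize_branch_lengths(t, rows, jc)
        t2, l2 = optimize_branch_lengths(t1, rows, jc)
        assert abs(l2 - l1) < 1e-6

    def test_lnl_monotone_across_sweeps(self, jc, rng):
        rows = {k: "".join(rng.choice(list("ACGU"), 100)) for k in "ABCDEF"}
        t = read_newick(
            "((A:0.5,B:0.01):0.2,(C:0.9,D:0.1):0.3,(E:0.2,F:0.2):0.1);"
        )
        engine = build_engine(t.copy(), rows, jc)
        prev = engine.lnl()
        for _ in range(5):
            cur = engine.optimize_branch_lengths(max_sweeps=1)
            assert cur >= prev - 1e-9
            prev = cur


class TestModelOptimisation:
    def test_alpha_recovery_moderate(self):
        m_true = make_model("JC", alpha=0.5)
        true = read_newick(
            "((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2,(E:0.3,F:0.3):0.2);"
        )
        codes, _ = simulate_columns(true, m_true, 3000, 77)
        rows = {k: "".join("ACGU"[c] for c in v) for k, v in codes.items()}
        fitted_tree, _ = optimize_branch_lengths(
            true, rows, make_model("JC", alpha=1.0)
        )
        model, _ = optimize_model(
            fitted_tree, rows, make_model("JC", alpha=1.0), max_sweeps=4
        )
        assert 0.3 <= model.alpha <= 0.8

    def test_exchangeability_recovery_direction(self):
        """Data simulated with a high transition rate should fit kappa > 1."""
        m_true = make_model("K80", rates={"kappa": 5.0})
        true = read_newick("((A:0.2,B:0.2):0.1,C:0.3,D:0.3);")
        codes, _ = simulate_columns(true, m_true, 2000, 5)
        rows = {k: "".join("ACGU"[c] for c in v) for k, v in codes.items()}
        model, _ = optimize_model(true, rows, make_model("K80"), max_sweeps=3)
        assert model.exchangeabilities[0, 2] > 2.0

    def test_nested_models_lnl_ordering(self, rng):
        """GTR contains HKY, so its optimised lnL can never be lower."""
        rows = {k: "".join(rng.choice(list("ACGU"), 300)) for k in "ABCD"}
        t = read_newick("((A:0.2,B:0.2):0.1,C:0.3,D:0.3);")
        from rnaphylo.phylo_ml.model import empirical_freqs

        freqs = empirical_freqs(list(rows.values()), "ACGU")
        hky, l_hky = optimize_model(
            t, rows, make_model("HKY", freqs=freqs), max_sweeps=4
        )
        gtr, l_gtr = optimize_model(
            t, rows, make_model("GTR", freqs=freqs), max_sweeps=4
        )
        assert l_gtr >= l_hky - 1e-6


class TestTwelveStateLikelihood:
    def test_twelve_state_alignment_accepted(self, rng):
        m = make_gtr12(alpha=0.8)
        tree = random_rooted_tree(["a", "b", "c"], rng)
        rows = {k: "".join(rng.choice(list(LETTERS12), 15)) for k in "abc"}
        aln = TwelveStateAlignment(sorted(rows), [rows[k] for k in sorted(rows)])
        assert np.isfinite(log_likelihood(tree, aln, m))

    def test_state_count_mismatch_rejected(self, rng, jc):
        tree = random_rooted_tree(["a", "b"], rng)
        rows = {"a": "AB", "b": "AB"}
        aln = TwelveStateAlignment(["a", "b"], ["AB", "AB"])
        with pytest.raises(ValueError, match="state"):
            log_likelihood(tree, aln, jc)
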