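import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaphylo.io_formats import SequenceRecord
from rnaphylo.structure_model import (
    HelixMotif,
    SecondaryStructure,
    annotate_domains,
    delimit_its2,
    detect_cbc,
    enumerate_suboptimal,
    find_motif,
    fold_max_pairs,
    pairs_from_dotbracket,
    select_by_template,
)
from oracles import enumerate_nested_structures, max_pairs_enumeration


class TestFolding:
    @pytest.mark.parametrize(
        "seq,expected_db,expected_pairs",
        [
            ("GGGAAACCC", "(((...)))", 3),
            ("AAAAA", ".....", 0),
            ("GAAAC", "(...)", 1),
        ],
    )
    def test_known_folds(self, seq, expected_db, expected_pairs):
        s = fold_max_pairs(seq, min_loop=3)
        assert s.dot_bracket == expected_db
        assert s.n_pairs == expected_pairs

    def test_gapped_input_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            fold_max_pairs("GA-AC")

    def test_structure_invariants_hold(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 25))
            seq = "".join(rng.choice(list("ACGU"), n))
            fold_max_pairs(seq).validate(strict_pairs=True)

    def test_matches_enumeration_oracle(self, rng):
        """Pair-count optimality against explicit structure enumeration."""
        for _ in range(60):
            n = int(rng.integers(1, 13))
            seq = "".join(rng.choice(list("ACGU"), n))
            assert fold_max_pairs(seq).n_pairs == max_pairs_enumeration(seq)

    def test_deterministic(self):
        s1 = fold_max_pairs("GCGCAAAGCGCAAAGC")
        s2 = fold_max_pairs("GCGCAAAGCGCAAAGC")
        assert s1.dot_bracket == s2.dot_bracket


class TestSuboptimalEnumeration:
    def test_delta_zero_gives_exactly_the_optima(self):
        subs = enumerate_suboptimal("GGGAAACCC", 0, 100)
        oracle = {
            s
            for s in enumerate_nested_structures("GGGAAACCC")
            if len(s) == max_pairs_enumeration("GGGAAACCC")
        }
        assert {s.pair_set for s in subs} == oracle

    def test_large_delta_includes_open_chain(self):
        subs = enumerate_suboptimal("GGGAAACCC", 10, 1000)
        assert any(s.n_pairs == 0 for s in subs)

    def test_candidate_cap(self):
        subs = enumerate_suboptimal("GGGAAACCC", 10, 3)
        assert len(subs) == 3

    def test_zero_cap_rejected(self):
        with pytest.raises(ValueError):
            enumerate_suboptimal("GGGAAACCC", 0, 0)

    def test_ordering(self):
        subs = enumerate_suboptimal("GGGAAACCC", 2, 1000)
        keys = [(-s.n_pairs, s.dot_bracket) for s in subs]
        assert keys == sorted(keys)


class TestTemplateSelection:
    def test_template_candidate_scores_one(self):
        cands = enumerate_suboptimal("GGGAAACCC", 1, 50)
        best, score = select_by_template(cands, cands[0].pair_set)
        assert score == 1.0 and best.pair_set == cands[0].pair_set

    def test_disjoint_candidate_scores_zero(self):
        open_chain = SecondaryStructure("GGGAAACCC", (None,) * 9)
        _, score = select_by_template([open_chain], frozenset({(0, 8)}))
        assert score == 0.0

    def test_partial_overlap_f1(self):
        # candidate shares 2 of 3 template pairs and has 3 own pairs -> 2/3
        template = frozenset({(0, 8), (1, 7), (2, 6)})
        cand = SecondaryStructure.from_dotbracket("GGGAAACCC", "(((...)))")
        other = SecondaryStructure("GGGAAACCC", (None,) * 9)
        tmpl23 = frozenset({(0, 8), (1, 7), (3, 5)})
        best, score = select_by_template([cand, other], tmpl23)
        assert best is cand
        assert score == pytest.approx(2 * 2 / (3 + 3))

    def test_empty_template_rejected(self):
        with pytest.raises(ValueError, match="template"):
            select_by_template(
                [SecondaryStructure("AAAA", (None,) * 4)], frozenset()
            )


class TestDomains:
    def test_two_exterior_stems_in_order(self):
        s = SecondaryStructure.from_dotbracket(
            "GAAACGGAAACCAA", "(...).((...)).", min_loop=3
        )
        ann = annotate_domains(s)
        assert [d[0] for d in ann.domains] == ["DI", "DII"]
        assert ann.domains[0][1:] == (0, 5)
        assert ann.domains[1][1:] == (6, 13)

    def test_all_unpaired_gives_empty_annotation(self):
        ann = annotate_domains(SecondaryStructure("ACGUA", (None,) * 5))
        assert ann.domains == []

    def test_domains_cover_all_exterior_paired_positions(self, small_family):
        for rec in small_family.records:
            struct = small_family.structures[rec.id]
            ann = annotate_domains(struct)
            covered = set()
            for _, s, e in ann.domains:
                covered |= set(range(s, e))
            paired = {i for i, j in enumerate(struct.pairs) if j is not None}
            assert paired <= covered

    def test_four_domain_family(self, small_family):
        for rec in small_family.records:
            ann = annotate_domains(small_family.structures[rec.id])
            assert len(ann.domains) == 4


class TestMotifs:
    def test_plain_match_position(self):
        (m,) = find_motif("GGCAGACC", "CAGAC")
        assert m.start == 3

    def test_iupac_degeneracy_y(self):
        pattern = "GGCAACGYGGUCUGC"
        hit_c = find_motif("AAGGCAACGCGGUCUGCAA", pattern)
        hit_u = find_motif("AAGGCAACGUGGUCUGCAA", pattern)
        assert hit_c and hit_u
        miss = find_motif("AAGGCAACGAGGUCUGCAA", pattern)
        assert not miss

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            find_motif("ACGU", "AXC")

    def test_single_stranded_context_excludes_paired(self):
        # hand-built: a pair overlapping the first CAGAC only
        struct = SecondaryStructure(
            "CAGACAAACAGAC",
            (6, None, None, None, None, None, 0, None, None, None, None,
             None, None),
            min_loop=3,
        )
        hits = find_motif(
            "CAGACAAACAGAC", "CAGAC", context="single-stranded",
            structure=struct,
        )
        assert [m.start for m in hits] == [9]

    def test_region_restriction(self):
        hits = find_motif("CAGACAAACAGAC", "CAGAC", region=(6, 13))
        assert [m.start for m in hits] == [9]


class TestCBC:
    def test_ostreidae_vs_gryphaeidae_di_triplet(self):
        rep = detect_cbc(HelixMotif("CGG", "CCG"), HelixMotif("CUC", "GAG"))
        assert rep.counts == {
            "unchanged": 1, "hemi-CBC": 0, "CBC": 2, "pairing-lost": 0,
        }

    def test_basal_stem_quadruplet(self):
        rep = detect_cbc(HelixMotif("AGCC", "GGCU"), HelixMotif("AGUC", "GACU"))
        assert rep.counts["CBC"] == 1 and rep.counts["unchanged"] == 3
        assert rep.categories[2] == "CBC"

    def test_identical_helices_all_unchanged(self):
        rep = detect_cbc(HelixMotif("CGG", "CCG"), HelixMotif("CGG", "CCG"))
        assert rep.counts["unchanged"] == 3

    def test_hemi_cbc(self):
        # G-C -> G-U : only one partner changed, still pairs
        rep = detect_cbc(HelixMotif("G", "C"), HelixMotif("G", "U"))
        assert rep.counts["hemi-CBC"] == 1

    def test_pairing_lost(self):
        rep = detect_cbc(HelixMotif("G", "C"), HelixMotif("G", "G"))
        assert rep.counts["pairing-lost"] == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            detect_cbc(HelixMotif("CG", "CG"), HelixMotif("CGG", "CCG"))

    def test_symmetric_between_valid_helices(self, rng):
        """Swapping the arguments swaps only the change direction."""
        pairs5 = ["AU", "UA", "GC", "CG", "GU", "UG"]
        for _ in range(50):
            a = [pairs5[i] for i in rng.integers(0, 6, 4)]
            b = [pairs5[i] for i in rng.integers(0, 6, 4)]
            ha = HelixMotif("".join(x[0] for x in a),
                            "".join(x[1] for x in reversed(a)))
            hb = HelixMotif("".join(x[0] for x in b),
                            "".join(x[1] for x in reversed(b)))
            assert detect_cbc(ha, hb).counts == detect_cbc(hb, ha).counts

    def test_invariant_under_joint_reversal(self):
        ha = HelixMotif("AGCC", "GGCU")
        hb = HelixMotif("AGUC", "GACU")
        # reversing both strands of both helices reverses position order only
        har = HelixMotif(ha.strand3, ha.strand5)
        hbr = HelixMotif(hb.strand3, hb.strand5)
        assert detect_cbc(ha, hb).counts == detect_cbc(har, hbr).counts


class TestDelimitIts2:
    def test_trims_between_flanks(self):
        rec = SequenceRecord(id="x", residues="AAAGCGGUCCCCAUAUCGG")
        out = delimit_its2(rec, "GCGGU", "AUAUC")
        assert out.residues == "CCCC"
        assert "its2=9..12" in out.description

    def test_missing_flank5(self):
        rec = SequenceRecord(id="x", residues="AAACCCCAUAUCGG")
        with pytest.raises(ValueError, match="5′ flank"):
            delimit_its2(rec, "GCGGU", "AUAUC")

    def test_adjacent_flanks_zero_length(self):
        rec = SequenceRecord(id="x", residues="AAAGCGGUAUAUCGG")
        with pytest.raises(ValueError, match="zero-length"):
            delimit_its2(rec, "GCGGU", "AUAUC")


@settings(derandomize=True, max_examples=60)
@given(seq=st.text(alphabet="ACGU", min_size=1, max_size=12))
def test_fold_equals_enumeration_property(seq):
    """Base-pair maximisation agrees with exhaustive enumeration (<=12 nt)."""
    assert fold_max_pairs(seq).n_pairs == max_pairs_enumeration(seq)


@settings(derandomize=True, max_examples=60)
@given(db=st.text(alphabet=".()", min_size=1, max_size=30))
def test_dotbracket_parser_rejects_or_roundtrips(db):
    try:
        pairs = pairs_from_dotbracket(db)
    except ValueError:
        # must be genuinely unbalanced
        assert db.count("(") != db.count(")") or _crosses_zero(db)
        return
    s = SecondaryStructure("A" * len(db), tuple(pairs), min_loop=0)
    assert s.dot_bracket == db


def _crosses_zero(db: str) -> bool:
    depth = 0
    for ch in db:
        depth += ch == "("
        depth -= ch == ")"
        if depth < 0:
            return True
    return False
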