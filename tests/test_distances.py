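import math
import subprocess

import numpy as np
import pytest

from rnaphylo.distances import (
    BarcodingReport,
    DistanceMatrix,
    barcoding_analysis,
    k2p_matrix,
    k2p_pair,
    merge_synonyms,
)
from rnaphylo.io_formats import Alignment, SequenceRecord
from oracles import k2p_recount


def _aln(rows: dict[str, str]) -> Alignment:
    return Alignment(
        [SequenceRecord(id=k, residues=v) for k, v in rows.items()]
    )


class TestK2PPair:
    def test_identical_rows_zero(self):
        assert k2p_pair("ACGUACGU", "ACGUACGU").d == 0.0

    def test_transition_case(self):
        pd = k2p_pair("AAAAAAAA", "GGAAAAAA")
        assert pd.P == 0.25 and pd.Q == 0.0
        assert pd.d == pytest.approx(-0.5 * math.log(0.5), abs=1e-5)

    def test_transversion_case(self):
        pd = k2p_pair("AAAAAAAA", "CCAAAAAA")
        assert pd.P == 0.0 and pd.Q == 0.25
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.5)
        assert pd.d == pytest.approx(expected, abs=1e-5)

    def test_matches_ape_K80(self, tmp_path):
        """Independent oracle: R ape dist.dna(model='K80')."""
        script = (
            'library(ape);'
            'm <- rbind(a=strsplit("acguacguaaggccuu","")[[1]],'
            '           b=strsplit("acgaacgugaggccua","")[[1]]);'
            'm[m=="u"] <- "t";'
            'cat(as.numeric(dist.dna(as.DNAbin(m), model="K80")))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            check=True,
        )
        ape_d = float(out.stdout.strip())
        ours = k2p_pair("ACGUACGUAAGGCCUU", "ACGAACGUGAGGCCUA").d
        assert ours == pytest.approx(ape_d, abs=1e-6)

    def test_saturation_flagged_not_crash(self):
        pd = k2p_pair("AAAA", "GGGG")
        assert pd.saturated and pd.d is None

    def test_percent_view(self):
        pd = k2p_pair("AAAAAAAA", "GGAAAAAA")
        assert pd.percent == pytest.approx(100 * pd.d)


class TestK2PMatrix:
    def test_complete_deletion_drops_columns_globally(self):
        aln = _aln({"a": "ACGU-CGU", "b": "ACGUACGU", "c": "ACGUACGA"})
        mat = k2p_matrix(aln, deletion="complete")
        # column 5 (gap in a) removed for every pair, so b-c differ at 1 of 7
        pd = mat.details[(1, 2)]
        assert pd.n_sites_used == 7

    def test_pairwise_deletion_per_pair(self):
        aln = _aln({"a": "ACGU-CGU", "b": "ACGUACGU", "c": "ACGUACGA"})
        mat = k2p_matrix(aln, deletion="pairwise")
        assert mat.details[(1, 2)].n_sites_used == 8

    def test_gap_free_complete_equals_pairwise(self, rng):
        for _ in range(5):
            rows = {
                f"s{i}": "".join(rng.choice(list("ACGU"), 40))
                for i in range(4)
            }
            aln = _aln(rows)
            mc = k2p_matrix(aln, "complete")
            mp = k2p_matrix(aln, "pairwise")
            assert np.allclose(mc.matrix, mp.matrix, equal_nan=True)

    def test_ambiguity_treated_as_gap(self):
        aln = _aln({"a": "ACGUNCGU", "b": "ACGUACGU"})
        mat = k2p_matrix(aln, deletion="complete")
        assert mat.details[(0, 1)].n_sites_used == 7

    def test_matches_recount_oracle(self, rng):
        """Brute-force per-pair recount on random small alignments."""
        for _ in range(20):
            n_rows = int(rng.integers(2, 7))
            n_cols = int(rng.integers(10, 61))
            rows = {
                f"s{i}": "".join(
                    rng.choice(list("ACGU-"), n_cols, p=[0.23] * 4 + [0.08])
                )
                for i in range(n_rows)
            }
            aln = _aln(rows)
            mat = k2p_matrix(aln, deletion="pairwise")
            labels = mat.labels
            for i in range(n_rows):
                for j in range(i + 1, n_rows):
                    expect = k2p_recount(rows[labels[i]], rows[labels[j]])
                    got = mat.matrix[i, j]
                    if expect is None:
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(expect, abs=1e-12)

    def test_monotone_in_transitions(self):
        """d is non-decreasing in P at fixed Q on the valid domain."""
        from rnaphylo.distances import k2p_from_counts

        last = -1.0
        for ts in range(0, 30):
            pd = k2p_from_counts(ts, 10, 100)
            assert pd.d is not None and pd.d >= last
            last = pd.d

    def test_unknown_deletion_mode(self):
        with pytest.raises(ValueError):
            k2p_matrix(_aln({"a": "ACGU", "b": "ACGU"}), deletion="bogus")


class TestBarcoding:
    def _matrix(self, labels, d):
        mat = np.zeros((len(labels), len(labels)))
        for (a, b), v in d.items():
            i, j = labels.index(a), labels.index(b)
            mat[i, j] = mat[j, i] = v
        return DistanceMatrix(labels, mat, "complete")

    def test_clean_gap(self):
        labels = ["x1", "x2", "y1", "y2"]
        mat = self._matrix(labels, {
            ("x1", "x2"): 0.01, ("y1", "y2"): 0.01,
            ("x1", "y1"): 0.10, ("x1", "y2"): 0.10,
            ("x2", "y1"): 0.10, ("x2", "y2"): 0.10,
        })
        rep = barcoding_analysis(
            mat, {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
        )
        assert rep.gap == pytest.approx(0.09)
        assert rep.overlaps == [] and rep.has_gap

    def test_overlap_listed_and_negative_gap(self):
        labels = ["x1", "x2", "y1", "y2"]
        mat = self._matrix(labels, {
            ("x1", "x2"): 0.01, ("y1", "y2"): 0.01,
            ("x1", "y1"): 0.005, ("x1", "y2"): 0.10,
            ("x2", "y1"): 0.10, ("x2", "y2"): 0.10,
        })
        rep = barcoding_analysis(
            mat, {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
        )
        assert rep.gap < 0
        assert [(a, b) for a, b, _ in rep.overlaps] == [("X", "Y")]

    def test_single_species_rejected(self):
        labels = ["x1", "x2"]
        mat = self._matrix(labels, {("x1", "x2"): 0.01})
        with pytest.raises(ValueError, match="species"):
            barcoding_analysis(mat, {"x1": "X", "x2": "X"})

    def test_synonyms_merge_before_classification(self):
        labels = ["a1", "b1", "c1", "c2"]
        mat = self._matrix(labels, {
            ("a1", "b1"): 0.001,  # becomes intraspecific after merging
            ("a1", "c1"): 0.10, ("a1", "c2"): 0.10,
            ("b1", "c1"): 0.10, ("b1", "c2"): 0.10,
            ("c1", "c2"): 0.002,
        })
        species = {"a1": "A", "b1": "B", "c1": "C", "c2": "C"}
        no_merge = barcoding_analysis(mat, species)
        assert no_merge.gap < 0
        merged = barcoding_analysis(mat, species, [frozenset({"A", "B"})])
        assert merged.gap > 0
        assert merge_synonyms(species, [frozenset({"A", "B"})])["b1"] == "A"

    def test_unmapped_taxon_rejected(self):
        labels = ["a1", "b1"]
        mat = self._matrix(labels, {("a1", "b1"): 0.1})
        with pytest.raises(ValueError, match="without species"):
            barcoding_analysis(mat, {"a1": "A"})

    def test_report_table_has_percent_column(self):
        labels = ["x1", "x2", "y1", "y2"]
        mat = self._matrix(labels, {
            ("x1", "x2"): 0.01, ("y1", "y2"): 0.01,
            ("x1", "y1"): 0.10, ("x1", "y2"): 0.10,
            ("x2", "y1"): 0.10, ("x2", "y2"): 0.10,
        })
        rep = barcoding_analysis(
            mat, {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
        )
        table = rep.to_table()
        assert "barcoding_gap" in table and "9.0000" in table
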