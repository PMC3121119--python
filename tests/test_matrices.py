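"""Matrix construction, transformation, and file-dialect round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hifmap
from hifmap.errors import ParseError, ValidationError
from hifmap.matrices import (
    ALPHABET,
    AlignedSiteSet,
    MotifMatrix,
    build_count_matrix,
    build_hre_matrix,
    format_matrix,
    read_matrix,
    to_frequency,
    to_score,
    write_matrix,
)
from hifmap.scanning import normalize_score, score_window

from conftest import random_score_matrix


class TestAlignedSiteSet:
    def test_rejects_unequal_lengths_naming_site(self):
        with pytest.raises(ValidationError, match="bad_site"):
            AlignedSiteSet(["ok", "bad_site"], ["ACGT", "ACG"])

    def test_rejects_non_acgt_naming_site(self):
        with pytest.raises(ValidationError, match="s2"):
            AlignedSiteSet(["s1", "s2"], ["ACGT", "ACNT"])

    def test_rejects_empty(self):
        with pytest.raises(ValidationError):
            AlignedSiteSet([], [])


class TestCountMatrix:
    def test_single_site(self):
        m = build_count_matrix(AlignedSiteSet(["s"], ["ACGT"]))
        assert m.values.sum(axis=0).tolist() == [1, 1, 1, 1]
        assert m.values[0, 0] == 1  # A at column 1

    def test_duplicate_sites(self):
        m = build_count_matrix(AlignedSiteSet(["a", "b"], ["CGTG", "CGTG"]))
        assert m.values[1, 0] == 2  # C at column 1
        assert m.values[2, 3] == 2  # G at column 4
        assert m.values.sum(axis=0).tolist() == [2, 2, 2, 2]

    def test_hre_sites_concentrate_core_columns(self, bundle):
        """Every bundled HRE site carries CGTG at columns 7-10, so the
        count mass there sits entirely on C, G, T, G."""
        sites = bundle.hre_site_set()
        m = build_count_matrix(sites)
        n = len(sites)
        for col, base in zip(range(6, 10), "CGTG"):
            assert m.values[ALPHABET.index(base), col] == n


class TestFrequency:
    def test_single_site_no_pseudocount(self):
        m = to_frequency(build_count_matrix(AlignedSiteSet(["s"], ["A"])), 0)
        assert m.values[:, 0].tolist() == [1, 0, 0, 0]

    def test_single_site_pseudocount_one(self):
        m = to_frequency(build_count_matrix(AlignedSiteSet(["s"], ["A"])), 1)
        assert m.values[:, 0] == pytest.approx([0.4, 0.2, 0.2, 0.2])

    def test_two_sites_hand_computed(self):
        sites = AlignedSiteSet(["a", "b"], ["ACAA", "GCAA"])
        m = to_frequency(build_count_matrix(sites), 0)
        assert m.values[:, 0] == pytest.approx([0.5, 0, 0.5, 0])

    @given(
        counts=st.lists(
            st.lists(st.integers(0, 50), min_size=4, max_size=4),
            min_size=1, max_size=12,
        ).filter(lambda cols: all(sum(c) > 0 for c in cols)),
        pseudocount=st.floats(0, 5, allow_nan=False),
    )
    @settings(deadline=None, max_examples=50)
    def test_columns_stochastic(self, counts, pseudocount):
        values = np.array(counts, dtype=float).T
        m = MotifMatrix(matrix_id="m", form="count", values=values)
        f = to_frequency(m, pseudocount)
        assert np.allclose(f.values.sum(axis=0), 1.0, atol=1e-9)
        assert (f.values >= 0).all()


class TestScoreForm:
    def test_frequency_mode_is_identity(self):
        f = to_frequency(build_count_matrix(AlignedSiteSet(["s"], ["ACG"])), 1)
        s = to_score(f, mode="frequency")
        assert np.array_equal(s.values, f.values)
        assert s.max_score == pytest.approx(f.values.max(axis=0).sum())

    def test_log_odds_uniform_column_is_zero(self):
        f = MotifMatrix("m", "frequency", np.full((4, 2), 0.25))
        s = to_score(f, mode="log_odds")
        assert np.allclose(s.values, 0.0)

    def test_log_odds_closed_form(self):
        f = MotifMatrix("m", "frequency", np.array([[0.4, 0.2, 0.2, 0.2]]).T)
        s = to_score(f, mode="log_odds")
        expected = np.log2(np.array([1.6, 0.8, 0.8, 0.8]))
        assert s.values[:, 0] == pytest.approx(expected)

    def test_log_odds_zero_frequency_directs_to_pseudocount(self):
        f = MotifMatrix("m", "frequency", np.array([[1.0, 0, 0, 0]]).T)
        with pytest.raises(ValidationError, match="pseudocount"):
            to_score(f, mode="log_odds")

    @pytest.mark.parametrize("seed", range(5))
    def test_consensus_achieves_max_score(self, seed):
        rng = np.random.default_rng(seed)
        m = random_score_matrix(rng, width=int(rng.integers(1, 12)))
        assert score_window(m, m.consensus()) == pytest.approx(m.max_score)
        assert normalize_score(m, m.max_score) == pytest.approx(1.0)


class TestHreMatrix:
    def test_width_and_core_geometry(self, hre_matrix):
        assert hre_matrix.width == 18
        assert hre_matrix.core == ("CGTG", 7)
        # core columns put their unique maxima on the core bases
        for col, base in zip(range(6, 10), "CGTG"):
            column = hre_matrix.values[:, col]
            k = ALPHABET.index(base)
            assert column[k] == pytest.approx(1.0)
            assert all(column[j] == 0 for j in range(4) if j != k)

    def test_three_site_gene_matrix(self, bundle):
        sites = bundle.hre_site_set(species="HSA", gene_id="ENSG00000119630")
        m = build_hre_matrix(sites)
        assert m.width == 18
        assert m.matrix_id == "V$HIF_STKE_2005"
        for col, base in zip(range(6, 10), "CGTG"):
            assert m.values[:, col].argmax() == ALPHABET.index(base)

    def test_single_site_indicator_flanks(self):
        site = "AAAAAACGTGAAAAAAAA"
        m = build_hre_matrix(AlignedSiteSet(["s"], [site]), pseudocount=0)
        for col in list(range(6)) + list(range(10, 18)):
            assert m.values[:, col].tolist() == [1, 0, 0, 0]

    def test_core_violation_names_site(self):
        bad = "AAAAAACATGAAAAAAAA"  # CATG, not CGTG, at columns 7-10
        with pytest.raises(ValidationError, match="offender"):
            build_hre_matrix(AlignedSiteSet(["offender"], [bad]))

    def test_sites_dominate_core_mutants(self, bundle, hre_matrix):
        """Each input site outscores every single-mismatch variant at a
        core position (12 mutants per site, checked exhaustively)."""
        for record in bundle.hre_sites:
            base_score = score_window(hre_matrix, record.window)
            for col in range(6, 10):
                for sub in "ACGT":
                    if sub == record.window[col]:
                        continue
                    mutant = (
                        record.window[:col] + sub + record.window[col + 1:]
                    )
                    assert score_window(hre_matrix, mutant) < base_score

    def test_ambiguous_core_accepts_either_base(self):
        sites = AlignedSiteSet(
            ["r1", "r2"],
            ["AAAAAACGTGAAAAAAAA", "AAAAAGCGTGAAAAAAAA"],
        )
        m = build_hre_matrix(sites, core_string="RCGTG", core_start=6)
        assert m.core == ("RCGTG", 6)


class TestDialects:
    @pytest.mark.parametrize("dialect", ["native_tsv", "transfac_flat", "jaspar_pfm"])
    def test_round_trip_values_and_id(self, tmp_path, dialect):
        rng = np.random.default_rng(11)
        m = random_score_matrix(rng, width=7, matrix_id="V$ROUND_TRIP")
        path = tmp_path / f"m.{dialect}"
        write_matrix(m, path, dialect)
        back = read_matrix(path, dialect)
        assert back.matrix_id == "V$ROUND_TRIP"
        assert np.allclose(back.values, m.values, atol=1e-9)

    def test_native_tsv_preserves_form_and_core(self, tmp_path, hre_matrix):
        path = tmp_path / "hre.tsv"
        write_matrix(hre_matrix, path, "native_tsv")
        back = read_matrix(path, "native_tsv")
        assert back.form == "score"
        assert back.core == ("CGTG", 7)
        assert np.allclose(back.values, hre_matrix.values, atol=1e-9)

    def test_hand_written_transfac_block(self, tmp_path):
        text = (
            "AC  M00001\nXX\nID  V$TINY\nXX\n"
            "P0      A      C      G      T\n"
            "01      3      0      1      0\n"
            "02      0      4      0      0\n"
            "XX\n//\n"
        )
        path = tmp_path / "tiny.transfac"
        path.write_text(text)
        m = read_matrix(path, "transfac_flat")
        assert m.matrix_id == "V$TINY"
        assert m.form == "count"
        assert m.values[:, 0].tolist() == [3, 0, 1, 0]
        assert m.values[:, 1].tolist() == [0, 4, 0, 0]

    def test_jaspar_pfm_rows_map_acgt(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text("1 2\n3 4\n5 6\n7 8\n")
        m = read_matrix(path, "jaspar_pfm")
        assert m.values[0].tolist() == [1, 2]  # A row
        assert m.values[3].tolist() == [7, 8]  # T row

    def test_transfac_malformed_row_reports_line(self, tmp_path):
        text = (
            "AC  M1\nXX\nID  V$X\nXX\n"
            "P0      A      C      G      T\n"
            "01      3      0\n"
            "XX\n//\n"
        )
        path = tmp_path / "bad.transfac"
        path.write_text(text)
        with pytest.raises(ParseError, match="line 6"):
            read_matrix(path, "transfac_flat")

    def test_native_tsv_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pos\tA\tC\tG\tT\n1\t0.1\t0.2\n")
        with pytest.raises(ParseError, match="line 2"):
            read_matrix(path, "native_tsv")

    def test_format_matrix_unknown_dialect(self, hre_matrix):
        with pytest.raises(ValidationError):
            format_matrix(hre_matrix, "meme")
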