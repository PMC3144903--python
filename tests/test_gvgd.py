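import itertools
import math

import pytest
from hypothesis import given, strategies as st

from domseg.gvgd import (
    GRANTHAM_PROPERTIES,
    RHO,
    AlignmentColumn,
    calibrate_rho,
    classify,
    class_index,
    column_at,
    conservation_fraction,
    gd,
    grantham_distance,
    gv,
    read_alignment,
    score_column,
)

RESIDUES = sorted(GRANTHAM_PROPERTIES)
residue = st.sampled_from(RESIDUES)


class TestGranthamDistance:
    def test_identity_is_zero(self):
        for aa in RESIDUES:
            assert grantham_distance(aa, aa) == 0.0

    def test_e_to_k(self):
        assert grantham_distance("E", "K") == pytest.approx(56.87, abs=0.05)

    def test_mean_100_calibration_recovers_conventional_scale(self):
        rho = calibrate_rho()
        assert rho == pytest.approx(RHO, rel=0.0015)
        mean = sum(
            grantham_distance(x, y, rho=rho)
            for x, y in itertools.combinations(RESIDUES, 2)
        ) / 190
        assert mean == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize(
        "pair, published",
        [(("S", "R"), 110), (("L", "R"), 102), (("W", "C"), 215),
         (("G", "W"), 184), (("I", "L"), 5), (("D", "E"), 45)],
    )
    def test_reproduces_published_integer_matrix(self, pair, published):
        # the published matrix was rounded from unrounded properties, so
        # recomputed values may sit up to ~0.8 off the printed integer
        assert grantham_distance(*pair) == pytest.approx(published, abs=0.8)

    @given(residue, residue)
    def test_symmetric_nonnegative_vanishing_on_diagonal(self, a, b):
        d = grantham_distance(a, b)
        assert d == grantham_distance(b, a)
        assert d >= 0
        assert (d == 0) == (a == b)

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            grantham_distance("E", "X")


class TestGvGd:
    def test_invariant_column_gv_zero(self):
        assert gv(AlignmentColumn.from_symbols("EEEE")) == 0.0

    def test_singleton_column_gv_zero(self):
        assert gv(AlignmentColumn.from_symbols("W")) == 0.0

    def test_two_residue_column_gv_equals_pairwise_distance(self):
        for a, b in [("E", "K"), ("G", "W"), ("A", "V")]:
            col = AlignmentColumn.from_symbols([a, b])
            assert gv(col) == pytest.approx(grantham_distance(a, b))

    def test_gd_from_invariant_column_equals_pairwise_distance(self):
        col = AlignmentColumn.from_symbols("EEEE")
        assert gd(col, "K") == pytest.approx(56.87, abs=0.05)
        assert gd(col, "E") == 0.0

    def test_gd_zero_when_variant_inside_property_ranges(self):
        # E lies within the D..K range on all three properties
        col = AlignmentColumn.from_symbols("DK")
        assert gd(col, "E") == 0.0

    @given(residue, st.lists(residue, min_size=1, max_size=8))
    def test_gd_bounded_by_max_pairwise_distance(self, variant, residues):
        col = AlignmentColumn.from_symbols(residues)
        bound = max(grantham_distance(variant, b) for b in col.residues)
        assert gd(col, variant) <= bound + 1e-9

    @given(residue, residue)
    def test_gd_on_invariant_column_attains_the_pairwise_distance(self, variant, obs):
        col = AlignmentColumn.from_symbols([obs, obs, obs])
        assert gd(col, variant) == pytest.approx(grantham_distance(variant, obs))

    def test_gaps_are_removed(self):
        col = AlignmentColumn.from_symbols(["E", "-", "E", "."])
        assert col.residues == ("E", "E")
        assert col.gap_count == 2

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            AlignmentColumn.from_symbols("--")


class TestClassifier:
    @pytest.mark.parametrize(
        "gv_value, gd_value, label",
        [(0, 56.87, "C55"), (0, 0, "C0"), (0, 70, "C65"),
         (0, 15, "C15"), (0, 54.9, "C45")],
    )
    def test_threshold_binning(self, gv_value, gd_value, label):
        assert classify(gv_value, gd_value) == label

    def test_gv_term_raises_the_boundaries(self):
        # tan(10 deg) * 10^2 ~ 17.6: a GD of 60 drops from C55 to C35 at GV=10
        assert classify(10.0, 60.0) == "C35"

    def test_monotone_in_gd(self):
        for gv_value in (0.0, 5.0, 20.0):
            labels = [class_index(classify(gv_value, g)) for g in range(0, 200, 5)]
            assert labels == sorted(labels)

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            classify(-1, 10)

    def test_end_to_end_disease_substitution(self):
        score = score_column(AlignmentColumn.from_symbols("EEEE"), "K")
        assert score.gv == 0.0
        assert score.gd == pytest.approx(56.87, abs=0.05)
        assert score.class_label == "C55"


class TestConservation:
    def test_identical_sequences(self):
        assert conservation_fraction(["ACGT", "ACGT", "ACGT"]) == 1.0

    def test_constructed_seventy_percent(self):
        base = "ACGTACGTAC"
        other = base[:7] + "GCA"  # differs at the last 3 of 10 columns
        assert conservation_fraction([base, base, base, other]) == pytest.approx(0.7)

    def test_gapped_columns_excluded(self):
        seqs = ["AC-T", "ACGT"]
        # column 3 is gapped; of the 3 remaining, all agree
        assert conservation_fraction(seqs) == 1.0

    def test_window_restriction(self):
        seqs = ["AAAA", "AATT"]
        assert conservation_fraction(seqs, start=1, end=2) == 1.0
        assert conservation_fraction(seqs, start=3, end=4) == 0.0

    def test_ragged_lengths_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            conservation_fraction(["ACG", "AC"])


class TestAlignmentIO:
    def test_fasta_and_clustal_round_trip(self, tmp_path):
        fasta = tmp_path / "aln.fa"
        fasta.write_text(">dog\nMAEK-\n>cat\nMAEKE\n>mouse\nMAEKE\n")
        seqs = read_alignment(fasta)
        assert seqs == ["MAEK-", "MAEKE", "MAEKE"]
        col = column_at(seqs, 4)
        assert col.residues == ("K", "K", "K")
        assert gv(col) == 0.0

        clustal = tmp_path / "aln.aln"
        clustal.write_text(
            "CLUSTAL W (1.83) multiple sequence alignment\n\n"
            "dog    MAEKE\ncat    MAEKE\n\n"
        )
        assert read_alignment(clustal) == ["MAEKE", "MAEKE"]

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("not an alignment\n")
        with pytest.raises(ValueError):
            read_alignment(bad)
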