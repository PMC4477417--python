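"""The property-distance aligner, the matrix baseline, and identity estimation."""

import itertools
import math

import pytest

import propalign as pa
from propalign import GapParams
from propalign.properties import ALPHABET

from helpers_oracle import best_alignment_score

TOY = pa.SubstitutionMatrix(
    "toy", "ACD", [[2.0, -1.0, -1.0], [-1.0, 2.0, -1.0], [-1.0, -1.0, 2.0]]
)


class TestPairDistance:
    def test_identical_residues_have_zero_distance(self, example_props):
        for aa in ALPHABET:
            assert pa.pair_distance(aa, aa, example_props) == 0.0

    def test_hand_computed_example(self, example_props):
        # normalized hydrophobicity difference |2.01/2.46 - 1.96/2.46| weighted 0.6,
        # plus normalized size difference 28/146 weighted 0.4
        expected = 0.6 * abs(2.01 / 2.46 - 1.96 / 2.46) + 0.4 * (28 / 146)
        assert pa.pair_distance("A", "G", example_props) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_over_all_pairs(self, example_props):
        for a, b in itertools.combinations(ALPHABET, 2):
            assert pa.pair_distance(a, b, example_props) == pytest.approx(
                pa.pair_distance(b, a, example_props), abs=0
            )

    def test_single_scale_reduces_to_absolute_difference(self, example_props):
        hyd = example_props.scales[0]
        single = pa.WeightedPropertySet((hyd,), (1.0,))
        norm = pa.normalize_scale(hyd)
        for a, b in [("A", "R"), ("C", "W"), ("G", "P")]:
            assert pa.pair_distance(a, b, single) == pytest.approx(
                abs(norm[a] - norm[b]), abs=1e-12
            )

    def test_unknown_residue_policy(self, example_props):
        with pytest.raises(ValueError, match="'B'"):
            pa.pair_distance("A", "B", example_props)
        d = pa.pair_distance("A", "B", example_props, on_unknown="mean")
        assert d >= 0.0


class TestGapPenalty:
    def test_length_one_is_alpha(self):
        assert pa.gap_penalty(1, GapParams(0.7, 0.1)) == 0.7
        assert pa.gap_penalty(1, GapParams(0.0, 5.0)) == 0.0

    def test_affine_growth(self):
        assert pa.gap_penalty(3, GapParams(0.7, 0.1)) == pytest.approx(0.9)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            pa.gap_penalty(0, GapParams(0.5, 0.1))

    def test_negative_penalties_rejected(self):
        with pytest.raises(ValueError):
            GapParams(-0.1, 0.1)


class TestAlignProperty:
    def test_empty_vs_empty(self, example_props):
        r = pa.align_property("", "", example_props, GapParams(0.5, 0.1))
        assert r.aligned_x == r.aligned_y == ""
        assert r.score == 0.0

    def test_empty_vs_sequence_costs_one_gap(self, example_props):
        gaps = GapParams(0.5, 0.1)
        r = pa.align_property("", "ACDEF", example_props, gaps)
        assert r.aligned_x == "-----"
        assert r.aligned_y == "ACDEF"
        assert r.score == pytest.approx(pa.gap_penalty(5, gaps), abs=1e-12)

    def test_self_alignment_is_gapless_with_zero_score(self, example_props):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        r = pa.align_property(seq, seq, example_props, GapParams(0.7, 0.1))
        assert r.aligned_x == r.aligned_y == seq
        assert r.score == 0.0
        assert r.percent_identity() == 100.0

    def test_reconstruction_and_rescoring(self, example_props, rng):
        gaps = GapParams(0.6, 0.2)
        for _ in range(20):
            x = "".join(rng.choice(list(ALPHABET), size=rng.integers(1, 30)))
            y = "".join(rng.choice(list(ALPHABET), size=rng.integers(1, 30)))
            r = pa.align_property(x, y, example_props, gaps)
            assert r.x_residues == x and r.y_residues == y
            rescored = pa.score_alignment(r.aligned_x, r.aligned_y, example_props, gaps)
            assert rescored == pytest.approx(r.score, abs=1e-9)

    def test_score_symmetric_under_sequence_exchange(self, example_props, rng):
        gaps = GapParams(0.5, 0.1)
        for _ in range(10):
            x = "".join(rng.choice(list(ALPHABET), size=12))
            y = "".join(rng.choice(list(ALPHABET), size=9))
            fwd = pa.align_property(x, y, example_props, gaps).score
            rev = pa.align_property(y, x, example_props, gaps).score
            assert fwd == pytest.approx(rev, abs=1e-9)

    def test_matches_exhaustive_enumeration(self, example_props, rng):
        """DP optimum equals brute-force minimization over all global alignments."""
        sub = "ACDW"
        dist = {
            (a, b): pa.pair_distance(a, b, example_props)
            for a in sub for b in sub
        }
        gaps = GapParams(0.5, 0.1)
        for _ in range(60):
            x = "".join(rng.choice(list(sub), size=rng.integers(0, 7)))
            y = "".join(rng.choice(list(sub), size=rng.integers(0, 7)))
            expected = best_alignment_score(
                x, y, lambda a, b: dist[(a, b)], gaps.alpha, gaps.beta
            )
            got = pa.align_property(x, y, example_props, gaps).score
            assert got == pytest.approx(expected, abs=1e-9), (x, y)

    def test_score_nondecreasing_in_gap_penalties(self, example_props, rng):
        x = "".join(rng.choice(list(ALPHABET), size=15))
        y = "".join(rng.choice(list(ALPHABET), size=12))
        scores = [
            pa.align_property(x, y, example_props, GapParams(a, b)).score
            for a, b in [(0.0, 0.0), (0.2, 0.0), (0.2, 0.1), (0.5, 0.1), (0.5, 0.3), (1.0, 0.3)]
        ]
        assert all(s2 >= s1 - 1e-12 for s1, s2 in zip(scores, scores[1:]))
        assert scores[0] >= 0.0

    def test_no_gap_gap_columns(self, example_props, rng):
        for _ in range(10):
            x = "".join(rng.choice(list(ALPHABET), size=rng.integers(0, 10)))
            y = "".join(rng.choice(list(ALPHABET), size=rng.integers(0, 10)))
            r = pa.align_property(x, y, example_props, GapParams(0.1, 0.1))
            assert not any(
                cx == "-" and cy == "-" for cx, cy in zip(r.aligned_x, r.aligned_y)
            )

    def test_columns_carry_coordinates_and_distances(self, example_props):
        r = pa.align_property("ACD", "AD", example_props, GapParams(0.9, 0.1))
        assert [c.x_pos for c in r.columns] == [1, 2, 3]
        pair_cols = [c for c in r.columns if c.distance is not None]
        assert math.fsum(c.distance for c in pair_cols) + 0.9 == pytest.approx(r.score)


class TestScoreAlignment:
    def test_identical_gapless_pair(self, example_props):
        assert pa.score_alignment("ACD", "ACD", example_props, GapParams(0.7, 0.1)) == 0.0

    def test_single_gap_between_identical_residues(self, example_props):
        # d(A,A) + g(1) + d(C,C) + d(D,D) = alpha
        s = pa.score_alignment("A-CD", "AGCD", example_props, GapParams(0.7, 0.1))
        assert s == pytest.approx(0.7, abs=1e-12)

    def test_terminal_gaps_are_charged(self, example_props):
        gaps = GapParams(0.7, 0.1)
        s = pa.score_alignment("AC--", "ACDE", example_props, gaps)
        assert s == pytest.approx(pa.gap_penalty(2, gaps), abs=1e-12)

    def test_errors(self, example_props):
        gaps = GapParams(0.5, 0.1)
        with pytest.raises(ValueError):
            pa.score_alignment("AC", "ACD", example_props, gaps)
        with pytest.raises(ValueError):
            pa.score_alignment("A-C", "A-C", example_props, gaps)


class TestAlignMatrix:
    def test_self_alignment_sums_diagonal(self, blosum62):
        seq = "MKTAYIAKQR"
        r = pa.align_matrix(seq, seq, blosum62, -11, -1)
        assert r.aligned_x == seq
        assert r.score == pytest.approx(sum(blosum62.score(c, c) for c in seq))

    def test_hand_enumerated_single_gap(self):
        # two matches (2+2) plus one length-1 gap (-1)
        r = pa.align_matrix("AAA", "AA", TOY, -1.0, -1.0)
        assert r.score == pytest.approx(3.0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(60):
            x = "".join(rng.choice(list("ACD"), size=rng.integers(0, 7)))
            y = "".join(rng.choice(list("ACD"), size=rng.integers(0, 7)))
            expected = best_alignment_score(x, y, TOY.score, -4.0, -1.0, maximize=True)
            got = pa.align_matrix(x, y, TOY, -4.0, -1.0).score
            assert got == pytest.approx(expected, abs=1e-9), (x, y)

    def test_agrees_with_biopython_pairwise_aligner(self, blosum62, rng):
        """Independent cross-check of the maximizing Gotoh against Bio.Align."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        for _ in range(25):
            x = "".join(rng.choice(list(ALPHABET), size=rng.integers(1, 40)))
            y = "".join(rng.choice(list(ALPHABET), size=rng.integers(1, 40)))
            assert pa.align_matrix(x, y, blosum62, -11.0, -1.0).score == pytest.approx(
                aligner.score(x, y), abs=1e-9
            )

    def test_residue_absent_from_matrix(self):
        with pytest.raises(KeyError, match="'W'"):
            pa.align_matrix("AW", "AC", TOY, -1, -1)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pa.SubstitutionMatrix("bad", "AC", [[1.0, 2.0], [3.0, 1.0]])

    def test_read_blast_format_matrix(self, tmp_path):
        text = "# toy matrix\n   A  C  D\nA  2 -1 -1\nC -1  2 -1\nD -1 -1  2\n"
        path = tmp_path / "toy.mat"
        path.write_text(text)
        m = pa.read_matrix(path, name="toy")
        assert m.score("A", "A") == 2.0
        assert m.score("A", "D") == -1.0


class TestEstimateIdentity:
    def test_identical_sequences(self, blosum62):
        assert pa.estimate_identity("ACDEFGHIKL", "ACDEFGHIKL", blosum62) == 100.0

    def test_no_identical_aligned_residues(self):
        # same-length pair over a toy matrix; best alignment is gapless
        m = pa.SubstitutionMatrix("t2", "AC", [[2.0, 0.0], [0.0, 2.0]])
        assert pa.estimate_identity("AAAA", "CCCC", m, -5, -1) == 0.0

    def test_constructed_half_identity(self, blosum62):
        # gapless optimum: 4 identical of 8 aligned columns
        x = "WWWWCCCC"
        y = "WWWWHHHH"
        assert pa.estimate_identity(x, y, blosum62) == pytest.approx(50.0)

    def test_empty_sequence_rejected(self, blosum62):
        with pytest.raises(ValueError):
            pa.estimate_identity("", "ACD", blosum62)


class TestUnknownResidues:
    def test_error_policy_reports_position(self, example_props):
        with pytest.raises(ValueError, match="position 3"):
            pa.align_property("ACXD", "ACD", example_props, GapParams(0.5, 0.1))

    def test_mean_imputation_aligns(self, example_props):
        r = pa.align_property(
            "ACXD", "ACD", example_props, GapParams(0.5, 0.1), on_unknown="mean"
        )
        assert r.x_residues == "ACXD"
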