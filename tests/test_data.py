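"""Interval containers, derived matrices, I/O and the synthetic generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import intervalpca as ip
from intervalpca.data import IntervalDataError

from conftest import random_interval_matrix


class TestIntervalMatrix:
    def test_rejects_inverted_bounds(self):
        with pytest.raises(IntervalDataError, match="lower bound exceeds upper"):
            ip.IntervalMatrix([[3.0], [0.0]], [[1.0], [1.0]])

    def test_rejects_nonfinite_and_tiny_shapes(self):
        with pytest.raises(IntervalDataError):
            ip.IntervalMatrix([[0.0, np.nan]], [[1.0, 2.0]])
        with pytest.raises(IntervalDataError, match="n >= 2"):
            ip.IntervalMatrix([[0.0]], [[1.0]])

    def test_default_labels(self):
        X = ip.IntervalMatrix([[0, 0], [1, 1]], [[1, 2], [2, 3]])
        assert X.case_labels == ("c1", "c2")
        assert X.var_names == ("X1", "X2")


class TestCenterMatrix:
    @pytest.mark.parametrize(
        "lo, hi, expected",
        [
            ([[1.0], [0.0]], [[3.0], [2.0]], [[2.0], [1.0]]),
            ([[5.0], [5.0]], [[5.0], [5.0]], [[5.0], [5.0]]),  # degenerate a=b
        ],
    )
    def test_midpoint(self, lo, hi, expected):
        X = ip.IntervalMatrix(lo, hi)
        Z = ip.center_matrix(X)
        np.testing.assert_allclose(Z.values, expected)
        assert X.contains(Z.values)

    def test_faces_fra1_first_variable(self, faces):
        # FRA1 X1 = [155.00, 157.00] → midpoint 156.00
        assert ip.center_matrix(faces).values[0, 0] == pytest.approx(156.00)

    def test_membership_random(self):
        rng = np.random.default_rng(0)
        X = random_interval_matrix(rng, 5, 4)
        assert X.contains(ip.center_matrix(X).values)


class TestVertexMatrix:
    def test_unit_square_corner_order(self):
        X = ip.IntervalMatrix([[0, 0], [5, 5]], [[1, 1], [5, 5]])
        V = ip.vertex_matrix(X)
        # case 1: binary counting, leftmost column slowest, a→0 / b→1
        np.testing.assert_allclose(V.rows[:4], [[0, 0], [0, 1], [1, 0], [1, 1]])
        assert V.N == 5  # 2^2 + 2^0
        np.testing.assert_array_equal(V.m_i, [2, 0])

    def test_degenerate_column_not_duplicated(self):
        X = ip.IntervalMatrix([[2, 0], [9, 9]], [[2, 1], [9, 9]])
        V = ip.vertex_matrix(X)
        np.testing.assert_allclose(V.rows[:2], [[2, 0], [2, 1]])
        assert V.m_i[0] == 1

    def test_faces_vertex_count(self, faces):
        V = ip.vertex_matrix(faces)
        assert V.N == 27 * 2**6 == 1728
        # every entry is one of the case's bounds
        picks_bound = (V.rows == faces.lower[V.case_of_row]) | (
            V.rows == faces.upper[V.case_of_row]
        )
        assert picks_bound.all()

    @given(st.integers(0, 2**31 - 1), st.integers(2, 5), st.integers(1, 5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_row_count_property(self, seed, n, m):
        rng = np.random.default_rng(seed)
        X = random_interval_matrix(rng, n, m, width_scale=rng.uniform(0, 1))
        V = ip.vertex_matrix(X)
        assert V.N == (2 ** X.nontrivial.sum(axis=1)).sum()
        assert V.case_of_row.shape == (V.N,)


class TestStandardize:
    def test_self_standardization_is_orthonormal_columns(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(7, 3))
        stats = ip.column_stats(Z)
        tilde = ip.standardize_wrt(Z, stats)
        np.testing.assert_allclose(tilde.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose((tilde**2).sum(axis=0), 1, atol=1e-10)

    def test_scalar_example(self):
        stats = ip.ColumnStats(np.array([0.0]), np.array([1.0]), 4)
        assert ip.standardize_wrt(np.array([[2.0], [0.0]]), stats)[0, 0] == pytest.approx(1.0)

    def test_interval_input_preserves_order(self):
        stats = ip.ColumnStats(np.array([2.0]), np.array([1.0]), 1)
        X = ip.IntervalMatrix([[1.0], [2.0]], [[3.0], [2.0]])
        out = ip.standardize_wrt(X, stats)
        assert out.lower[0, 0] == pytest.approx(-1.0)
        assert out.upper[0, 0] == pytest.approx(1.0)

    def test_zero_sd_rejected_with_column_position(self):
        with pytest.raises(IntervalDataError, match="constant column 1"):
            ip.column_stats(np.array([[1.0, 5.0], [2.0, 5.0]]))


class TestCSV(object):
    @pytest.mark.parametrize("dialect", ["bracket", "paired"])
    def test_round_trip_lossless(self, tmp_path, dialect):
        rng = np.random.default_rng(3)
        X = random_interval_matrix(rng, 6, 4)
        path = tmp_path / "x.csv"
        ip.write_interval_csv(X, path, dialect)
        back = ip.read_interval_csv(path, dialect)
        np.testing.assert_array_equal(back.lower, X.lower)
        np.testing.assert_array_equal(back.upper, X.upper)
        assert back.case_labels == X.case_labels
        assert back.var_names == X.var_names

    def test_bracket_parse_and_errors(self, tmp_path):
        path = tmp_path / "x.csv"
        path.write_text('case,X1\na,"[155.00,157.00]"\nb,"[1,2]"\n')
        X = ip.read_interval_csv(path, "bracket")
        assert (X.lower[0, 0], X.upper[0, 0]) == (155.0, 157.0)

        path.write_text('case,X1\na,"[3,1]"\nb,"[1,2]"\n')
        with pytest.raises(IntervalDataError, match="lower bound exceeds upper"):
            ip.read_interval_csv(path, "bracket")

        path.write_text('case,X1\na,"155"\nb,"[1,2]"\n')
        with pytest.raises(IntervalDataError, match="row 1"):
            ip.read_interval_csv(path, "bracket")

    def test_paired_requires_matched_pairs(self, tmp_path):
        path = tmp_path / "x.csv"
        path.write_text("case,X1.lo,X2.hi\na,1,2\nb,1,2\n")
        with pytest.raises(IntervalDataError, match="mismatched pair"):
            ip.read_interval_csv(path, "paired")


class TestFacesFixture:
    def test_shape_and_labels(self, faces):
        assert (faces.n, faces.m) == (27, 6)
        assert faces.case_labels[0] == "FRA1"
        assert faces.case_labels[-1] == "ROM3"
        assert faces.var_names == ("X1", "X2", "X3", "X4", "X5", "X6")

    def test_printed_values(self, faces):
        i = faces.case_labels.index("HUS1")
        assert (faces.lower[i, 0], faces.upper[i, 0]) == (168.9, 172.84)
        i = faces.case_labels.index("ROM3")
        assert (faces.lower[i, 5], faces.upper[i, 5]) == (50.99, 60.46)
        i = faces.case_labels.index("FRA2")
        assert (faces.lower[i, 0], faces.upper[i, 0]) == (154.0, 160.01)

    def test_all_intervals_nontrivial(self, faces):
        assert faces.nontrivial.all()


class TestSynthesizer:
    def test_deterministic_given_seed(self):
        a = ip.synthesize_interval_matrix(10, 4, seed=7)
        b = ip.synthesize_interval_matrix(10, 4, seed=7)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)

    def test_zero_width_gives_degenerate_box(self):
        X = ip.synthesize_interval_matrix(8, 3, width_spec=0.0, seed=2)
        assert (X.lower == X.upper).all()
        assert ip.vertex_matrix(X).N == 8

    def test_default_output_is_valid(self):
        X = ip.synthesize_interval_matrix(27, 6, seed=1)
        assert (X.lower <= X.upper).all()
        assert np.isfinite(X.lower).all() and np.isfinite(X.upper).all()

    def test_negative_width_rejected(self):
        with pytest.raises(IntervalDataError, match="negative half-width"):
            ip.synthesize_interval_matrix(5, 2, width_spec=lambda r, n, m: -np.ones((n, m)))
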