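"""DTW engine tests against an exhaustive warping-path oracle."""

from __future__ import annotations

import numpy as np
import pytest

from actispot.dtw import (
    best_subsequence_matches,
    dtw_full,
    dtw_subsequence,
    pairwise_dtw_matrix,
    subsequence_profile,
)


def euclid(a, b):
    return float(np.linalg.norm(np.atleast_1d(a) - np.atleast_1d(b)))


def oracle_dtw(a, b):
    """Minimal cost over explicitly enumerated monotone warping paths.

    Walks every path from (0,0) to (n-1,m-1) with steps {(1,0),(0,1),(1,1)}
    and sums Euclidean costs — no recurrence shared with the implementation.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, acc):
        acc += euclid(a[i], b[j])
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], acc)
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def random_instance(rng, dim):
    n, m = int(rng.integers(1, 8)), int(rng.integers(1, 8))
    a = rng.normal(size=(n, dim))
    b = rng.normal(size=(m, dim))
    return a, b


class TestDtwFull:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.normal(size=(6, 3))
            assert dtw_full(a, a).distance == pytest.approx(0.0, abs=1e-12)

    def test_two_constant_sequences(self):
        # all pairwise costs are 1; the cheapest path has 2 steps
        res = dtw_full([0.0, 0.0], [1.0, 1.0])
        assert res.distance == pytest.approx(2.0)
        assert res.path == [(0, 0), (1, 1)]

    def test_perfect_warp_of_stretched_copy(self):
        res = dtw_full([0.0, 1.0, 2.0], [0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        assert res.distance == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("dim", [1, 3])
    def test_matches_exhaustive_path_enumeration(self, dim):
        rng = np.random.default_rng(101 + dim)
        for _ in range(60):
            a, b = random_instance(rng, dim)
            got = dtw_full(a, b).distance
            assert got == pytest.approx(oracle_dtw(a, b), abs=1e-9)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = random_instance(rng, 2)
            dab, dba = dtw_full(a, b).distance, dtw_full(b, a).distance
            assert dab == pytest.approx(dba, abs=1e-9)
            assert dab >= 0.0

    def test_path_sum_equals_distance(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b = random_instance(rng, 3)
            res = dtw_full(a, b)
            path_sum = sum(euclid(a[i], b[j]) for i, j in res.path)
            assert res.distance == pytest.approx(path_sum, abs=1e-9)
            assert res.normalized_distance == pytest.approx(
                res.distance / len(res.path)
            )

    def test_path_steps_are_monotone(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=(6, 1)), rng.normal(size=(7, 1))
        path = dtw_full(a, b).path
        assert path[0] == (0, 0) and path[-1] == (5, 6)
        for (i0, j0), (i1, j1) in zip(path, path[1:]):
            assert (i1 - i0, j1 - j0) in {(1, 0), (0, 1), (1, 1)}

    def test_rejects_empty_and_mismatched(self):
        with pytest.raises(ValueError):
            dtw_full([], [1.0])
        with pytest.raises(ValueError):
            dtw_full(np.zeros((3, 2)), np.zeros((3, 3)))


class TestDtwSubsequence:
    def test_verbatim_embedding_gives_zero_at_copy_end(self):
        template = np.array([1.0, 3.0, 2.0])
        series = np.concatenate([np.zeros(4), template, np.zeros(3)])
        last_row, _ = dtw_subsequence(template, series)
        assert last_row[6] == pytest.approx(0.0, abs=1e-12)
        assert np.all(last_row[np.arange(len(series)) != 6] > 0)

    def test_single_element_template_is_pointwise_cost(self):
        series = np.array([0.0, 1.5, -2.0])
        last_row, _ = dtw_subsequence([0.5], series)
        np.testing.assert_allclose(last_row, np.abs(series - 0.5))

    @pytest.mark.parametrize("dim", [1, 3])
    def test_last_row_matches_windowed_full_dtw(self, dim):
        """last_row[j] == min over starts s<=j of full DTW on series[s..j]."""
        rng = np.random.default_rng(31 + dim)
        for _ in range(30):
            t = rng.normal(size=(int(rng.integers(1, 5)), dim))
            s = rng.normal(size=(int(rng.integers(1, 8)), dim))
            last_row, _ = dtw_subsequence(t, s)
            for j in range(len(s)):
                expect = min(
                    dtw_full(t, s[start : j + 1]).distance for start in range(j + 1)
                )
                assert last_row[j] == pytest.approx(expect, abs=1e-9)

    def test_free_start_no_worse_than_forced_start(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            t = rng.normal(size=(4, 1))
            s = rng.normal(size=(7, 1))
            last_row, _ = dtw_subsequence(t, s)
            assert last_row.min() <= dtw_full(t, s).distance + 1e-9


class TestBestSubsequenceMatches:
    def test_series_equal_to_template(self):
        t = np.array([0.0, 2.0, 1.0, 3.0])
        matches = best_subsequence_matches(t, t)
        assert matches[0].distance == pytest.approx(0.0, abs=1e-12)
        assert (matches[0].start_index, matches[0].end_index) == (0, 3)

    def test_two_disjoint_copies_found(self):
        t = np.array([1.0, 4.0, 2.0])
        series = np.concatenate([np.zeros(3), t, np.zeros(5), t, np.zeros(3)])
        matches = best_subsequence_matches(t, series)
        zero = [m for m in matches if m.distance < 1e-9]
        spans = {(m.start_index, m.end_index) for m in zero}
        assert spans == {(3, 5), (11, 13)}

    def test_monotone_profile_yields_single_global_minimum(self):
        # template of large values against an increasing ramp: last_row
        # decreases toward the end, so the only local minimum is the last index
        t = np.array([10.0, 10.0])
        series = np.arange(8, dtype=float)
        matches = best_subsequence_matches(t, series)
        ends = [m.end_index for m in matches]
        assert ends == [7]

    def test_sorted_by_distance(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=(3, 1))
        s = rng.normal(size=(30, 1))
        matches = best_subsequence_matches(t, s)
        dists = [m.normalized_distance for m in matches]
        assert dists == sorted(dists)

    def test_profile_normalization_consistent_with_matches(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=(3, 1))
        s = rng.normal(size=(20, 1))
        norm_row, raw_row = subsequence_profile(t, s)
        for m in best_subsequence_matches(t, s):
            assert raw_row[m.end_index] == pytest.approx(m.distance, abs=1e-9)
            assert norm_row[m.end_index] == pytest.approx(
                m.normalized_distance, abs=1e-9
            )


class TestPairwiseMatrix:
    def test_identical_sequences_have_zero_distance(self):
        a = np.array([[0.0], [1.0], [2.0]])
        M = pairwise_dtw_matrix([a, a.copy(), a + 1.0])
        assert M[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert M[0, 2] == pytest.approx(M[1, 2], abs=1e-12)

    def test_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(8)
        seqs = [rng.normal(size=(int(rng.integers(2, 6)), 2)) for _ in range(4)]
        M = pairwise_dtw_matrix(seqs)
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(M), 0.0, atol=1e-12)
        assert (M >= 0).all()

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            pairwise_dtw_matrix([np.zeros((3, 1))])
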