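"""Dynamic time warping: full-sequence distance and subsequence matching.

The same motion performed at different speeds produces sensor traces of
different lengths; DTW aligns them by the minimal-cost monotone warping
path under the recursion

    d(i, j) = cost(i, j) + min(d(i, j-1), d(i-1, j), d(i-1, j-1))

with Euclidean local cost.  Two variants are provided:

* :func:`dtw_full` — both sequences aligned end to end (used by the
  fixed-length sliding matcher and by template clustering).
* :func:`dtw_subsequence` — the template's start is free, i.e. the first
  template row is initialised with the local cost at every series
  position, so the last accumulated row gives, for every series position
  ``j``, the cheapest match of the whole template ending at ``j``.  Local
  minima of that row are the match candidates for activity spotting.

Accumulated distances are optionally normalized by warping-path length so
that matches of templates of different lengths are comparable.  Tie-breaks
in backtracking are fixed (diagonal, then vertical, then horizontal) for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

__all__ = [
    "DTWResult",
    "SubsequenceMatch",
    "dtw_full",
    "dtw_subsequence",
    "subsequence_profile",
    "best_subsequence_matches",
    "pairwise_dtw_matrix",
]


@dataclass
class DTWResult:
    """Alignment of two complete sequences."""

    distance: float
    path: list[tuple[int, int]]
    normalized_distance: float


@dataclass
class SubsequenceMatch:
    """A template match inside a longer series (inclusive index span)."""

    start_index: int
    end_index: int
    distance: float
    normalized_distance: float
    path_length: int

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("start_index must be <= end_index")


def _as_2d(seq) -> np.ndarray:
    arr = np.asarray(seq, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("sequences must be 1-D or (n, d) arrays")
    return arr


def _cost_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("sequences must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"dimensionality mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    return cdist(a, b)


@njit(cache=True)
def _accumulate_full(C):  # pragma: no cover - exercised via dtw_full
    n, m = C.shape
    D = np.empty((n, m))
    D[0, 0] = C[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + C[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + C[i, 0]
        for j in range(1, m):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = C[i, j] + best
    return D


@njit(cache=True)
def _accumulate_subsequence(C):  # pragma: no cover
    n, m = C.shape
    D = np.empty((n, m))
    for j in range(m):
        D[0, j] = C[0, j]  # free start: no penalty for where the match begins
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + C[i, 0]
        for j in range(1, m):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = C[i, j] + best
    return D


@njit(cache=True)
def _subsequence_spans(D):  # pragma: no cover
    """Backtrack from every end position: (start index, path length) per j.

    Tie-breaks mirror the Python backtracker: diagonal, vertical, horizontal.
    """
    n, m = D.shape
    starts = np.empty(m, dtype=np.int64)
    lengths = np.empty(m, dtype=np.int64)
    for j_end in range(m):
        i, j = n - 1, j_end
        steps = 1
        while i > 0:
            if j == 0:
                i -= 1
            else:
                diag = D[i - 1, j - 1]
                vert = D[i - 1, j]
                horiz = D[i, j - 1]
                best = diag
                if vert < best:
                    best = vert
                if horiz < best:
                    best = horiz
                if diag == best:
                    i -= 1
                    j -= 1
                elif vert == best:
                    i -= 1
                else:
                    j -= 1
            steps += 1
        starts[j_end] = j
        lengths[j_end] = steps
    return starts, lengths


def _backtrack_full(D: np.ndarray) -> list[tuple[int, int]]:
    i, j = D.shape[0] - 1, D.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, vert, horiz = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            best = min(diag, vert, horiz)
            if diag == best:
                i, j = i - 1, j - 1
            elif vert == best:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return path


def dtw_full(query, reference) -> DTWResult:
    """Minimal-cost end-to-end alignment of two sequences.

    Accepts 1-D sequences or (n, d) arrays of equal dimensionality.
    """
    a, b = _as_2d(query), _as_2d(reference)
    C = _cost_matrix(a, b)
    D = _accumulate_full(C)
    path = _backtrack_full(D)
    dist = float(D[-1, -1])
    return DTWResult(distance=dist, path=path, normalized_distance=dist / len(path))


def dtw_subsequence(template, series) -> tuple[np.ndarray, np.ndarray]:
    """Free-start accumulated cost of the template inside the series.

    Returns ``(last_row, D)`` where ``last_row[j]`` is the minimal cost of
    matching the complete template ending at series position ``j`` and
    ``D`` is the full accumulated-cost matrix (for span backtracking).
    """
    t, s = _as_2d(template), _as_2d(series)
    C = _cost_matrix(t, s)
    D = _accumulate_subsequence(C)
    return D[-1].copy(), D


def subsequence_profile(template, series) -> tuple[np.ndarray, np.ndarray]:
    """Per-end-position match profile: (normalized last row, raw last row).

    Used to compare different templates' match quality at the same series
    position on a common (per-path-step) scale, e.g. activity template
    versus idle template in the zeroline selection rule.
    """
    last_row, D = dtw_subsequence(template, series)
    _, lengths = _subsequence_spans(D)
    return last_row / lengths, last_row


def _local_minima(x: np.ndarray) -> list[int]:
    """Indices of local minima; plateaus resolve to their leftmost index.

    Boundary positions count as minima when they are no larger than their
    single neighbour.
    """
    n = x.size
    mins: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        left_ok = i == 0 or x[i - 1] > x[i]
        right_ok = j == n - 1 or x[j + 1] > x[i]
        if left_ok and right_ok:
            mins.append(i)
        i = j + 1
    return mins


def best_subsequence_matches(
    template, series, normalize: bool = True
) -> list[SubsequenceMatch]:
    """Candidate matches of a template in a long series.

    Candidate end positions are the local minima of the subsequence DTW
    last row; each candidate's start is recovered by backtracking.  The
    list is sorted by (normalized, if requested) distance ascending.
    """
    last_row, D = dtw_subsequence(template, series)
    starts, lengths = _subsequence_spans(D)
    matches = []
    for j in _local_minima(last_row):
        dist = float(last_row[j])
        matches.append(
            SubsequenceMatch(
                start_index=int(starts[j]),
                end_index=int(j),
                distance=dist,
                normalized_distance=dist / int(lengths[j]),
                path_length=int(lengths[j]),
            )
        )
    key = (lambda m: (m.normalized_distance, m.start_index)) if normalize else (
        lambda m: (m.distance, m.start_index)
    )
    matches.sort(key=key)
    return matches


def pairwise_dtw_matrix(sequences) -> np.ndarray:
    """Symmetric matrix of normalized full-DTW distances."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    arrs = [_as_2d(s) for s in sequences]
    dims = {a.shape[1] for a in arrs}
    if len(dims) != 1:
        raise ValueError("all sequences must share dimensionality")
    n = len(arrs)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_full(arrs[i], arrs[j]).normalized_distance
            M[i, j] = M[j, i] = d
    return M
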