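"""Affine-gap global alignment by dynamic programming (Gotoh three-state).

This is a maximization alignment over an arbitrary pairwise score matrix: it
is reused with a secondary-structure match score, with a distance-signal
similarity under zero gap penalties (the dynamic-time-warping regime) and
with the RBF coordinate score.

Gap-cost convention: a run of L consecutive gaps in one sequence costs
``open + (L - 1) * extend``; terminal gaps are penalized like internal ones
(true global alignment). A gap run in one sequence immediately followed by a
gap run in the other opens a new gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GAP", "GapPenalties", "IndexAlignment", "affine_dp_align"]

#: Sentinel residue index marking a gap in an alignment pair.
GAP = -1

_NEG = -np.inf


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap penalties (non-negative score units): open >= extend >= 0."""

    open: float
    extend: float

    def __post_init__(self) -> None:
        if not (self.open >= self.extend >= 0.0):
            raise ValueError("require open >= extend >= 0")


@dataclass
class IndexAlignment:
    """A global alignment as ordered (i, j) index pairs; GAP = -1.

    Non-gap indices on each side are strictly increasing and complete
    (every residue of both inputs appears exactly once).
    """

    pairs: list[tuple[int, int]]
    score: float

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        """The matched (non-gap on both sides) pairs."""
        return [(i, j) for i, j in self.pairs if i != GAP and j != GAP]

    def aligned_indices(self) -> tuple[np.ndarray, np.ndarray]:
        ap = self.aligned_pairs
        if not ap:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        arr = np.asarray(ap, dtype=int)
        return arr[:, 0], arr[:, 1]


def affine_dp_align(
    score_matrix: np.ndarray, penalties: GapPenalties
) -> IndexAlignment:
    """Global alignment maximizing sum(S[i, j]) minus affine gap costs.

    Traceback ties prefer match over a gap in the second sequence over a
    gap in the first, so output is deterministic.
    """
    s = np.asarray(score_matrix, dtype=float)
    if s.ndim != 2 or s.size == 0:
        raise ValueError("score matrix must be a non-empty 2-D array")
    if not np.isfinite(s).all():
        raise ValueError("score matrix entries must be finite")
    n, m = s.shape
    go, ge = penalties.open, penalties.extend

    # state matrices over (n+1) x (m+1); M = ends in match, X = gap in
    # second seq (consumes i), Y = gap in first seq (consumes j)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = -go - (j - 1) * ge

    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        si = s[i - 1]
        for j in range(1, m + 1):
            Mi[j] = si[j - 1] + max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Xi[j] = max(Mi1[j] - go, Xi1[j] - ge, Yi1[j] - go)
            Yi[j] = max(Mi[j - 1] - go, Yi[j - 1] - ge, Xi[j - 1] - go)

    # traceback, preferring M > X > Y at every tie
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    score = float((M[i, j], X[i, j], Y[i, j])[state])
    while i > 0 or j > 0:
        if state == 0:
            pairs.append((i - 1, j - 1))
            state = _pick(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            pairs.append((i - 1, GAP))
            state = _pick(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            i -= 1
        else:
            pairs.append((GAP, j - 1))
            state = _pick(M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
            j -= 1
    pairs.reverse()
    return IndexAlignment(pairs=pairs, score=score)


def _pick(m: float, x: float, y: float) -> int:
    # same float arithmetic as the fill, so equality testing is exact
    if m >= x and m >= y:
        return 0
    return 1 if x >= y else 2
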