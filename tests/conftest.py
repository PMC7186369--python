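import numpy as np
import pytest

from stralign.synthetic import FixtureSpec, make_structure

MIXED_BLOCKS = [("helix", 15), ("loop", 10), ("strand", 10), ("loop", 10), ("helix", 15)]


@pytest.fixture(scope="session")
def mixed_structure():
    """60-residue helix/loop/strand/loop/helix chain used across tests."""
    return make_structure(FixtureSpec(blocks=MIXED_BLOCKS, seed=3, struct_id="mixed"))


@pytest.fixture(scope="session")
def helix20():
    return make_structure(FixtureSpec(blocks=[("helix", 20)], struct_id="helix20"))


def brute_force_best_alignment(score, gap_open, gap_extend):
    """Exhaustive enumeration of all global monotone alignments.

    Every alignment is a lattice path of match / gap-in-second /
    gap-in-first moves; each is scored by scanning its gap runs with the
    affine convention open + (L-1)*extend (terminal gaps included, a gap
    run in one sequence followed by one in the other opens anew).
    Independent of the dynamic-programming implementation.
    """
    n, m = score.shape
    best = -np.inf

    def walk(i, j, acc, last):
        nonlocal best
        if i == n and j == m:
            best = max(best, acc)
            return
        if i < n and j < m:
            walk(i + 1, j + 1, acc + score[i, j], "M")
        if i < n:
            walk(i + 1, j, acc - (gap_extend if last == "X" else gap_open), "X")
        if j < m:
            walk(i, j + 1, acc - (gap_extend if last == "Y" else gap_open), "Y")

    walk(0, 0, 0.0, "start")
    return best


def alignment_objective(pairs, score, gap_open, gap_extend):
    """Recompute the affine-gap objective of an explicit alignment."""
    total, run = 0.0, None
    for i, j in pairs:
        if i >= 0 and j >= 0:
            total += score[i, j]
            run = None
        elif j < 0:
            total -= gap_extend if run == "X" else gap_open
            run = "X"
        else:
            total -= gap_extend if run == "Y" else gap_open
            run = "Y"
    return total
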