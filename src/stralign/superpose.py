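"""Rigid-body superposition: the Kabsch solver and the two coarse
initial-superposition strategies used before coordinate-level alignment.

Two structures can only be aligned on inter-structure residue distances once
they sit in a common frame, but finding that frame needs a residue
correspondence — a chicken-and-egg problem. It is broken with coarse,
orientation-free alignments:

1. *secondary superposition* — align 3-class secondary-structure strings by
   dynamic programming (match +1, mismatch -1, unassigned 0) and Kabsch over
   the aligned alpha-carbons;
2. *signal superposition* — slide a 30-residue window along each chain and
   describe each window by the rotation-invariant vector of distances from
   every residue to the window's first (or last) residue; dynamic time
   warping (zero gap penalties) over a Gaussian similarity of those signals
   matches windows, and Kabsch over the anchor alpha-carbons of matched
   windows gives the transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dp import GapPenalties, affine_dp_align

__all__ = [
    "RigidTransform",
    "SignalSegment",
    "SuperpositionError",
    "kabsch",
    "rmsd",
    "make_segments",
    "score_signal",
    "signal_superpose",
    "secondary_superpose",
]

SEGMENT_LENGTH = 30
_SIGNAL_WIDTH = 10.0  # denominator of the Gaussian in the segment score


class SuperpositionError(RuntimeError):
    """A superposition strategy could not produce a usable transform."""


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation, with det(rotation) = +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying `other` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


def rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean square deviation between corresponded coordinate sets."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def kabsch(x: np.ndarray, y: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform taking point set x onto point set y.

    Uses the SVD of the cross-covariance of the centered sets, with the
    reflection correction so the returned rotation always has det +1.
    Requires k >= 3 points; collinear/degenerate sets still return a
    proper rotation (the reflection-corrected optimum).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("x and y must be matching (k, 3) arrays")
    if x.shape[0] < 3:
        raise ValueError("at least 3 points are required")
    cx, cy = x.mean(axis=0), y.mean(axis=0)
    h = (x - cx).T @ (y - cy)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, cy - rot @ cx)


@dataclass
class SignalSegment:
    """One window's rotation-invariant distance signal.

    start : index of the window's first residue
    anchor : 'first' or 'last' — which residue distances are measured to
    signal : distances (A) from each window residue to the anchor residue
    """

    start: int
    anchor: str
    signal: np.ndarray

    @property
    def anchor_index(self) -> int:
        return self.start if self.anchor == "first" else self.start + len(self.signal) - 1


def make_segments(
    structure, anchor: str = "first", segment_length: int = SEGMENT_LENGTH
) -> list[SignalSegment]:
    """Overlapping (stride-1) windows of the CA trace as distance signals.

    Chains shorter than ``segment_length`` fall back to a window of
    ``max(10, N // 2)`` residues so short chains remain alignable; chains
    shorter than that raise :class:`SuperpositionError`.
    """
    if anchor not in ("first", "last"):
        raise ValueError("anchor must be 'first' or 'last'")
    ca = np.asarray(structure.ca_coords, float)
    n = len(ca)
    length = segment_length if n >= segment_length else max(10, n // 2)
    if n < length:
        raise SuperpositionError(
            f"chain of {n} residues is too short for {length}-residue segments"
        )
    segments = []
    for start in range(n - length + 1):
        window = ca[start : start + length]
        ref = window[0] if anchor == "first" else window[-1]
        signal = np.linalg.norm(window - ref, axis=1)
        segments.append(SignalSegment(start=start, anchor=anchor, signal=signal))
    return segments


def score_signal(a: SignalSegment, b: SignalSegment) -> float:
    """Similarity of two equal-length signals in [0, 1]:
    median over positions of exp(-(d_a - d_b)^2 / 10)."""
    if len(a.signal) != len(b.signal):
        raise ValueError("signals must have equal length")
    delta = a.signal - b.signal
    return float(np.median(np.exp(-(delta**2) / _SIGNAL_WIDTH)))


def signal_superpose(s1, s2, anchor: str = "first",
                     segment_length: int = SEGMENT_LENGTH) -> RigidTransform:
    """Coarse transform of s1 onto s2 from dynamic time warping of the
    rotation-invariant window signals.

    The window lists are aligned with zero gap penalties (pure monotone
    matching), then the anchor alpha-carbons of every matched window pair
    feed the Kabsch solver.
    """
    seg1 = make_segments(s1, anchor, segment_length)
    seg2 = make_segments(s2, anchor, segment_length)
    if len(seg1) < 3 or len(seg2) < 3:
        raise SuperpositionError("need at least 3 segments per structure")
    length = min(len(seg1[0].signal), len(seg2[0].signal))
    score = np.empty((len(seg1), len(seg2)))
    sig1 = np.stack([s.signal[:length] for s in seg1])
    sig2 = np.stack([s.signal[:length] for s in seg2])
    delta = sig1[:, None, :] - sig2[None, :, :]
    score = np.median(np.exp(-(delta**2) / _SIGNAL_WIDTH), axis=2)
    aln = affine_dp_align(score, GapPenalties(0.0, 0.0))
    ii, jj = aln.aligned_indices()
    if len(ii) < 3:
        raise SuperpositionError("fewer than 3 aligned segment pairs")
    anchors1 = np.asarray(s1.ca_coords)[[seg1[i].anchor_index for i in ii]]
    anchors2 = np.asarray(s2.ca_coords)[[seg2[j].anchor_index for j in jj]]
    return kabsch(anchors1, anchors2)


#: secondary-structure match score: unassigned 0, equal +1, unequal -1
def score_secondary(code_a: str, code_b: str) -> int:
    if code_a == "-" or code_b == "-":
        return 0
    return 1 if code_a == code_b else -1


def secondary_structure_score_matrix(codes1: str, codes2: str) -> np.ndarray:
    a = np.frombuffer(codes1.encode(), dtype="S1")
    b = np.frombuffer(codes2.encode(), dtype="S1")
    s = np.where(a[:, None] == b[None, :], 1.0, -1.0)
    s[a == b"-", :] = 0.0
    s[:, b == b"-"] = 0.0
    return s


def secondary_superpose(
    s1, s2, penalties: GapPenalties = GapPenalties(1.0, 0.0)
) -> RigidTransform:
    """Coarse transform of s1 onto s2 from a secondary-structure alignment.

    The 3-class code strings are globally aligned (match +1, mismatch -1,
    unassigned 0, gap open 1 / extend 0) and the aligned residues'
    alpha-carbons feed the Kabsch solver.
    """
    if set(s1.sec_codes) <= {"-"} or set(s2.sec_codes) <= {"-"}:
        raise SuperpositionError("secondary structure codes unassigned")
    s = secondary_structure_score_matrix(s1.sec_codes, s2.sec_codes)
    aln = affine_dp_align(s, penalties)
    ii, jj = aln.aligned_indices()
    if len(ii) < 3:
        raise SuperpositionError("fewer than 3 aligned residue pairs")
    return kabsch(
        np.asarray(s1.ca_coords)[ii], np.asarray(s2.ca_coords)[jj]
    )
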