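"""Alignment-quality metrics for multiple structure alignments.

Column-level metrics (gap-less positions, equivalence against a reference
alignment) read the alignment alone. Pair-level metrics (RMSD,
structurally equivalent residues) are computed for every structure pair
after superposing all structures onto one common reference — the longest
protein — on the alignment's gap-less columns, then averaged over all
unordered pairs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import combinations

import numpy as np

from .dp import GAP
from .multiple import MultipleAlignment
from .superpose import RigidTransform, kabsch

__all__ = [
    "AlignmentQuality",
    "gapless_positions",
    "equivalence_score",
    "superpose_to_reference",
    "pairwise_rmsd",
    "structurally_equivalent",
    "alignment_quality",
]

EQUIVALENCE_CUTOFF = 4.0  # Angstrom


@dataclass
class AlignmentQuality:
    gapless_count: int
    gapless_ratio: float
    mean_pairwise_rmsd: float
    mean_equivalent_count: float
    mean_equivalent_fraction: float
    equivalence_score: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_tsv(self, path) -> None:
        items = asdict(self)
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for key, val in items.items():
                fh.write(f"{key}\t{val}\n")


def gapless_positions(msa: MultipleAlignment) -> tuple[int, float]:
    """Count and column-fraction of positions where no structure has a gap."""
    mask = msa.gapless_column_mask()
    return int(mask.sum()), float(mask.mean())


def _column_tuples(msa: MultipleAlignment, ids: list[str]):
    rows = np.stack([np.asarray(msa.rows[sid]) for sid in ids])
    return rows


def equivalence_score(msa: MultipleAlignment, reference: MultipleAlignment) -> float:
    """Percentage of the alignment's gap-less columns that appear as
    columns of the reference alignment (same residue index in every
    structure).

    Both alignments must cover the same structures with the same residue
    counts; a mismatch raises ``ValueError``.
    """
    ids = sorted(msa.rows)
    if sorted(reference.rows) != ids:
        raise ValueError(
            f"structure ids differ: {ids} vs {sorted(reference.rows)}"
        )
    for sid in ids:
        n_test = int((np.asarray(msa.rows[sid]) != GAP).sum())
        n_ref = int((np.asarray(reference.rows[sid]) != GAP).sum())
        if n_test != n_ref:
            raise ValueError(
                f"structure {sid!r} has {n_test} residues in the alignment "
                f"but {n_ref} in the reference (sequences do not match)"
            )
    test = _column_tuples(msa, ids)
    ref = _column_tuples(reference, ids)
    gapless = (test != GAP).all(axis=0)
    if not gapless.any():
        raise ValueError("alignment has no gap-less positions")
    ref_columns = {tuple(col) for col in ref.T}
    matching = sum(1 for col in test.T[gapless] if tuple(col) in ref_columns)
    return 100.0 * matching / int(gapless.sum())


def superpose_to_reference(
    msa: MultipleAlignment, structures
) -> dict[str, np.ndarray]:
    """Superpose every structure onto the longest one (ties: first by id)
    using the alignment's gap-less columns; returns transformed CA sets."""
    by_id = {s.id: s for s in structures}
    ref_id = min(by_id, key=lambda sid: (-len(by_id[sid]), sid))
    mask = msa.gapless_column_mask()
    if mask.sum() < 3:
        raise ValueError("fewer than 3 gap-less positions to superpose on")
    ref_idx = np.asarray(msa.rows[ref_id])[mask]
    ref_ca = np.asarray(by_id[ref_id].ca_coords)
    out = {}
    for sid, s in by_id.items():
        ca = np.asarray(s.ca_coords)
        if sid == ref_id:
            out[sid] = ca.copy()
            continue
        idx = np.asarray(msa.rows[sid])[mask]
        transform = kabsch(ca[idx], ref_ca[ref_idx])
        out[sid] = transform.apply(ca)
    return out


def _pair_columns(msa: MultipleAlignment, sid_a: str, sid_b: str):
    ra = np.asarray(msa.rows[sid_a])
    rb = np.asarray(msa.rows[sid_b])
    both = (ra != GAP) & (rb != GAP)
    return ra[both], rb[both]


def pairwise_rmsd(msa: MultipleAlignment, coords: dict[str, np.ndarray]) -> float:
    """Mean over unordered structure pairs of the CA RMSD across columns
    where both structures have residues, in the common superposition."""
    rmsds = []
    for a, b in combinations(sorted(coords), 2):
        ia, ib = _pair_columns(msa, a, b)
        if len(ia) == 0:
            continue
        delta = coords[a][ia] - coords[b][ib]
        rmsds.append(np.sqrt((delta**2).sum(axis=1).mean()))
    if not rmsds:
        raise ValueError("no structure pair shares an aligned column")
    return float(np.mean(rmsds))


def structurally_equivalent(
    msa: MultipleAlignment,
    coords: dict[str, np.ndarray],
    cutoff: float = EQUIVALENCE_CUTOFF,
) -> tuple[float, float]:
    """Mean count and fraction (over unordered pairs) of residue pairs in
    the same alignment position within ``cutoff`` A of each other."""
    counts, fractions = [], []
    for a, b in combinations(sorted(coords), 2):
        ia, ib = _pair_columns(msa, a, b)
        if len(ia) == 0:
            counts.append(0)
            fractions.append(0.0)
            continue
        dist = np.linalg.norm(coords[a][ia] - coords[b][ib], axis=1)
        close = dist <= cutoff
        counts.append(int(close.sum()))
        fractions.append(float(close.mean()))
    return float(np.mean(counts)), float(np.mean(fractions))


def alignment_quality(
    msa: MultipleAlignment,
    structures,
    reference: MultipleAlignment | None = None,
    cutoff: float = EQUIVALENCE_CUTOFF,
) -> AlignmentQuality:
    """All quality metrics in one record."""
    count, ratio = gapless_positions(msa)
    coords = superpose_to_reference(msa, structures)
    mean_rmsd = pairwise_rmsd(msa, coords)
    eq_count, eq_frac = structurally_equivalent(msa, coords, cutoff)
    score = equivalence_score(msa, reference) if reference is not None else None
    return AlignmentQuality(
        gapless_count=count,
        gapless_ratio=ratio,
        mean_pairwise_rmsd=mean_rmsd,
        mean_equivalent_count=eq_count,
        mean_equivalent_fraction=eq_frac,
        equivalence_score=score,
    )
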