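"""Backbone hydrogen-bond based secondary structure assignment ("DSSP-lite").

Hydrogen bonds are detected with the Kabsch–Sander electrostatic model:

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332  [kcal/mol]

where the donor is the backbone amide (N-H) of residue *i* and the acceptor
the carbonyl (C=O) of residue *j*; a bond is called when E < -0.5 kcal/mol.
The amide hydrogen is not present in most PDB files and is reconstructed by
placing it 1.0 A from N along the direction of the previous residue's C=O
bond, the construction used by DSSP itself.

Codes are collapsed to a 3-class alphabet:

* ``H`` — alpha helix: residues covered by two consecutive i -> i+4 turns,
* ``E`` — extended strand: members of a parallel or antiparallel bridge,
* ``C`` — coil (everything else),
* ``-`` — unassignable (incomplete backbone).

Helix takes precedence over strand, as in DSSP.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hbond_energies", "assign_secondary_from_backbone"]

#: Kabsch–Sander energy threshold for calling a hydrogen bond (kcal/mol).
HBOND_CUTOFF = -0.5

#: Clamp for the electrostatic energy at clashing geometries (kcal/mol).
ENERGY_FLOOR = -9.9

_Q1Q2F = 0.084 * 332.0
_NH_LENGTH = 1.0


def _amide_hydrogens(n: np.ndarray, c: np.ndarray, o: np.ndarray) -> np.ndarray:
    """Reconstruct H(i) from N(i) and the previous residue's C=O.

    The first residue (and any residue following a broken stretch) gets NaN:
    it has no reconstructable amide hydrogen and cannot donate.
    """
    n_res = len(n)
    h = np.full((n_res, 3), np.nan)
    co = c[:-1] - o[:-1]
    norms = np.linalg.norm(co, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h[1:] = n[1:] + _NH_LENGTH * co / norms[:, None]
    return h


def hbond_energies(
    n: np.ndarray, ca: np.ndarray, c: np.ndarray, o: np.ndarray
) -> np.ndarray:
    """Kabsch–Sander energy matrix E[i, j]: amide of residue i donating to
    the carbonyl of residue j, in kcal/mol. NaN where undefined (missing
    atoms, |i - j| < 2).
    """
    n = np.asarray(n, dtype=float)
    c = np.asarray(c, dtype=float)
    o = np.asarray(o, dtype=float)
    n_res = len(n)
    h = _amide_hydrogens(n, c, o)
    e = np.full((n_res, n_res), np.nan)

    def dist(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        r_on = dist(o, n).T  # [donor, acceptor]
        r_ch = dist(c, h).T
        r_oh = dist(o, h).T
        r_cn = dist(c, n).T
        energy = _Q1Q2F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    energy = np.where(np.isfinite(energy), energy, np.nan)
    # exclude self and sequence neighbours; clamp clashes
    ii, jj = np.indices((n_res, n_res))
    energy[np.abs(ii - jj) < 2] = np.nan
    e = np.maximum(energy, ENERGY_FLOOR)
    return e


def _turn4(hb: np.ndarray) -> np.ndarray:
    """turn[i] is True when N-H(i+4) donates to C=O(i)."""
    n_res = hb.shape[0]
    t = np.zeros(n_res, dtype=bool)
    if n_res > 4:
        t[: n_res - 4] = hb[4:, : n_res - 4].diagonal()
    return t


def _bridges(hb: np.ndarray) -> np.ndarray:
    """Mark residues participating in parallel or antiparallel bridges."""
    n_res = hb.shape[0]
    in_bridge = np.zeros(n_res, dtype=bool)

    def bond(i, j):
        return 0 <= i < n_res and 0 <= j < n_res and hb[i, j]

    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            parallel = (bond(i - 1, j) and bond(j, i + 1)) or (
                bond(j - 1, i) and bond(i, j + 1)
            )
            antiparallel = (bond(i, j) and bond(j, i)) or (
                bond(i - 1, j + 1) and bond(j - 1, i + 1)
            )
            if parallel or antiparallel:
                in_bridge[i] = in_bridge[j] = True
    return in_bridge


def assign_secondary_from_backbone(backbone: np.ndarray) -> str:
    """Assign 3-class codes from an (N, 4, 3) backbone array (N, CA, C, O).

    Residues with a missing N, CA or C get '-'. If fewer than five
    consecutive residues have complete backbones nothing but coil/'-'
    can be assigned and the whole string is '-'.
    """
    backbone = np.asarray(backbone, dtype=float)
    n_res = backbone.shape[0]
    complete = np.isfinite(backbone[:, :3, :]).all(axis=(1, 2))
    run, best = 0, 0
    for flag in complete:
        run = run + 1 if flag else 0
        best = max(best, run)
    if best < 5:
        return "-" * n_res

    hb_e = hbond_energies(
        backbone[:, 0], backbone[:, 1], backbone[:, 2], backbone[:, 3]
    )
    hb = np.zeros_like(hb_e, dtype=bool)
    np.greater(HBOND_CUTOFF, hb_e, out=hb, where=np.isfinite(hb_e))

    codes = np.full(n_res, "C", dtype="<U1")
    codes[~complete] = "-"

    turn = _turn4(hb)
    for i in range(n_res - 5):
        if turn[i] and turn[i + 1]:
            codes[i + 1 : i + 5] = "H"

    in_bridge = _bridges(hb)
    strand = in_bridge & (codes == "C")
    codes[strand] = "E"
    return "".join(codes)
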