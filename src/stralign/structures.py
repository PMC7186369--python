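"""Protein structure container and file I/O (PDB read, aligned FASTA read/write).

A :class:`ProteinStructure` holds one chain's residues: per-residue backbone
coordinates (N, CA, C, O), a beta-carbon coordinate (the alpha-carbon for
glycine and for residues without a CB atom), the one-letter sequence and
3-class secondary-structure codes. Only residues with an alpha-carbon are
kept; everything downstream indexes residues 0..N-1 in chain order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import biotite.structure as bts
import biotite.structure.io.pdb as btpdb
from biotite.sequence import ProteinSequence

from .dssp import assign_secondary_from_backbone

__all__ = [
    "ProteinStructure",
    "StructureIOError",
    "ChainNotFoundError",
    "EmptySelectionError",
    "read_pdb",
    "write_pdb",
    "assign_secondary",
    "write_fasta_alignment",
    "read_fasta_alignment",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureIOError(ValueError):
    """Base error for structure parsing/selection problems."""


class ChainNotFoundError(StructureIOError):
    pass


class EmptySelectionError(StructureIOError):
    pass


@dataclass
class ProteinStructure:
    """One protein chain reduced to per-residue arrays.

    Parameters
    ----------
    id : str
        Identifier used in alignments and feature matrices.
    chain : str
        One-letter chain identifier.
    sequence : str
        One-letter amino-acid sequence, length N.
    backbone : (N, 4, 3) float array
        N/CA/C/O coordinates in Angstrom; NaN where an atom is missing
        (CA is never missing).
    cb_coords : (N, 3) float array
        Beta-carbon coordinates; equals the alpha-carbon for Gly and for
        residues lacking a CB atom.
    sec_codes : str
        Length-N string over {H, E, C, -}; '-' means unassigned.
    """

    id: str
    chain: str
    sequence: str
    backbone: np.ndarray
    cb_coords: np.ndarray
    sec_codes: str = ""
    atoms: bts.AtomArray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.backbone = np.asarray(self.backbone, dtype=float)
        self.cb_coords = np.asarray(self.cb_coords, dtype=float)
        n = self.backbone.shape[0]
        if n < 1 or self.backbone.shape[1:] != (4, 3):
            raise ValueError("backbone must be a non-empty (N, 4, 3) array")
        if len(self.sequence) != n or self.cb_coords.shape != (n, 3):
            raise ValueError("per-residue arrays must share length N")
        if not np.isfinite(self.ca_coords).all():
            raise ValueError("alpha-carbon coordinates must be finite")
        if not self.sec_codes:
            self.sec_codes = "-" * n

    def __len__(self) -> int:
        return self.backbone.shape[0]

    @property
    def ca_coords(self) -> np.ndarray:
        return self.backbone[:, 1, :]

    def transformed(self, transform) -> "ProteinStructure":
        """Return a copy with every coordinate moved by a rigid transform."""
        atoms = None
        if self.atoms is not None:
            atoms = self.atoms.copy()
            atoms.coord = transform.apply(atoms.coord)
        return replace(
            self,
            backbone=transform.apply(self.backbone.reshape(-1, 3)).reshape(-1, 4, 3),
            cb_coords=transform.apply(self.cb_coords),
            atoms=atoms,
        )


def assign_secondary(structure: ProteinStructure) -> str:
    """3-class secondary structure from backbone hydrogen bonding.

    Returns a length-N string over {H, E, C, -}; degenerate input (e.g. a
    CA-only trace) yields all '-'. Deterministic, and invariant under
    rigid-body motion since only interatomic distances enter the
    Kabsch–Sander energies.
    """
    return assign_secondary_from_backbone(structure.backbone)


def _structure_from_atom_array(
    arr: bts.AtomArray, struct_id: str, chain: str
) -> ProteinStructure:
    res_starts = bts.get_residue_starts(arr)
    n_res = len(res_starts)
    backbone = np.full((n_res, 4, 3), np.nan)
    cb = np.full((n_res, 3), np.nan)
    seq_chars = []
    keep = []
    bounds = list(res_starts) + [arr.array_length()]
    for r in range(n_res):
        sl = slice(bounds[r], bounds[r + 1])
        names = arr.atom_name[sl]
        coords = arr.coord[sl]
        has_ca = False
        for k, atom in enumerate(BACKBONE_ATOMS):
            hits = np.flatnonzero(names == atom)
            if hits.size:
                backbone[r, k] = coords[hits[0]]
                if atom == "CA":
                    has_ca = True
        hits = np.flatnonzero(names == "CB")
        if hits.size:
            cb[r] = coords[hits[0]]
        if not has_ca:
            continue
        keep.append(r)
        res_name = arr.res_name[sl][0]
        try:
            one = ProteinSequence.convert_letter_3to1(res_name)
        except KeyError:
            one = "X"
        seq_chars.append(one)

    if not keep:
        raise EmptySelectionError(
            f"{struct_id}: no residues with alpha-carbons in selection"
        )
    keep = np.asarray(keep)
    backbone = backbone[keep]
    cb = cb[keep]
    # Gly (and any residue without CB) falls back to the alpha-carbon
    missing_cb = ~np.isfinite(cb).all(axis=1)
    cb[missing_cb] = backbone[missing_cb, 1]
    structure = ProteinStructure(
        id=struct_id,
        chain=chain,
        sequence="".join(seq_chars),
        backbone=backbone,
        cb_coords=cb,
        atoms=arr,
    )
    structure.sec_codes = assign_secondary(structure)
    return structure


def read_pdb(
    path,
    chain: str | None = None,
    start: int | None = None,
    end: int | None = None,
    struct_id: str | None = None,
    sec_codes: str | None = None,
) -> ProteinStructure:
    """Read one chain of a PDB file as a :class:`ProteinStructure`.

    Parameters
    ----------
    chain : optional
        One-letter chain id; default is the first chain in the file.
    start, end : optional
        Inclusive author residue numbers (PDB resSeq) delimiting the
        selection; internal indexing is 0-based thereafter.
    sec_codes : optional
        Precomputed secondary-structure string (e.g. from an external DSSP
        run) to use instead of the internal assignment. Must cover the
        selected residues.

    Only the first model is used; hetero atoms are dropped, altlocs resolve
    to the highest occupancy, and residues without an alpha-carbon are
    discarded (survivor order is preserved).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb_file = btpdb.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=1, altloc="occupancy")
    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise EmptySelectionError(f"{path}: no polymer atoms")
    chains = [str(c) for c in np.unique(arr.chain_id)]
    if chain is None:
        chain = str(arr.chain_id[0])
    if chain not in chains:
        raise ChainNotFoundError(f"{path}: chain {chain!r} not in {chains}")
    arr = arr[arr.chain_id == chain]
    if start is not None:
        arr = arr[arr.res_id >= start]
    if end is not None:
        arr = arr[arr.res_id <= end]
    if arr.array_length() == 0:
        raise EmptySelectionError(
            f"{path}: empty selection (chain {chain}, {start}-{end})"
        )
    struct = _structure_from_atom_array(
        arr, struct_id or path.stem, chain
    )
    if sec_codes is not None:
        if len(sec_codes) != len(struct):
            raise ValueError(
                f"sec_codes length {len(sec_codes)} != {len(struct)} residues"
            )
        struct.sec_codes = sec_codes
    return struct


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write backbone + CB atoms as a single-chain PDB file."""
    atoms = []
    three = {
        c: ProteinSequence.convert_letter_1to3(c) if c != "X" else "UNK"
        for c in set(structure.sequence)
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    for r in range(len(structure)):
        res_name = three[structure.sequence[r]]
        coords = dict(zip(BACKBONE_ATOMS, structure.backbone[r]))
        if res_name != "GLY":
            coords["CB"] = structure.cb_coords[r]
        for name, xyz in coords.items():
            if not np.isfinite(xyz).all():
                continue
            atoms.append(
                bts.Atom(
                    xyz,
                    chain_id=structure.chain,
                    res_id=r + 1,
                    res_name=res_name,
                    atom_name=name,
                    element=elements[name],
                )
            )
    arr = bts.array(atoms)
    pdb_file = btpdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def write_fasta_alignment(msa, structures, path) -> None:
    """Write a multiple alignment as aligned FASTA ('-' for gaps).

    Record ids are structure ids; rows must all have the alignment's
    column count.
    """
    structures = {s.id: s for s in structures}
    if msa.column_count < 1 or not msa.rows:
        raise ValueError("empty alignment")
    lines = []
    for sid, row in msa.rows.items():
        if len(row) != msa.column_count:
            raise ValueError(f"row {sid!r} has ragged length {len(row)}")
        seq = structures[sid].sequence
        lines.append(f">{sid}")
        lines.append(
            "".join("-" if idx < 0 else seq[idx] for idx in row)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta_alignment(path) -> dict[str, str]:
    """Read an aligned FASTA file into an id -> gapped-sequence mapping.

    All records must share one length; raises on ragged input.
    """
    text = Path(path).read_text()
    records: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            records[name] = ""
        elif name is None:
            raise ValueError(f"{path}: sequence data before first header")
        else:
            records[name] += line
    if not records:
        raise ValueError(f"{path}: no records")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    return records
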