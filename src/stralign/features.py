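"""Per-residue structural features and the alignment-indexed feature matrix.

Features intended for downstream machine learning on a structure family:

* elastic-network mobilities — Gaussian (GNM) and anisotropic (ANM) network
  model square fluctuations from the lowest 50 normal modes;
* backbone geometry — hydrogen-bond energy, solvent accessibility,
  alpha (CA) virtual dihedral, kappa bend angle, phi/psi torsions, and the
  tco carbonyl-carbonyl cosine;
* residue depth below the solvent-accessible surface.

Values are scattered into the columns of a multiple structure alignment to
give a structures x columns x features array with explicit NaN at gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as bts
from scipy.linalg import eigh
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from ._geometry import dihedral, bond_angle
from .dp import GAP
from .dssp import hbond_energies

__all__ = [
    "gnm_fluctuations",
    "anm_fluctuations",
    "backbone_features",
    "residue_depth",
    "extract_features",
    "FeatureMatrix",
    "aligned_feature_matrix",
]

_DEGENERACY_RTOL = 1e-11


def _nonzero_modes(evals: np.ndarray, expected_zeros: int) -> np.ndarray:
    """Indices of nonzero modes, smallest eigenvalue first.

    Elastic network matrices have an exact null space (1 mode for the
    Kirchhoff matrix, 6 rigid-body modes for the Hessian) whose computed
    eigenvalues sit at machine noise, many orders below the softest
    physical mode. The ``expected_zeros`` smallest-magnitude eigenvalues
    are discarded; if more than that fall below a tight relative
    threshold the network is degenerate and ``ValueError`` is raised by
    the caller via the returned count.
    """
    amax = np.abs(evals).max()
    order = np.argsort(np.abs(evals))
    extra_null = np.abs(evals[order[expected_zeros]]) < _DEGENERACY_RTOL * amax
    if extra_null:
        raise _DegenerateModes()
    nonzero = order[expected_zeros:]
    return nonzero[np.argsort(evals[nonzero])]


class _DegenerateModes(Exception):
    pass

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_VDW = 1.70


class DisconnectedNetworkError(ValueError):
    """The elastic-network contact graph has more than one component."""


def _contact_components(adjacency: np.ndarray) -> list[list[int]]:
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(adjacency, directed=False)
    return [list(np.flatnonzero(labels == k)) for k in range(n_comp)]


def gnm_fluctuations(
    ca_coords: np.ndarray, cutoff: float = 10.0, n_modes: int = 50
) -> np.ndarray:
    """Gaussian network model square fluctuations of the CA trace.

    The Kirchhoff matrix has -1 for residue pairs within ``cutoff`` (A) and
    row-sum-cancelling diagonals; the fluctuation of residue i sums
    u_ki^2 / lambda_k over the ``min(n_modes, N-1)`` smallest nonzero
    modes. With all modes this equals the diagonal of the Moore-Penrose
    pseudo-inverse of the Kirchhoff matrix.
    """
    ca = np.asarray(ca_coords, float)
    n = len(ca)
    if n < 3:
        raise ValueError("need at least 3 residues")
    contact = squareform(pdist(ca) <= cutoff)
    gamma = -contact.astype(float)
    np.fill_diagonal(gamma, contact.sum(axis=1))
    evals, evecs = eigh(gamma)
    try:
        nonzero = _nonzero_modes(evals, expected_zeros=1)
    except _DegenerateModes:
        comps = _contact_components(contact)
        raise DisconnectedNetworkError(
            f"contact graph has {len(comps)} components: {comps}"
        ) from None
    idx = nonzero[: min(n_modes, n - 1)]
    return (evecs[:, idx] ** 2 / evals[idx]).sum(axis=1)


def anm_fluctuations(
    ca_coords: np.ndarray, cutoff: float = 15.0, n_modes: int = 50
) -> np.ndarray:
    """Anisotropic network model square fluctuations of the CA trace.

    Builds the standard 3N x 3N Hessian with super-elements
    -(r_ij r_ij^T) / |r_ij|^2 for contacts within ``cutoff`` (A); the
    fluctuation of residue i sums its three eigenvector components squared
    over lambda for the ``min(n_modes, 3N-6)`` smallest nonzero modes.
    """
    ca = np.asarray(ca_coords, float)
    n = len(ca)
    if n < 4:
        raise ValueError("need at least 4 residues")
    diff = ca[:, None, :] - ca[None, :, :]
    dist2 = (diff**2).sum(axis=2)
    contact = (dist2 <= cutoff**2) & ~np.eye(n, dtype=bool)
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in np.flatnonzero(contact[i]):
            block = -np.outer(diff[i, j], diff[i, j]) / dist2[i, j]
            hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
    evals, evecs = eigh(hess)
    try:
        nonzero = _nonzero_modes(evals, expected_zeros=6)
    except _DegenerateModes:
        raise ValueError(
            "more than 6 near-zero modes: degenerate or disconnected network"
        ) from None
    idx = nonzero[: min(n_modes, 3 * n - 6)]
    contrib = evecs[:, idx] ** 2 / evals[idx]
    return contrib.reshape(n, 3, -1).sum(axis=(1, 2))


def backbone_features(structure) -> pd.DataFrame:
    """DSSP-style per-residue backbone features.

    Columns: hbond_energy (best, i.e. most negative, Kabsch-Sander energy
    as donor or acceptor, kcal/mol), accessibility (solvent-accessible
    surface area, A^2, Shrake-Rupley), alpha (virtual CA dihedral
    i-1..i+2, deg), kappa (bend angle at CA_i between CA_{i-2} and
    CA_{i+2}, deg), phi, psi (backbone torsions, deg) and tco (cosine of
    the angle between the C=O bonds of residues i and i-1). Undefined
    entries (chain termini, missing atoms) are NaN.
    """
    bb = np.asarray(structure.backbone, float)
    n = len(bb)
    ca = bb[:, 1]
    out = pd.DataFrame(
        index=range(n),
        columns=[
            "hbond_energy",
            "accessibility",
            "alpha",
            "kappa",
            "phi",
            "psi",
            "tco",
        ],
        dtype=float,
    )

    e = hbond_energies(bb[:, 0], bb[:, 1], bb[:, 2], bb[:, 3])
    filled = np.where(np.isfinite(e), e, np.inf)
    best = np.minimum(filled.min(axis=1), filled.min(axis=0))
    out["hbond_energy"] = np.where(np.isfinite(best), best, np.nan)

    out["accessibility"] = _residue_sasa(structure)

    def ok(*atoms):
        return all(np.isfinite(a).all() for a in atoms)

    for i in range(n):
        if 1 <= i <= n - 3 and ok(ca[i - 1], ca[i], ca[i + 1], ca[i + 2]):
            out.loc[i, "alpha"] = dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
        if 2 <= i <= n - 3 and ok(ca[i - 2], ca[i], ca[i + 2]):
            out.loc[i, "kappa"] = bond_angle(ca[i - 2], ca[i], ca[i + 2])
        if i >= 1 and ok(bb[i - 1, 2], bb[i, 0], bb[i, 1], bb[i, 2]):
            out.loc[i, "phi"] = dihedral(bb[i - 1, 2], bb[i, 0], bb[i, 1], bb[i, 2])
        if i <= n - 2 and ok(bb[i, 0], bb[i, 1], bb[i, 2], bb[i + 1, 0]):
            out.loc[i, "psi"] = dihedral(bb[i, 0], bb[i, 1], bb[i, 2], bb[i + 1, 0])
        if i >= 1 and ok(bb[i, 2], bb[i, 3], bb[i - 1, 2], bb[i - 1, 3]):
            v1 = bb[i, 3] - bb[i, 2]
            v0 = bb[i - 1, 3] - bb[i - 1, 2]
            out.loc[i, "tco"] = float(
                np.dot(v1, v0) / (np.linalg.norm(v1) * np.linalg.norm(v0))
            )
    return out


def _atom_table(structure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(coords, residue index, element) for all available atoms."""
    if structure.atoms is not None:
        arr = structure.atoms
        arr = arr[~np.isin(arr.element, ("H", "D"))]
        res_ids = arr.res_id
        _, res_index = np.unique(res_ids, return_inverse=True)
        return arr.coord, res_index, arr.element
    coords, res, elem = [], [], []
    names = ("N", "CA", "C", "O")
    for i in range(len(structure)):
        for k, name in enumerate(names):
            xyz = structure.backbone[i, k]
            if np.isfinite(xyz).all():
                coords.append(xyz)
                res.append(i)
                elem.append(name[0])
        if not np.allclose(structure.cb_coords[i], structure.backbone[i, 1]):
            coords.append(structure.cb_coords[i])
            res.append(i)
            elem.append("C")
    return np.asarray(coords), np.asarray(res), np.asarray(elem)


def _residue_sasa(structure, point_number: int = 200) -> np.ndarray:
    """Per-residue Shrake-Rupley solvent-accessible surface area (A^2)."""
    coords, res_index, elements = _atom_table(structure)
    atoms = bts.AtomArray(len(coords))
    atoms.coord = coords
    atoms.res_id = res_index + 1
    atoms.chain_id = np.full(len(coords), "A")
    atoms.atom_name = np.array(
        [e if e != "C" else "C" for e in elements], dtype="U4"
    )
    atoms.res_name = np.full(len(coords), "ALA", dtype="U3")
    atoms.element = np.asarray(elements, dtype="U2")
    atoms.hetero = np.zeros(len(coords), dtype=bool)
    per_atom = bts.sasa(atoms, point_number=point_number, vdw_radii="Single")
    out = np.full(len(structure), np.nan)
    for i in range(len(structure)):
        mask = res_index == i
        if mask.any():
            out[i] = np.nansum(per_atom[mask])
    return out


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _sampled_surface(
    coords: np.ndarray, radii: np.ndarray, sphere_points: int
) -> np.ndarray:
    """Solvent-accessible surface sample: points on each atom's expanded
    sphere not buried inside any other atom's expanded sphere.

    Sampling directions are fixed in a canonical molecule frame (principal
    axes with deterministic signs), so the sampled surface — and any
    distance measured to it — is invariant under rigid motion of the
    input, not just approximately so.
    """
    center = coords.mean(axis=0)
    x = coords - center
    _, axes = eigh(x.T @ x)
    for k in (0, 1):  # orient by the skewness of the projections
        if ((x @ axes[:, k]) ** 3).sum() < 0:
            axes[:, k] *= -1
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    unit = _sphere_points(sphere_points) @ axes.T
    candidates = coords[:, None, :] + radii[:, None, None] * unit[None, :, :]
    candidates = candidates.reshape(-1, 3)
    owner = np.repeat(np.arange(len(coords)), sphere_points)
    cand_tree = cKDTree(candidates)
    keep = np.ones(len(candidates), dtype=bool)
    for a in range(len(coords)):
        idx = np.asarray(cand_tree.query_ball_point(coords[a], radii[a] - 1e-9),
                         dtype=int)
        if idx.size:
            keep[idx[owner[idx] != a]] = False
    if not keep.any():  # pathological overlap; fall back to all points
        return candidates
    return candidates[keep]


def residue_depth(
    structure, probe: float = 1.4, sphere_points: int = 256
) -> np.ndarray:
    """Mean distance (A) of each residue's atoms to the sampled
    solvent-accessible surface.

    The surface is sampled with ``sphere_points`` quasi-uniform points per
    atom on spheres of radius vdW + probe; points inside any other atom's
    expanded sphere are discarded. Rigid-motion invariant by construction.
    """
    coords, res_index, elements = _atom_table(structure)
    if len(coords) < 4:
        raise ValueError("need at least 4 atoms")
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements]) + probe
    surface = _sampled_surface(coords, radii, sphere_points)
    dist_to_surface = cKDTree(surface).query(coords)[0]
    out = np.full(len(structure), np.nan)
    for i in range(len(structure)):
        mask = res_index == i
        if mask.any():
            out[i] = dist_to_surface[mask].mean()
    return out


def extract_features(
    structure,
    gnm_cutoff: float = 10.0,
    anm_cutoff: float = 15.0,
    n_modes: int = 50,
    probe: float = 1.4,
    sphere_points: int = 256,
) -> pd.DataFrame:
    """All per-residue features for one structure as a DataFrame.

    Atom-level residue depth is reduced to three columns — at the
    alpha-carbon, at the beta-carbon (the alpha-carbon for Gly) and the
    residue mean.
    """
    df = backbone_features(structure)
    df["gnm_fluctuation"] = gnm_fluctuations(structure.ca_coords, gnm_cutoff, n_modes)
    df["anm_fluctuation"] = anm_fluctuations(structure.ca_coords, anm_cutoff, n_modes)

    coords, res_index, elements = _atom_table(structure)
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements]) + probe
    depth_mean = residue_depth(structure, probe, sphere_points)
    # CA/CB depth reductions query the same sampled surface
    surf_tree = cKDTree(_sampled_surface(coords, radii, sphere_points))
    depth_ca = surf_tree.query(structure.ca_coords)[0]
    depth_cb = surf_tree.query(structure.cb_coords)[0]
    df["depth_ca"] = depth_ca
    df["depth_cb"] = depth_cb
    df["depth_mean"] = depth_mean
    return df


@dataclass
class FeatureMatrix:
    """structures x alignment columns x features, NaN at gap cells."""

    structure_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(self.structure_ids), self.values.shape[1], len(self.feature_names))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")

    @property
    def column_count(self) -> int:
        return self.values.shape[1]

    def drop_gap_columns(self) -> "FeatureMatrix":
        """Keep only columns with no missing cells (the usual ML
        preprocessing: discard alignment positions containing gaps)."""
        mask = np.isfinite(self.values).all(axis=(0, 2))
        return FeatureMatrix(
            self.structure_ids, self.feature_names, self.values[:, mask, :]
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per structure x column."""
        records = []
        for s, sid in enumerate(self.structure_ids):
            for c in range(self.column_count):
                records.append(
                    {"structure": sid, "column": c,
                     **dict(zip(self.feature_names, self.values[s, c]))}
                )
        return pd.DataFrame.from_records(records)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NaN")

    @classmethod
    def read_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        ids = list(dict.fromkeys(df["structure"]))
        features = [c for c in df.columns if c not in ("structure", "column")]
        n_cols = int(df["column"].max()) + 1
        values = np.full((len(ids), n_cols, len(features)), np.nan)
        for s, sid in enumerate(ids):
            sub = df[df["structure"] == sid]
            values[s, sub["column"].to_numpy()] = sub[features].to_numpy()
        return cls(ids, features, values)


def aligned_feature_matrix(msa, per_structure_features: dict[str, pd.DataFrame]) -> FeatureMatrix:
    """Scatter per-residue feature tables into alignment columns.

    ``per_structure_features`` maps structure id -> (N_residues x features)
    DataFrame; all tables must share the same feature columns. Gap cells
    are NaN.
    """
    ids = msa.structure_ids
    names = list(per_structure_features[ids[0]].columns)
    values = np.full((len(ids), msa.column_count, len(names)), np.nan)
    for s, sid in enumerate(ids):
        table = per_structure_features[sid]
        if list(table.columns) != names:
            raise ValueError(f"feature columns differ for structure {sid!r}")
        row = np.asarray(msa.rows[sid])
        n_res = (row != GAP).sum()
        if len(table) != n_res:
            raise ValueError(
                f"structure {sid!r}: {len(table)} feature rows for {n_res} residues"
            )
        cols = np.flatnonzero(row != GAP)
        values[s, cols, :] = table.to_numpy()[row[cols]]
    return FeatureMatrix(ids, names, values)
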