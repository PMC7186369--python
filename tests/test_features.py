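"""Structural features: elastic-network fluctuations against pseudo-inverse
oracles, backbone geometry read-back, residue depth, aligned matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import pinv
from scipy.spatial.distance import pdist, squareform

from stralign.features import (
    DisconnectedNetworkError,
    FeatureMatrix,
    aligned_feature_matrix,
    anm_fluctuations,
    backbone_features,
    extract_features,
    gnm_fluctuations,
    residue_depth,
)
from stralign.multiple import multiple_align
from stralign.synthetic import FixtureSpec, make_structure, random_rigid


def gnm_pinv_oracle(ca, cutoff=10.0):
    contact = squareform(pdist(ca) <= cutoff)
    gamma = -contact.astype(float)
    np.fill_diagonal(gamma, contact.sum(axis=1))
    return np.diag(pinv(gamma))


def anm_pinv_oracle(ca, cutoff=15.0):
    n = len(ca)
    diff = ca[:, None, :] - ca[None, :, :]
    dist2 = (diff**2).sum(axis=2)
    contact = (dist2 <= cutoff**2) & ~np.eye(n, dtype=bool)
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in np.flatnonzero(contact[i]):
            block = -np.outer(diff[i, j], diff[i, j]) / dist2[i, j]
            hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
    pi = pinv(hess)
    return np.array([np.trace(pi[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]) for i in range(n)])


class TestElasticNetworks:
    def test_gnm_all_modes_match_pseudoinverse(self, mixed_structure):
        ca = mixed_structure.ca_coords
        flucts = gnm_fluctuations(ca, n_modes=len(ca) - 1)
        oracle = gnm_pinv_oracle(ca)
        assert np.abs(flucts - oracle).max() / oracle.max() < 1e-6

    def test_anm_all_modes_match_pseudoinverse(self, mixed_structure):
        ca = mixed_structure.ca_coords
        flucts = anm_fluctuations(ca, n_modes=3 * len(ca) - 6)
        oracle = anm_pinv_oracle(ca)
        assert np.abs(flucts - oracle).max() / oracle.max() < 1e-6

    def test_fluctuations_nonnegative_and_termini_flexible(self, mixed_structure):
        ca = mixed_structure.ca_coords
        g = gnm_fluctuations(ca)
        a = anm_fluctuations(ca)
        assert (g >= 0).all() and (a >= 0).all()
        assert np.argmax(g) in (0, len(ca) - 1)

    def test_anm_rigid_motion_invariant(self, mixed_structure):
        moved = random_rigid(mixed_structure, seed=91)
        a1 = anm_fluctuations(mixed_structure.ca_coords)
        a2 = anm_fluctuations(moved.ca_coords)
        # fluctuations depend on pairwise distances only; soft modes make
        # the absolute scale large, so compare relatively
        assert np.abs(a1 - a2).max() / a1.max() < 1e-8

    def test_disconnected_contact_graph_rejected(self):
        ca = np.vstack([np.random.default_rng(0).normal(0, 2, (5, 3)),
                        np.random.default_rng(1).normal(100, 2, (5, 3))])
        with pytest.raises(DisconnectedNetworkError):
            gnm_fluctuations(ca)


class TestBackboneFeatures:
    def test_helix_torsions_read_back(self, helix20):
        feats = backbone_features(helix20)
        interior = feats.iloc[3:17]
        assert abs(interior["phi"].mean() + 57.0) < 10.0
        assert abs(interior["psi"].mean() + 47.0) < 10.0

    def test_terminal_torsions_missing(self, helix20):
        feats = backbone_features(helix20)
        assert np.isnan(feats.loc[0, "phi"])
        assert np.isnan(feats.loc[len(helix20) - 1, "psi"])
        assert np.isnan(feats.loc[0, "tco"])

    def test_helix_hbond_energies_negative(self, helix20):
        feats = backbone_features(helix20)
        assert (feats["hbond_energy"].iloc[4:15] < -0.5).all()

    def test_tco_near_one_in_helix(self, helix20):
        # consecutive carbonyls in a helix point the same way
        assert backbone_features(helix20)["tco"].iloc[5:15].mean() > 0.7

    def test_geometric_features_rigid_invariant(self, mixed_structure):
        moved = random_rigid(mixed_structure, seed=92)
        f1 = backbone_features(mixed_structure)
        f2 = backbone_features(moved)
        for col in ("alpha", "kappa", "phi", "psi", "tco", "hbond_energy"):
            np.testing.assert_allclose(f1[col], f2[col], atol=1e-6)


class TestResidueDepth:
    def test_single_residue_is_shallow(self):
        s = make_structure(FixtureSpec(blocks=[("helix", 1)]))
        depth = residue_depth(s)
        assert depth[0] <= 1.4 + 1.8

    def test_buried_center_is_deepest(self):
        """The innermost residue of a compact chain lies deeper than the
        most exposed one."""
        s = make_structure(
            FixtureSpec(blocks=[("helix", 12), ("turn", 2), ("helix", 12)])
        )
        depth = residue_depth(s)
        center = s.ca_coords - s.ca_coords.mean(axis=0)
        radius = np.linalg.norm(center, axis=1)
        assert depth[np.argmin(radius)] > depth[np.argmax(radius)]

    def test_rigid_motion_invariant(self, mixed_structure):
        moved = random_rigid(mixed_structure, seed=93)
        assert np.abs(
            residue_depth(mixed_structure) - residue_depth(moved)
        ).max() < 1e-8


@pytest.fixture(scope="module")
def fam_and_matrix(mixed_structure):
    fam = [random_rigid(mixed_structure, seed=i, new_id=f"s{i}") for i in range(2)]
    msa = multiple_align(fam)
    per_structure = {s.id: extract_features(s) for s in fam}
    return fam, msa, aligned_feature_matrix(msa, per_structure)


class TestAlignedFeatureMatrix:
    def test_gap_free_alignment_has_no_gap_missing_cells(self, fam_and_matrix):
        fam, msa, matrix = fam_and_matrix
        assert msa.gapless_column_mask().all()
        # features defined everywhere (network models, depth, accessibility)
        for name in ("gnm_fluctuation", "anm_fluctuation", "depth_ca", "accessibility"):
            k = matrix.feature_names.index(name)
            assert np.isfinite(matrix.values[:, :, k]).all()

    def test_gap_cells_are_missing(self, mixed_structure):
        from stralign.synthetic import delete_residues

        short = delete_residues(mixed_structure, 20, 4, new_id="short")
        fam = [random_rigid(mixed_structure, seed=5, new_id="full"), short]
        msa = multiple_align(fam)
        # wider network cutoff: the deletion splits the 10 A contact graph
        matrix = aligned_feature_matrix(
            msa, {s.id: extract_features(s, gnm_cutoff=20.0, anm_cutoff=22.0) for s in fam}
        )
        gap_cols = np.flatnonzero(~msa.gapless_column_mask())
        s_idx = matrix.structure_ids.index("short")
        assert len(gap_cols) == 4
        assert np.isnan(matrix.values[s_idx, gap_cols, :]).all()

    def test_drop_gap_columns_removes_all_missing(self, mixed_structure):
        from stralign.synthetic import delete_residues

        short = delete_residues(mixed_structure, 20, 4, new_id="short")
        fam = [random_rigid(mixed_structure, seed=5, new_id="full"), short]
        msa = multiple_align(fam)
        matrix = aligned_feature_matrix(
            msa, {s.id: extract_features(s, gnm_cutoff=20.0, anm_cutoff=22.0) for s in fam}
        ).drop_gap_columns()
        assert np.isfinite(matrix.values).all()

    def test_tsv_round_trip_preserves_missing(self, fam_and_matrix, tmp_path):
        _, _, matrix = fam_and_matrix
        path = tmp_path / "features.tsv"
        matrix.write_tsv(path)
        back = FeatureMatrix.read_tsv(path)
        assert back.feature_names == matrix.feature_names
        assert np.array_equal(np.isnan(back.values), np.isnan(matrix.values))
        np.testing.assert_allclose(
            np.nan_to_num(back.values), np.nan_to_num(matrix.values), atol=1e-8
        )

    def test_length_mismatch_names_structure(self, fam_and_matrix):
        fam, msa, _ = fam_and_matrix
        bad = {s.id: extract_features(s) for s in fam}
        bad[fam[0].id] = bad[fam[0].id].iloc[:-1]
        with pytest.raises(ValueError, match=fam[0].id):
            aligned_feature_matrix(msa, bad)
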