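"""Kabsch superposition and the two coarse initial-superposition strategies."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stralign.superpose import (
    RigidTransform,
    SuperpositionError,
    kabsch,
    make_segments,
    rmsd,
    score_signal,
    secondary_superpose,
    signal_superpose,
)
from stralign.synthetic import FixtureSpec, make_structure, perturb, random_rigid


class TestKabsch:
    def test_identity_on_identical_sets(self):
        x = np.random.default_rng(0).normal(size=(8, 3))
        t = kabsch(x, x)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0.0, atol=1e-12)
        assert rmsd(t.apply(x), x) < 1e-12

    def test_recovers_random_rotations(self):
        """50 seeded random rigid motions are recovered to 1e-8 and the
        post-transform RMSD vanishes."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            x = rng.normal(size=(10, 3))
            rot = Rotation.random(rng=rng).as_matrix()
            trans = rng.uniform(-20, 20, 3)
            y = x @ rot.T + trans
            t = kabsch(x, y)
            assert np.abs(t.rotation - rot).max() < 1e-8
            assert np.abs(t.translation - trans).max() < 1e-8
            assert rmsd(t.apply(x), y) < 1e-8

    def test_rmsd_matches_direct_svd_oracle(self):
        """With one displaced point the Kabsch RMSD equals an independent
        SVD recomputation (scipy's vector aligner on centered sets)."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=(6, 3))
        y = x.copy()
        y[2] += [1.5, -0.5, 0.2]
        t = kabsch(x, y)
        rot_ref, _ = Rotation.align_vectors(y - y.mean(0), x - x.mean(0))
        ref = rmsd((x - x.mean(0)) @ rot_ref.as_matrix().T + y.mean(0), y)
        assert rmsd(t.apply(x), y) == pytest.approx(ref, abs=1e-9)

    def test_never_increases_rmsd(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(size=(12, 3))
            y = x + rng.normal(0, 1.0, size=(12, 3))
            assert rmsd(kabsch(x, y).apply(x), y) <= rmsd(x, y) + 1e-12

    def test_rotations_are_proper(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=(5, 3))
            y = rng.normal(size=(5, 3))
            t = kabsch(x, y)
            assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-6)
            assert np.allclose(t.rotation @ t.rotation.T, np.eye(3), atol=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSegments:
    def test_segment_counts(self):
        s30 = make_structure(FixtureSpec(blocks=[("helix", 30)]))
        s40 = make_structure(FixtureSpec(blocks=[("helix", 40)]))
        assert len(make_segments(s30)) == 1
        assert len(make_segments(s40)) == 11

    def test_anchor_distance_is_zero(self):
        s = make_structure(FixtureSpec(blocks=[("helix", 35)]))
        for seg in make_segments(s, "first"):
            assert seg.signal[0] == 0.0
        for seg in make_segments(s, "last"):
            assert seg.signal[-1] == 0.0

    def test_signals_are_rotation_invariant(self, mixed_structure):
        moved = random_rigid(mixed_structure, seed=9)
        for a, b in zip(make_segments(mixed_structure), make_segments(moved)):
            assert np.abs(a.signal - b.signal).max() < 1e-10

    def test_short_chain_shrinks_window(self):
        s = make_structure(FixtureSpec(blocks=[("helix", 24)]))
        segs = make_segments(s)
        assert len(segs[0].signal) == 12
        assert len(segs) == 24 - 12 + 1


class TestScoreSignal:
    def test_identical_segments_score_one(self, mixed_structure):
        seg = make_segments(mixed_structure)[0]
        assert score_signal(seg, seg) == pytest.approx(1.0)

    def test_constant_offset_halves_score_at_ln2_width(self, mixed_structure):
        seg = make_segments(mixed_structure)[0]
        shifted = make_segments(mixed_structure)[0]
        shifted.signal = seg.signal + np.sqrt(10 * np.log(2))
        assert score_signal(seg, shifted) == pytest.approx(0.5)

    def test_matches_elementwise_recomputation(self, mixed_structure):
        rng = np.random.default_rng(13)
        a, b = make_segments(mixed_structure)[:2]
        b.signal = b.signal + rng.normal(0, 1, len(b.signal))
        expected = float(np.median(np.exp(-((a.signal - b.signal) ** 2) / 10.0)))
        assert score_signal(a, b) == pytest.approx(expected)

    def test_length_mismatch_rejected(self, mixed_structure):
        a = make_segments(mixed_structure)[0]
        b = make_segments(mixed_structure)[0]
        b.signal = b.signal[:-1]
        with pytest.raises(ValueError):
            score_signal(a, b)


class TestSignalSuperpose:
    def test_exact_copy_re_superposes_perfectly(self, mixed_structure):
        moved = random_rigid(mixed_structure, seed=21)
        t = signal_superpose(mixed_structure, moved)
        assert rmsd(t.apply(mixed_structure.ca_coords), moved.ca_coords) < 1e-6

    def test_noisy_copy_superposes_closely(self, mixed_structure):
        noisy = perturb(random_rigid(mixed_structure, seed=22), 0.3, seed=23)
        t = signal_superpose(mixed_structure, noisy)
        assert rmsd(t.apply(mixed_structure.ca_coords), noisy.ca_coords) < 1.0

    def test_too_short_chain_rejected(self):
        s = make_structure(FixtureSpec(blocks=[("helix", 8)]))
        with pytest.raises(SuperpositionError):
            signal_superpose(s, s)

    def test_equivariant_under_pre_rotation(self, mixed_structure):
        """Pre-rotating the first structure changes the returned transform
        by exactly that rotation."""
        moved = random_rigid(mixed_structure, seed=31)
        pre = random_rigid(mixed_structure, seed=32)
        t_direct = signal_superpose(mixed_structure, moved)
        t_pre = signal_superpose(pre, moved)
        # recover the pre-rotation: t_direct == t_pre o (pre-transform)
        from stralign.superpose import kabsch as _kabsch

        pre_t = _kabsch(mixed_structure.ca_coords, pre.ca_coords)
        composed = t_pre.compose(pre_t)
        assert np.abs(composed.rotation - t_direct.rotation).max() < 1e-6
        assert np.abs(composed.translation - t_direct.translation).max() < 1e-6


class TestSecondarySuperpose:
    def test_identical_mixed_structure_re_superposes(self, mixed_structure):
        moved = random_rigid(mixed_structure, seed=41)
        t = secondary_superpose(mixed_structure, moved)
        assert rmsd(t.apply(mixed_structure.ca_coords), moved.ca_coords) < 1e-6

    def test_all_coil_vs_all_helix_fails(self, helix20):
        coil = make_structure(FixtureSpec(blocks=[("loop", 20)], seed=8))
        with pytest.raises(SuperpositionError):
            secondary_superpose(coil, helix20)

    def test_unassigned_codes_rejected(self, helix20):
        bare = make_structure(FixtureSpec(blocks=[("helix", 20)]))
        bare.sec_codes = "-" * 20
        with pytest.raises(SuperpositionError):
            secondary_superpose(bare, helix20)


def test_rigid_transform_compose_and_inverse():
    rng = np.random.default_rng(55)
    t1 = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
    t2 = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
    x = rng.normal(size=(4, 3))
    assert np.allclose(t1.compose(t2).apply(x), t1.apply(t2.apply(x)))
    assert np.allclose(t1.inverse().apply(t1.apply(x)), x, atol=1e-12)
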