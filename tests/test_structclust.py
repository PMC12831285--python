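"""Ensemble frame, CC matrix, state embedding and hinge decomposition."""

import numpy as np
import pytest

from foldguide import fixtures as fx
from foldguide import structclust as sc
from foldguide.structures import CA, StructureModel

from oracles import grid_embed_residual_3


def _ca_structure(coords, name="toy"):
    n = coords.shape[0]
    pos = np.zeros((n, 37, 3))
    mask = np.zeros((n, 37))
    pos[:, CA, :] = coords
    mask[:, CA] = 1.0
    return StructureModel(
        chain_ids=np.full(n, "A", dtype="U4"),
        residue_numbers=np.arange(1, n + 1, dtype=np.int64),
        aatype=np.zeros(n, dtype=np.int64),
        atom_positions=pos, atom_mask=mask, name=name)


class TestBuildFrame:
    def test_identical_structures_zero_deviation(self, helix20):
        frame = sc.build_frame([helix20, helix20.copy()])
        assert frame.n_common == 20
        assert np.allclose(frame.coords[0], frame.coords[1])
        assert np.allclose(frame.coords[0], frame.mean_coords, atol=1e-9)

    def test_translation_removed(self, helix20):
        import foldguide.geometry as geo
        moved = helix20.transformed(np.eye(3), np.array([10.0, -4.0, 2.0]))
        frame = sc.build_frame([helix20, moved])
        assert np.allclose(frame.coords[0], frame.coords[1], atol=1e-9)

    def test_two_state_mean_between_states(self, two_state_ensemble):
        structures, labels = two_state_ensemble
        frame = sc.build_frame(structures)
        d0 = np.linalg.norm(frame.coords[0] - frame.mean_coords)
        d1 = np.linalg.norm(frame.coords[1] - frame.mean_coords)
        assert d0 > 1.0 and d1 > 1.0  # mean sits between the states

    def test_insufficient_overlap_rejected(self):
        rng = np.random.default_rng(0)
        a = _ca_structure(rng.normal(size=(5, 3)))
        b = _ca_structure(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="common"):
            sc.build_frame([a, b])


class TestCCMatrix:
    def test_duplicate_members_correlate_fully(self, helix20):
        wiggled = helix20.copy()
        rng = np.random.default_rng(3)
        wiggled.atom_positions = wiggled.atom_positions + rng.normal(
            scale=0.5, size=wiggled.atom_positions.shape)
        frame = sc.build_frame([helix20, helix20.copy(), wiggled])
        cc = sc.cc_matrix(frame)
        assert cc.values[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(cc.values, cc.values.T)
        assert np.allclose(np.diag(cc.values), 1.0)

    def test_mirror_displacement_anticorrelates(self):
        rng = np.random.default_rng(1)
        base = rng.normal(scale=5.0, size=(30, 3))
        d = rng.normal(scale=0.5, size=(30, 3))
        frame = sc.build_frame([_ca_structure(base + d),
                                _ca_structure(base - d)])
        cc = sc.cc_matrix(frame)
        assert cc.values[0, 1] == pytest.approx(-1.0, abs=1e-6)

    def test_orthogonal_displacements_uncorrelated(self):
        # four members: +-u on atom 3 (x) and +-v on atom 17 (y); the u- and
        # v-patterns are orthogonal deviation directions
        rng = np.random.default_rng(2)
        base = rng.normal(scale=6.0, size=(30, 3))
        u = np.zeros((30, 3)); u[3, 0] = 0.5
        v = np.zeros((30, 3)); v[17, 1] = 0.5
        frame = sc.build_frame([_ca_structure(base + u),
                                _ca_structure(base - u),
                                _ca_structure(base + v),
                                _ca_structure(base - v)])
        cc = sc.cc_matrix(frame)
        assert abs(cc.values[0, 2]) < 0.05
        assert cc.values[0, 1] == pytest.approx(-1.0, abs=1e-3)

    def test_degenerate_members_flagged_and_correlated(self, helix20):
        # all members identical: zero deviation norms, flagged, pairwise CC 1
        frame = sc.build_frame([helix20, helix20.copy(), helix20.copy()])
        cc = sc.cc_matrix(frame)
        assert cc.degenerate.all()
        assert np.allclose(cc.values, 1.0)


class TestEmbed:
    def test_all_correlated_collapse_to_point(self):
        cc = sc.CCMatrix(values=np.ones((3, 3)))
        emb = sc.embed(cc, d=2, seed=0)
        assert emb.residual < 1e-6
        assert emb.n_clusters == 1
        d01 = np.linalg.norm(emb.vectors[0] - emb.vectors[1])
        assert d01 < 1e-3

    def test_planted_two_cluster_recovered(self):
        n = 8
        cc = np.full((n, n), 0.2)
        for i in range(n):
            for j in range(n):
                if (i < 4) == (j < 4):
                    cc[i, j] = 0.95
        np.fill_diagonal(cc, 1.0)
        emb = sc.embed(sc.CCMatrix(values=cc), d=2, seed=0, k=2)
        labels = emb.cluster_labels
        assert len(set(labels[:4].tolist())) == 1
        assert len(set(labels[4:].tolist())) == 1
        assert labels[0] != labels[-1]

    def test_three_structure_residual_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        # a CC matrix that is not exactly embeddable in 2-D unit vectors
        cc = np.array([[1.0, 0.7, -0.2],
                       [0.7, 1.0, 0.5],
                       [-0.2, 0.5, 1.0]])
        emb = sc.embed(sc.CCMatrix(values=cc), d=2, seed=0)
        oracle = grid_embed_residual_3(cc)
        assert emb.residual == pytest.approx(oracle, abs=1e-3)

    def test_residual_non_increasing_with_dimension(self, two_state_ensemble):
        structures, _ = two_state_ensemble
        frame = sc.build_frame(structures)
        cc = sc.cc_matrix(frame)
        r2 = sc.embed(cc, d=2, seed=0).residual
        rn = sc.embed(cc, d=cc.n - 1, seed=0).residual
        assert rn <= r2 + 1e-9

    def test_unit_ball_constraint(self, two_state_ensemble):
        structures, _ = two_state_ensemble
        frame = sc.build_frame(structures)
        emb = sc.embed(sc.cc_matrix(frame), d=2, seed=0)
        assert np.all(np.linalg.norm(emb.vectors, axis=1) <= 1.0 + 1e-6)


class TestHinges:
    def test_duplicated_structure_one_group(self, helix20):
        frame = sc.build_frame([helix20, helix20.copy()])
        rd = sc.hinges(frame)
        assert rd.n_groups == 1
        assert rd.hinge_boundaries == []

    def test_two_block_recovery(self):
        structures, _ = fx.make_two_state_ensemble(fx.FixtureSpec(
            kind="two_state_ensemble", hinge_angle=0.0, delta_angle=30.0,
            noise=0.1, n_members=6, seed=9))
        frame = sc.build_frame(structures)
        rd = sc.hinges(frame, tol=1.5)
        lab = rd.labels
        assert rd.n_groups == 2
        assert len(set(lab[:40].tolist())) == 1
        assert len(set(lab[45:].tolist())) == 1
        assert lab[0] != lab[-1]
        assert len(rd.hinge_boundaries) == 1
        assert 40 <= rd.hinge_boundaries[0] <= 45
        # the moving block varies more than rigid-internal noise
        for g, (lo, hi) in rd.group_rmsd_range.items():
            assert hi < 1.0

    def test_infinite_tolerance_single_group(self, two_state_ensemble):
        structures, _ = two_state_ensemble
        frame = sc.build_frame(structures)
        rd = sc.hinges(frame, tol=1e9)
        assert rd.n_groups == 1


class TestClassifyStates:
    def test_references_propagate_to_cluster_members(self, two_state_ensemble):
        structures, truth = two_state_ensemble
        frame = sc.build_frame(structures)
        emb = sc.embed(sc.cc_matrix(frame), d=2, seed=0, k=2)
        refs = {int(np.nonzero(truth == 0)[0][0]): "inward",
                int(np.nonzero(truth == 1)[0][0]): "outward"}
        report = sc.classify_states(emb, refs)
        assert not report.ambiguous
        expected = ["inward" if t == 0 else "outward" for t in truth]
        assert report.labels == expected

    def test_single_cluster_single_state(self, helix20):
        frame = sc.build_frame([helix20, helix20.copy(), helix20.copy()])
        emb = sc.embed(sc.cc_matrix(frame), d=2, seed=0)
        report = sc.classify_states(emb)
        assert len(set(report.labels)) == 1

    def test_conflicting_references_flagged(self, two_state_ensemble):
        structures, truth = two_state_ensemble
        frame = sc.build_frame(structures)
        emb = sc.embed(sc.cc_matrix(frame), d=2, seed=0, k=2)
        same = np.nonzero(truth == 0)[0][:2]
        refs = {int(same[0]): "inward", int(same[1]): "outward"}
        report = sc.classify_states(emb, refs)
        assert report.ambiguous


def test_cc_invariant_to_member_rigid_motions(two_state_ensemble):
    from foldguide.geometry import rotation_about_axis
    structures, _ = two_state_ensemble
    cc0 = sc.cc_matrix(sc.build_frame(structures)).values
    moved = [s.transformed(rotation_about_axis([1.0, 0.3, -2.0], 25.0 + i),
                           np.array([3.0 * i, -2.0, 1.0]))
             for i, s in enumerate(structures)]
    cc1 = sc.cc_matrix(sc.build_frame(moved)).values
    assert np.allclose(cc0, cc1, atol=1e-6)
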