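"""Structure-to-template conversion, relabeling, truncation and clustering."""

import numpy as np
import pytest

from foldguide import fixtures as fx
from foldguide.feature_store import QueryFeatures
from foldguide.msa_ops import RegionSelection
from foldguide.structures import ATOM37_INDEX, BACKBONE_CB_SLOTS, CA
from foldguide.template_ops import (AlignmentMap, LowIdentityError,
                                    RelabelMode, align_sequences,
                                    cluster_templates, multi_chain_template,
                                    relabel_template, structure_to_template,
                                    truncate_to_cbeta)

from conftest import identity_templates
from oracles import brute_force_alignment

ALA = 0


@pytest.fixture
def helix_template(helix20):
    q = QueryFeatures.from_sequence(helix20.sequence)
    return q, structure_to_template(helix20, q)


class TestStructureToTemplate:
    def test_identical_sequences_identity_mapping(self, helix20):
        q = QueryFeatures.from_sequence(helix20.sequence)
        t = structure_to_template(helix20, q)
        assert t.covered.all()
        assert np.array_equal(t.labels, q.aatype)
        # coordinates are copied verbatim: no rotation applied
        assert np.allclose(t.atom_positions[:, CA],
                           helix20.atom_positions[:, CA])

    def test_low_identity_needs_explicit_mapping(self, helix20):
        # a distant template (like an 11%-identity transporter) is refused
        # on auto-alignment but accepted with a user-supplied mapping
        q = QueryFeatures.from_sequence("W" * len(helix20))
        with pytest.raises(LowIdentityError):
            structure_to_template(helix20, q)
        amap = AlignmentMap(pairs=[(i, i) for i in range(len(helix20))],
                            identity=0.11)
        t = structure_to_template(helix20, q, mapping=amap)
        assert t.covered.all()

    def test_auto_alignment_matches_enumeration_oracle(self):
        query, template = "ACDEFGHK", "CDEFGH"
        amap = align_sequences(query, template)
        assert amap.pairs == brute_force_alignment(query, template)

    def test_placement_restricts_coverage(self, helix20):
        q = QueryFeatures.from_sequence(helix20.sequence)
        t = structure_to_template(helix20, q,
                                  placement=RegionSelection([("*", 5, 10)]))
        covered = np.nonzero(t.covered)[0]
        assert covered.min() >= 4 and covered.max() <= 9


class TestRelabel:
    def test_polyalanine(self, helix_template):
        q, t = helix_template
        out = relabel_template(t, "polyalanine", q)
        assert np.all(out.labels[out.covered] == ALA)

    def test_polyalanine_with_query_window(self):
        # polyalanine except an 11-residue hinge (81-91) carrying the query
        # sequence: exactly 11 positions keep non-Ala labels
        big = fx.make_structure(fx.FixtureSpec(kind="two_block_hinge",
                                               lengths=(80, 11, 80)))
        q = QueryFeatures.from_sequence(big.sequence)
        t = structure_to_template(big, q)
        mode = RelabelMode(mode="polyalanine",
                           exception=RegionSelection([("*", 81, 91)]),
                           exception_mode="query")
        out = relabel_template(t, mode, q)
        window = out.labels[80:91]
        assert np.array_equal(window, q.aatype[80:91])
        outside = np.concatenate([out.labels[:80], out.labels[91:]])
        assert np.all(outside == ALA)
        assert int((out.labels != ALA).sum()) == int(
            (q.aatype[80:91] != ALA).sum())

    def test_keep_is_identity_and_coverage_invariant(self, helix_template):
        q, t = helix_template
        out = relabel_template(t, "keep", q)
        assert np.array_equal(out.labels, t.labels)
        for mode in ("polyalanine", "query"):
            out = relabel_template(t, mode, q)
            assert np.array_equal(out.covered, t.covered)

    def test_custom_length_mismatch(self, helix_template):
        q, t = helix_template
        with pytest.raises(ValueError, match="length"):
            relabel_template(t, RelabelMode(mode="custom", sequence="AAA"), q)


class TestTruncateToCbeta:
    def test_only_backbone_and_cbeta_remain(self):
        s = fx.make_structure(fx.FixtureSpec(kind="helix", lengths=(12,),
                                             sequence="AVGLKDERSTWY"))
        q = QueryFeatures.from_sequence(s.sequence)
        t = structure_to_template(s, q)
        out = truncate_to_cbeta(t)
        keep = set(BACKBONE_CB_SLOTS)
        for slot in range(37):
            if slot not in keep:
                assert np.all(out.atom_mask[:, slot] == 0)
        # glycine keeps 4 atoms (no CB)
        g = s.sequence.index("G")
        assert out.atom_mask[g, ATOM37_INDEX["CB"]] == 0
        assert int(out.atom_mask[g].sum()) == 4

    def test_idempotent_and_coverage_invariant(self, helix_template):
        _, t = helix_template
        once = truncate_to_cbeta(t)
        twice = truncate_to_cbeta(once)
        assert np.array_equal(once.atom_mask, twice.atom_mask)
        assert np.array_equal(once.atom_positions, twice.atom_positions)
        assert np.array_equal(once.covered, t.covered)


class TestMultiChainTemplate:
    def test_dimer_interface_geometry_preserved(self):
        # a dimer source assigned to the two chain regions of a homodimer
        # plan keeps the inter-chain geometry verbatim
        comp = fx.make_toy_complex(fx.FixtureSpec(kind="toy_complex",
                                                  lengths=(24,)))
        n = 24
        seq = comp.select_chain("A").sequence
        query = QueryFeatures.from_sequence(seq + seq)
        a, b = comp.select_chain("A"), comp.select_chain("B")
        map_a = AlignmentMap(pairs=[(i, i) for i in range(n)])
        map_b = AlignmentMap(pairs=[(n + i, i) for i in range(n)])
        t = multi_chain_template([(a, map_a, None), (b, map_b, None)], query)
        assert t.covered.all()
        d = np.linalg.norm(t.atom_positions[:n, CA].mean(axis=0)
                           - t.atom_positions[n:, CA].mean(axis=0))
        d_src = np.linalg.norm(a.ca_coords.mean(axis=0)
                               - b.ca_coords.mean(axis=0))
        assert d == pytest.approx(d_src)

    def test_single_chain_leaves_other_uncovered(self):
        comp = fx.make_toy_complex(fx.FixtureSpec(kind="toy_complex",
                                                  lengths=(24,)))
        seq = comp.select_chain("A").sequence
        query = QueryFeatures.from_sequence(seq + seq)
        a = comp.select_chain("A")
        map_a = AlignmentMap(pairs=[(i, i) for i in range(24)])
        t = multi_chain_template([(a, map_a, None)], query)
        assert t.covered[:24].all()
        assert not t.covered[24:].any()

    def test_overlap_rejected(self, helix20):
        q = QueryFeatures.from_sequence(helix20.sequence)
        amap = AlignmentMap(pairs=[(i, i) for i in range(20)])
        with pytest.raises(ValueError, match="overlap"):
            multi_chain_template([(helix20, amap, None),
                                  (helix20, amap, None)], q)


class TestClusterTemplates:
    def test_two_state_partition_recovered(self, two_state_ensemble):
        structures, truth = two_state_ensemble
        _, templates = identity_templates(structures)
        result = cluster_templates(templates, k=2, seed=0)
        # label agreement up to permutation
        agree = max(
            np.mean(result.labels == truth),
            np.mean(result.labels == 1 - truth))
        assert agree == 1.0

    def test_unbalanced_partition_recovered(self):
        structures, truth = fx.make_two_state_ensemble(fx.FixtureSpec(
            kind="two_state_ensemble", hinge_angle=5.0, delta_angle=30.0,
            noise=0.2, n_members=8, seed=4))
        # rebuild as 5 + 3 by dropping three members of one state
        keep = [i for i in range(8) if truth[i] == 0] \
            + [i for i in range(8) if truth[i] == 1][:3]
        subset = [structures[i] for i in keep]
        sub_truth = np.array([truth[i] for i in keep])
        _, templates = identity_templates(subset)
        result = cluster_templates(templates, k=2, seed=0)
        agree = max(np.mean(result.labels == sub_truth),
                    np.mean(result.labels == 1 - sub_truth))
        assert agree == 1.0

    def test_identical_templates_single_group(self, helix20):
        q, templates = identity_templates([helix20, helix20, helix20])
        # need >= 20 common CAs: helix20 has exactly 20
        result = cluster_templates(templates, k="auto", seed=0)
        assert len(result.groups) == 1

    def test_k3_deterministic(self, two_state_ensemble):
        structures, _ = two_state_ensemble
        _, templates = identity_templates(structures)
        a = cluster_templates(templates, k=3, seed=7)
        b = cluster_templates(templates, k=3, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert len(a.groups) == 3

    def test_insufficient_coverage_rejected(self):
        s = fx.make_structure(fx.FixtureSpec(kind="helix", lengths=(10,)))
        _, templates = identity_templates([s, s])
        with pytest.raises(ValueError, match="coverage"):
            cluster_templates(templates)
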