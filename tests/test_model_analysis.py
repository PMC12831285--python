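"""Superposition, stereochemistry, compactness, interfaces and ranking."""

import json

import numpy as np
import pytest

from foldguide import fixtures as fx
from foldguide.geometry import rotation_about_axis
from foldguide.model_analysis import (RankReport, compactness,
                                      interface_metrics,
                                      ramachandran_outliers, rank_models,
                                      superpose, write_report)
from foldguide.structures import CA, StructureModel

from oracles import grid_superpose_rmsd


def _toy(n, seed):
    rng = np.random.default_rng(seed)
    coords = rng.normal(scale=2.0, size=(n, 3))
    pos = np.zeros((n, 37, 3))
    mask = np.zeros((n, 37))
    pos[:, CA] = coords
    mask[:, CA] = 1.0
    return StructureModel(chain_ids=np.full(n, "A", dtype="U4"),
                          residue_numbers=np.arange(1, n + 1, dtype=np.int64),
                          aatype=np.zeros(n, dtype=np.int64),
                          atom_positions=pos, atom_mask=mask, name=f"t{seed}")


class TestSuperpose:
    def test_identity(self, helix20):
        sp = superpose(helix20, helix20.copy())
        assert sp.rmsd == pytest.approx(0.0, abs=1e-12)
        assert sp.n_aligned == 20

    def test_rigid_motion_invariance(self, helix20):
        moved = helix20.transformed(rotation_about_axis([1, 2, 3], 73.0),
                                    np.array([4.0, -7.0, 11.0]))
        sp = superpose(moved, helix20)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(sp.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric(self):
        a, b = _toy(8, 1), _toy(8, 2)
        assert superpose(a, b).rmsd == pytest.approx(superpose(b, a).rmsd,
                                                     abs=1e-9)

    def test_matches_orientation_grid_oracle(self):
        rng = np.random.default_rng(12)
        for seed in range(5):
            n = int(rng.integers(4, 11))
            a = _toy(n, seed)
            R = rotation_about_axis(rng.normal(size=3), float(rng.uniform(0, 180)))
            b = a.transformed(R, rng.normal(size=3))
            b.atom_positions[:, CA] += rng.normal(scale=0.3, size=(n, 3))
            sp = superpose(a, b)
            oracle = grid_superpose_rmsd(a.atom_positions[:, CA],
                                         b.atom_positions[:, CA])
            assert sp.rmsd == pytest.approx(oracle, abs=1e-4)

    def test_too_few_pairs_rejected(self):
        a, b = _toy(2, 3), _toy(2, 4)
        with pytest.raises(ValueError):
            superpose(a, b)


class TestRamachandran:
    def test_ideal_helix_has_no_outliers(self, helix20):
        frac, detail = ramachandran_outliers(helix20)
        assert frac == 0.0
        assert detail["n_classified"] == 18

    def test_ideal_strand_has_no_outliers(self):
        s = fx.make_structure(fx.FixtureSpec(kind="strand", lengths=(15,)))
        frac, _ = ramachandran_outliers(s)
        assert frac == 0.0

    def test_forced_left_handed_outlier_flagged(self):
        # phi +60, psi -120 sits outside every allowed region for non-Gly
        phi_psi = [fx.PHI_PSI["helix"]] * 9
        phi_psi[4] = (60.0, -120.0)
        backbone = fx.build_backbone(phi_psi)
        m = fx._assemble("AAAAVAAAA", backbone, name="forced")
        frac, detail = ramachandran_outliers(m)
        assert detail["flags"][4]
        assert frac == pytest.approx(1.0 / detail["n_classified"])

    def test_glycine_unrestricted(self):
        phi_psi = [fx.PHI_PSI["helix"]] * 9
        phi_psi[4] = (60.0, -120.0)
        backbone = fx.build_backbone(phi_psi)
        m = fx._assemble("AAAAGAAAA", backbone, name="gly")
        frac, _ = ramachandran_outliers(m)
        assert frac == 0.0

    def test_degenerate_chain_reports_zero_with_flag(self):
        m = fx.make_structure(fx.FixtureSpec(kind="helix", lengths=(2,)))
        frac, detail = ramachandran_outliers(m)
        assert frac == 0.0
        assert detail["n_classified"] == 0


class TestCompactness:
    def test_collapsed_scores_zero(self):
        m = _toy(10, 0)
        m.atom_positions[:, CA] = 0.0
        assert compactness(m) == 0.0

    def test_extended_chain_scores_high(self):
        m = fx.make_structure(fx.FixtureSpec(kind="extended", lengths=(50,)))
        assert compactness(m) > 2.0

    def test_rotation_invariant(self, helix20):
        moved = helix20.transformed(rotation_about_axis([0, 1, 0], 55.0),
                                    np.array([1.0, 2.0, 3.0]))
        assert compactness(moved) == pytest.approx(compactness(helix20),
                                                   abs=1e-9)


class TestInterfaces:
    def test_separated_chains_zero(self):
        hb = fx.make_hbond_strand_pair()
        far = hb.copy()
        sel = far.chain_ids == "B"
        far.atom_positions[sel] += np.array([100.0, 0.0, 0.0])
        rep = interface_metrics(far, ("A", "B"))
        assert rep.buried_area == 0.0
        assert rep.hbond_count == 0
        assert rep.tier == "none"

    def test_four_canonical_backbone_hbonds(self):
        rep = interface_metrics(fx.make_hbond_strand_pair(), ("A", "B"))
        assert rep.hbond_count == 4
        assert rep.buried_area > 0.0

    def test_symmetric_in_chain_order(self):
        hb = fx.make_hbond_strand_pair()
        ab = interface_metrics(hb, ("A", "B"))
        ba = interface_metrics(hb, ("B", "A"))
        assert ab.buried_area == pytest.approx(ba.buried_area, abs=1e-6)
        assert ab.hbond_count == ba.hbond_count

    def test_burial_grows_on_approach(self):
        comp = fx.make_toy_complex(fx.FixtureSpec(kind="toy_complex",
                                                  lengths=(24,)))
        sel = comp.chain_ids == "B"
        areas = []
        for extra in (20.0, 6.0, 0.0):
            m = comp.copy()
            m.atom_positions[sel] += np.array([0.0, 0.0, 0.0]) \
                + extra * np.array([0.57735] * 3)
            areas.append(interface_metrics(m, ("A", "B")).buried_area)
        assert areas[0] <= areas[1] <= areas[2]

    def test_missing_chain_rejected(self):
        hb = fx.make_hbond_strand_pair()
        with pytest.raises(ValueError, match="chain"):
            interface_metrics(hb, ("A", "Z"))


class TestRanking:
    def test_single_model_rank_one(self, helix20):
        report = rank_models([helix20])
        assert report.best.name == helix20.name

    def test_higher_plddt_wins(self, helix20):
        low = helix20.copy()
        low.confidence = np.full(20, 69.0)
        low.name = "low"
        high = helix20.copy()
        high.confidence = np.full(20, 88.0)
        high.name = "high"
        report = rank_models([low, high])
        assert [e.name for e in report.entries] == ["high", "low"]

    def test_missing_required_interface_outranks_plddt(self):
        comp = fx.make_toy_complex(fx.FixtureSpec(kind="toy_complex",
                                                  lengths=(24,)))
        comp.confidence = np.full(len(comp), 60.0)
        broken = comp.copy()
        broken.name = "apart"
        broken.confidence = np.full(len(comp), 95.0)
        sel = broken.chain_ids == "B"
        broken.atom_positions[sel] += np.array([200.0, 0.0, 0.0])
        report = rank_models([broken, comp],
                             declared_interfaces=[("A", "B")])
        assert report.best.name == comp.name
        assert report.entries[-1].missing_required_interfaces == 1

    def test_permutation_invariant(self, helix20):
        models = []
        for i, conf in enumerate((55.0, 90.0, 73.0)):
            m = helix20.copy()
            m.confidence = np.full(20, conf)
            m.name = f"m{i}"
            models.append(m)
        order1 = [e.name for e in rank_models(models).entries]
        order2 = [e.name for e in rank_models(models[::-1]).entries]
        assert order1 == order2 == ["m1", "m2", "m0"]


class TestReport:
    def test_json_twin_round_trips(self, tmp_path, helix20):
        report = rank_models([helix20])
        paths = write_report(report, tmp_path)
        with open(paths["json"]) as fh:
            loaded = RankReport.from_dict(json.load(fh))
        assert loaded.to_dict()["ranking"] == report.to_dict()["ranking"]
        assert (tmp_path / "report.html").exists()
        assert (tmp_path / "session.pml").exists()

    def test_report_lists_provenance(self, tmp_path):
        from foldguide.feature_store import empty_features
        from foldguide.runtime import MockBackend
        fs = empty_features("ACDEFGHIKLMNP")
        model = MockBackend().invoke(fs, 1, seed=0)[0]
        report = rank_models([model], fs=fs)
        write_report(report, tmp_path)
        html = (tmp_path / "report.html").read_text()
        assert "empty_features" in html
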