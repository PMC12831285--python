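import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from foldguide import fixtures as fx
from foldguide.feature_store import (FeatureSet, MSABlock, QueryFeatures,
                                     TemplateFeature, empty_features)
from foldguide.template_ops import AlignmentMap, structure_to_template


@pytest.fixture
def helix20():
    return fx.make_structure(fx.FixtureSpec(kind="helix", lengths=(20,)))


@pytest.fixture
def two_state_ensemble():
    return fx.make_two_state_ensemble(fx.FixtureSpec(
        kind="two_state_ensemble", hinge_angle=10.0, delta_angle=30.0,
        noise=0.2, n_members=8, seed=1))


def identity_templates(structures):
    """Templates from structures sharing one sequence, identity-mapped."""
    q = QueryFeatures.from_sequence(structures[0].sequence)
    idmap = AlignmentMap(pairs=[(i, i) for i in range(len(structures[0]))])
    return q, [structure_to_template(s, q, mapping=idmap) for s in structures]


def random_feature_set(rng: np.random.Generator) -> FeatureSet:
    """A random but valid FeatureSet (for round-trip property tests)."""
    L = int(rng.integers(5, 30))
    seq = "".join("ARNDCQEGHILKMFPSTWYV"[i]
                  for i in rng.integers(0, 20, size=L))
    fs = empty_features(seq)
    depth = int(rng.integers(1, 8))
    if depth > 1:
        rows = [fs.query.aatype.copy()]
        dels = [np.zeros(L, dtype=np.int64)]
        for _ in range(depth - 1):
            rows.append(rng.integers(0, 22, size=L).astype(np.int64))
            dels.append(rng.integers(0, 4, size=L).astype(np.int64))
        fs.msa = MSABlock(np.stack(rows), np.stack(dels),
                          ["query"] + [f"r{i}" for i in range(depth - 1)])
    for ti in range(int(rng.integers(0, 3))):
        t = TemplateFeature.empty(L, name=f"t{ti}")
        covered = rng.uniform(size=L) < 0.7
        if not covered.any():
            covered[0] = True
        t.labels[covered] = rng.integers(0, 21, size=int(covered.sum()))
        t.atom_mask[covered, 1] = 1.0  # CA
        t.atom_positions[covered, 1, :] = rng.normal(size=(int(covered.sum()), 3))
        t.sum_prob = float(rng.uniform())
        fs.templates.append(t)
    return fs
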