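"""Turning structures into query-aligned templates, and template editing.

A template is a known structure mapped into the query frame.  How strongly it
steers a prediction depends on its residue labels: the query sequence poses a
strong restraint, polyalanine a weak geometric tie.  The operations here build
templates from structures (with automatic or user-supplied alignments),
relabel them (keep / polyalanine / query / custom, with an exception window),
truncate side chains to C-beta, assemble multi-chain templates that encode
interfaces, and cluster template stacks into putative conformational states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .feature_store import (AA_TO_INDEX, GAP_INDEX, QueryFeatures,
                            TemplateFeature, UNKNOWN_INDEX, encode_sequence)
from .msa_ops import RegionSelection
from .structures import BACKBONE_CB_SLOTS, CA, StructureModel

ALA_INDEX = AA_TO_INDEX["A"]
DEFAULT_MIN_IDENTITY = 0.20


@dataclass
class AlignmentMap:
    """Monotone query<->template residue correspondence (0-based indices)."""

    pairs: list[tuple[int, int]]
    identity: float = 1.0

    def __post_init__(self):
        q = [p[0] for p in self.pairs]
        t = [p[1] for p in self.pairs]
        if len(set(q)) != len(q) or len(set(t)) != len(t):
            raise ValueError("duplicated positions in alignment map")
        if any(b <= a for a, b in zip(q, q[1:])) or \
           any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("alignment map not strictly increasing")


class LowIdentityError(ValueError):
    """Automatic alignment fell below the identity floor."""


def align_sequences(query_seq: str, template_seq: str) -> AlignmentMap:
    """Global alignment (BLOSUM62, affine gaps) returning residue pairs."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    q = query_seq.replace("-", "X")
    t = template_seq.replace("-", "X")
    aln = aligner.align(q, t)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for off in range(qe - qs):
            qi, ti = qs + off, ts + off
            pairs.append((qi, ti))
            if q[qi] == t[ti]:
                matches += 1
    if not pairs:
        raise ValueError("no alignable residues between query and template")
    identity = matches / len(pairs)
    return AlignmentMap(pairs=pairs, identity=identity)


def structure_to_template(
    structure: StructureModel,
    query: QueryFeatures,
    mapping: Union[str, AlignmentMap] = "auto",
    placement: Optional[RegionSelection] = None,
    plan=None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    sum_prob: float = 1.0,
) -> TemplateFeature:
    """Copy a structure's 37-slot coordinates into the query frame.

    With ``mapping="auto"`` the template sequence is globally aligned to the
    query and rejected below the identity floor (default 20%) — distant
    templates must be supplied with an explicit :class:`AlignmentMap`, the
    deliberate route for low-homology guidance.  ``placement`` restricts the
    covered region of the query (e.g. one chain of a concatenated target).
    """
    L = len(query)
    if mapping == "auto":
        amap = align_sequences(query.sequence, structure.sequence)
        if amap.identity < min_identity:
            raise LowIdentityError(
                f"automatic alignment identity {amap.identity:.1%} below the "
                f"{min_identity:.0%} floor; supply an explicit AlignmentMap "
                f"to use this template deliberately")
    else:
        amap = mapping
    allowed = None
    if placement is not None:
        allowed = set(int(c) for c in placement.resolve(L, plan))
    t = TemplateFeature.empty(L, name=structure.name)
    t.sum_prob = sum_prob
    n_copied = 0
    for qi, ti in amap.pairs:
        if qi < 0 or qi >= L or ti < 0 or ti >= len(structure):
            raise ValueError(f"mapping pair ({qi}, {ti}) out of range")
        if allowed is not None and qi not in allowed:
            continue
        if structure.atom_mask[ti, CA] == 0:
            continue  # template must have a CA for mapped residues
        t.labels[qi] = structure.aatype[ti]
        t.atom_positions[qi] = structure.atom_positions[ti]
        t.atom_mask[qi] = structure.atom_mask[ti]
        n_copied += 1
    if n_copied == 0:
        raise ValueError("no alignable residues with CA coordinates")
    t.atom_positions[t.atom_mask == 0] = 0.0
    return t


@dataclass
class RelabelMode:
    """Residue-label rewriting policy for a template.

    ``mode`` is one of ``keep``, ``polyalanine``, ``query``, ``custom``.  An
    optional exception window overrides the base mode (e.g. polyalanine
    everywhere except a hinge annotated with the query sequence).
    """

    mode: str = "keep"
    sequence: Optional[str] = None          # for mode="custom", length L
    exception: Optional[RegionSelection] = None
    exception_mode: str = "query"
    exception_sequence: Optional[str] = None

    def __post_init__(self):
        valid = ("keep", "polyalanine", "query", "custom")
        if self.mode not in valid or self.exception_mode not in valid:
            raise ValueError(f"relabel mode must be one of {valid}")


def _labels_for(mode: str, t: TemplateFeature, query: Optional[QueryFeatures],
                sequence: Optional[str]) -> np.ndarray:
    L = len(t.labels)
    if mode == "keep":
        return t.labels.copy()
    if mode == "polyalanine":
        return np.full(L, ALA_INDEX, dtype=np.int64)
    if mode == "query":
        if query is None:
            raise ValueError("relabel mode 'query' requires the query")
        return query.aatype.copy()
    # custom
    if sequence is None:
        raise ValueError("relabel mode 'custom' requires a sequence")
    if len(sequence) != L:
        raise ValueError(
            f"custom sequence length {len(sequence)} != template length {L}")
    return encode_sequence(sequence)


def relabel_template(t: TemplateFeature, mode: Union[str, RelabelMode],
                     query: Optional[QueryFeatures] = None,
                     plan=None) -> TemplateFeature:
    """Rewrite the residue labels of covered positions; coverage is invariant."""
    if isinstance(mode, str):
        mode = RelabelMode(mode=mode)
    out = t.copy()
    covered = t.covered
    base = _labels_for(mode.mode, t, query, mode.sequence)
    out.labels[covered] = base[covered]
    if mode.exception is not None:
        cols = mode.exception.resolve(len(t.labels), plan)
        exc = _labels_for(mode.exception_mode, t, query,
                          mode.exception_sequence)
        sel = np.zeros(len(t.labels), dtype=bool)
        sel[cols] = True
        sel &= covered
        out.labels[sel] = exc[sel]
    return out


def truncate_to_cbeta(t: TemplateFeature) -> TemplateFeature:
    """Drop side-chain atoms beyond C-beta (glycine keeps its 4 atoms)."""
    out = t.copy()
    keep = np.zeros(out.atom_mask.shape[1], dtype=bool)
    keep[list(BACKBONE_CB_SLOTS)] = True
    out.atom_mask[:, ~keep] = 0
    out.atom_positions[out.atom_mask == 0] = 0.0
    return out


def multi_chain_template(
    assignments: Sequence[tuple[StructureModel, Union[str, AlignmentMap],
                                Optional[RegionSelection]]],
    query: QueryFeatures,
    plan=None,
    name: str = "multi_chain",
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> TemplateFeature:
    """Assemble one template from several sources covering disjoint regions.

    Each source contributes its own rigid block in its own frame — no
    re-superposition is applied across sources, so a source that already
    contains an interface carries that inter-region geometry verbatim.
    """
    L = len(query)
    out = TemplateFeature.empty(L, name=name)
    claimed = np.zeros(L, dtype=bool)
    for structure, mapping, region in assignments:
        part = structure_to_template(structure, query, mapping=mapping,
                                     placement=region, plan=plan,
                                     min_identity=min_identity)
        cov = part.covered
        overlap = claimed & cov
        if np.any(overlap):
            pos = int(np.nonzero(overlap)[0][0])
            raise ValueError(
                f"overlapping template assignments at query position {pos}")
        claimed |= cov
        out.labels[cov] = part.labels[cov]
        out.atom_positions[cov] = part.atom_positions[cov]
        out.atom_mask[cov] = part.atom_mask[cov]
    if not claimed.any():
        raise ValueError("no region covered by any assignment")
    return out


@dataclass
class TemplateClustering:
    groups: list[list[TemplateFeature]]
    labels: np.ndarray          # cluster index per template
    member_indices: list[list[int]]
    embedding: object = None    # StateEmbedding from structclust


def cluster_templates(templates: Sequence[TemplateFeature],
                      k: Union[int, str] = "auto",
                      seed: int = 0) -> TemplateClustering:
    """Partition a template stack into structurally consistent groups.

    Templates are compared over their common covered CA positions via the
    pairwise structural correlation matrix and its low-dimensional embedding;
    by default two groups (the two-state hypothesis), or ``k`` groups when the
    user subdivides further, or ``k="auto"`` to let the angular gap decide.
    """
    from . import structclust
    if len(templates) < 2:
        raise ValueError("need at least two templates to cluster")
    common = templates[0].covered & (templates[0].atom_mask[:, CA] > 0)
    for t in templates[1:]:
        common &= t.covered & (t.atom_mask[:, CA] > 0)
    if int(common.sum()) < 20:
        raise ValueError(
            f"insufficient common CA coverage ({int(common.sum())} < 20)")
    idx = np.nonzero(common)[0]
    members = []
    for t in templates:
        members.append(StructureModel(
            chain_ids=np.full(idx.size, "A", dtype="U4"),
            residue_numbers=idx.astype(np.int64) + 1,
            aatype=np.where(t.labels[idx] == GAP_INDEX, UNKNOWN_INDEX,
                            t.labels[idx]),
            atom_positions=t.atom_positions[idx].copy(),
            atom_mask=_ca_only_mask(t.atom_mask[idx]),
            name=t.name,
        ))
    frame = structclust.build_frame(members)
    cc = structclust.cc_matrix(frame)
    kk = None if k == "auto" else int(k)
    emb = structclust.embed(cc, d=2, seed=seed, k=kk)
    labels = emb.cluster_labels
    n_groups = int(labels.max()) + 1
    member_indices = [[i for i in range(len(templates)) if labels[i] == g]
                      for g in range(n_groups)]
    groups = [[templates[i] for i in grp] for grp in member_indices]
    return TemplateClustering(groups=groups, labels=labels,
                              member_indices=member_indices, embedding=emb)


def _ca_only_mask(mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    out[:, CA] = mask[:, CA]
    return out
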