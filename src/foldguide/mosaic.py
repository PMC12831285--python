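"""Mosaic mode: split a large target into overlapping sub-predictions and
merge the per-segment models back into one structure.

Targets too large for the predictor are decomposed preferentially at chain
boundaries (a complex split into sub-complexes sharing whole chains) and
otherwise into overlapping intra-chain windows.  Each segment is predicted
independently; at merge time the first segment fixes the frame and every
subsequent segment is rigid-body superposed (Kabsch on shared-anchor CAs)
onto the growing assembly.  Overlap residues are taken from the segment with
higher mean confidence; a merge whose anchor superposition RMSD exceeds the
acceptance threshold is refused with a diagnostic rather than silently glued.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .assembly import AssemblyPlan
from .geometry import apply_rigid, kabsch
from .structures import CA, StructureModel

MIN_OVERLAP = 30
DEFAULT_ANCHOR_RMSD = 5.0


@dataclass
class MosaicSegment:
    start: int                  # concatenated frame, 0-based inclusive
    stop: int                   # exclusive
    recipe: dict = field(default_factory=dict)  # e.g. {"templates": [...]}

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass
class MosaicPlan:
    segments: list[MosaicSegment]
    shared_anchors: list[tuple[int, int, int, int]]  # (seg_i, seg_j, start, stop)
    seed_policy: str = "independent"  # independent | best_of_previous

    def __post_init__(self):
        if self.seed_policy not in ("independent", "best_of_previous"):
            raise ValueError(f"unknown seed_policy {self.seed_policy!r}")


class MergeRefusedError(RuntimeError):
    """Anchor superposition disagreed beyond the acceptance threshold."""


def split(target: AssemblyPlan, max_len: int, overlap: int = MIN_OVERLAP
          ) -> MosaicPlan:
    """Greedy left-to-right segmentation of the target.

    Chains are packed whole into segments of at most ``max_len`` residues;
    consecutive segments share the last chain of the previous segment as a
    whole-chain anchor.  A single chain longer than ``max_len`` falls back to
    overlapping windows within the chain.
    """
    if not (max_len > overlap >= MIN_OVERLAP):
        raise ValueError(
            f"need max_len > overlap >= {MIN_OVERLAP}, got "
            f"max_len={max_len}, overlap={overlap}")
    chain_segs = target.chain_segments()
    intervals: list[tuple[int, int]] = []  # whole-chain intervals
    for seg in chain_segs:
        if seg.length > max_len:
            if overlap >= seg.length:
                raise ValueError(
                    f"chain {seg.chain_id} (length {seg.length}) cannot be "
                    f"windowed with overlap {overlap}")
            step = max_len - overlap
            pos = seg.start
            while True:
                stop = min(pos + max_len, seg.stop)
                intervals.append((pos, stop))
                if stop >= seg.stop:
                    break
                pos = stop - overlap
        else:
            intervals.append((seg.start, seg.stop))

    segments: list[MosaicSegment] = []
    current: list[tuple[int, int]] = []

    def seg_len(iv: list[tuple[int, int]]) -> int:
        return sum(b - a for a, b in iv)

    for iv in intervals:
        if current and seg_len(current) + (iv[1] - iv[0]) > max_len:
            segments.append(MosaicSegment(current[0][0], current[-1][1]))
            # next segment starts from the previous segment's last interval
            # (the shared whole-chain / window anchor)
            current = [current[-1]]
            if seg_len(current) + (iv[1] - iv[0]) > max_len:
                current = []  # anchor itself too large; rely on window overlap
        current.append(iv)
    if current:
        segments.append(MosaicSegment(current[0][0], current[-1][1]))
    if len(segments) == 1:
        return MosaicPlan(segments=segments, shared_anchors=[])

    anchors = []
    for i in range(len(segments) - 1):
        a, b = segments[i], segments[i + 1]
        lo, hi = max(a.start, b.start), min(a.stop, b.stop)
        if hi - lo < 1:
            raise ValueError(
                f"segments {i} and {i + 1} share no anchor region")
        anchors.append((i, i + 1, lo, hi))
    plan = MosaicPlan(segments=segments, shared_anchors=anchors)
    for i, j, lo, hi in anchors:
        if hi - lo < MIN_OVERLAP:
            raise ValueError(
                f"anchor between segments {i} and {j} is {hi - lo} residues "
                f"(< {MIN_OVERLAP})")
    return plan


@dataclass
class MergeReport:
    anchor_rmsds: list[float]
    source_segment: np.ndarray  # which segment supplied each residue


def merge(models: list[StructureModel], plan: MosaicPlan,
          anchor_rmsd_threshold: float = DEFAULT_ANCHOR_RMSD
          ) -> tuple[StructureModel, MergeReport]:
    """Assemble per-segment models into one structure in the first segment's
    frame.  Models are given in segment order and must each cover their
    segment's length.
    """
    if len(models) != len(plan.segments):
        raise ValueError("one model per segment required")
    for m, seg in zip(models, plan.segments):
        if len(m) != seg.length:
            raise ValueError(
                f"model {m.name!r} length {len(m)} != segment length "
                f"{seg.length}")
    total = max(s.stop for s in plan.segments)
    first = plan.segments[0]

    filled = np.zeros(total, dtype=bool)
    positions = np.zeros((total, 37, 3))
    mask = np.zeros((total, 37))
    aatype = np.zeros(total, dtype=np.int64)
    conf = np.full(total, np.nan)
    source = np.full(total, -1, dtype=np.int64)

    def model_conf(m: StructureModel) -> np.ndarray:
        return (m.confidence if m.confidence is not None
                else np.full(len(m), 100.0))

    # overlap conflict: mean pLDDT over the overlap decides as a block, with
    # the earlier segment as the deterministic tie-break
    def paste_block(seg_idx: int, m: StructureModel, seg: MosaicSegment
                    ) -> None:
        c = model_conf(m)
        overlap = np.array([filled[seg.start + j] for j in range(seg.length)])
        if overlap.any():
            new_mean = float(np.mean(c[overlap]))
            old_mean = float(np.mean(conf[seg.start:seg.stop][overlap]))
            replace_overlap = new_mean > old_mean
        else:
            replace_overlap = False
        for j in range(seg.length):
            g = seg.start + j
            if not filled[g] or replace_overlap:
                positions[g] = m.atom_positions[j]
                mask[g] = m.atom_mask[j]
                aatype[g] = m.aatype[j]
                conf[g] = c[j]
                source[g] = seg_idx
                filled[g] = True

    paste_block(0, models[0], first)
    anchor_rmsds: list[float] = []
    for idx in range(1, len(plan.segments)):
        seg = plan.segments[idx]
        m = models[idx]
        anchor_global = [
            (lo, hi) for (i, j, lo, hi) in plan.shared_anchors
            if j == idx and i < idx
        ]
        pairs_target, pairs_mobile = [], []
        for lo, hi in anchor_global:
            for g in range(lo, hi):
                j = g - seg.start
                if filled[g] and mask[g, CA] > 0 and m.atom_mask[j, CA] > 0:
                    pairs_target.append(positions[g, CA])
                    pairs_mobile.append(m.atom_positions[j, CA])
        if len(pairs_mobile) < 3:
            raise MergeRefusedError(
                f"segment {idx}: anchor has no CA coverage")
        R, t, rmsd = kabsch(np.array(pairs_mobile), np.array(pairs_target))
        anchor_rmsds.append(rmsd)
        if rmsd > anchor_rmsd_threshold:
            raise MergeRefusedError(
                f"segment {idx}: anchor superposition RMSD {rmsd:.2f} A "
                f"exceeds the {anchor_rmsd_threshold:.1f} A acceptance "
                f"threshold; the segment models disagree on the shared region")
        moved = m.copy()
        moved.atom_positions = apply_rigid(
            m.atom_positions.reshape(-1, 3), R, t).reshape(m.atom_positions.shape)
        moved.atom_positions[moved.atom_mask == 0] = 0.0
        paste_block(idx, moved, seg)

    if not filled.all():
        raise ValueError("segments do not cover the target")
    merged = StructureModel(
        chain_ids=np.full(total, "A", dtype="U4"),
        residue_numbers=np.arange(1, total + 1, dtype=np.int64),
        aatype=aatype,
        atom_positions=positions,
        atom_mask=mask,
        confidence=conf,
        name="mosaic_merged",
    )
    return merged, MergeReport(anchor_rmsds=anchor_rmsds,
                               source_segment=source)


def seed_next(plan: MosaicPlan, best_model: StructureModel,
              best_segment: int = 0) -> MosaicPlan:
    """Template later segments with the anchor region of the best model.

    Under ``seed_policy="best_of_previous"`` the shared-anchor region of the
    best-scored earlier prediction is converted to a query-labeled template
    and added to every later segment's recipe; ``independent`` is identity.
    """
    if plan.seed_policy == "independent":
        return plan
    from .feature_store import QueryFeatures
    from .template_ops import AlignmentMap, structure_to_template
    best_seg = plan.segments[best_segment]
    if len(best_model) != best_seg.length:
        raise ValueError("best model does not cover its segment")
    new_segments = [MosaicSegment(s.start, s.stop, dict(s.recipe))
                    for s in plan.segments]
    for (i, j, lo, hi) in plan.shared_anchors:
        if i != best_segment:
            continue
        target = new_segments[j]
        # anchor in the coordinates of each segment
        b_idx = np.arange(lo - best_seg.start, hi - best_seg.start)
        anchor = best_model.select(b_idx)
        if not anchor.ca_mask.any():
            raise ValueError("anchor region missing from best model")
        t_query = QueryFeatures.from_sequence(
            _segment_sequence(best_model, plan, target))
        offset = lo - target.start
        mapping = AlignmentMap(
            pairs=[(offset + k, k) for k in range(len(anchor))])
        tmpl = structure_to_template(anchor, t_query, mapping=mapping)
        tmpl.name = f"seed_from_segment_{best_segment}"
        target.recipe.setdefault("templates", []).append(tmpl)
    return MosaicPlan(segments=new_segments,
                      shared_anchors=list(plan.shared_anchors),
                      seed_policy=plan.seed_policy)


def _segment_sequence(best_model: StructureModel, plan: MosaicPlan,
                      seg: MosaicSegment) -> str:
    # The template only needs a query frame of the right length; residues
    # outside the anchor are placeholders (never covered by the template).
    return "A" * seg.length
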