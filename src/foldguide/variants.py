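"""Point variants on the query sequence and the two-step revert cycle.

Mutating the query changes local residue propensities (e.g. prolines break
helices) without touching templates or the non-query alignment rows.  Because
the final model must carry the original sequence, a mutation is temporary:
the mutant prediction is fed back as a template for a second prediction whose
query is reverted to the original sequence (``revert_cycle``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from .feature_store import (AA_TO_INDEX, FeatureSet, QueryFeatures,
                            encode_sequence)
from .structures import StructureModel


@dataclass
class VariantSpec:
    """Point substitutions: (chain_id, position 1-based, original, replacement).

    The stated original residue is checked against the sequence, guarding
    against numbering drift.  Entries parse from the config form ``"A:I31P"``.
    """

    variants: list[tuple[str, int, str, str]] = field(default_factory=list)

    @classmethod
    def parse(cls, items) -> "VariantSpec":
        out = []
        for it in items:
            if isinstance(it, str):
                chain, rest = it.split(":")
                orig, repl = rest[0].upper(), rest[-1].upper()
                pos = int(rest[1:-1])
                out.append((chain, pos, orig, repl))
            else:
                chain, pos, orig, repl = it
                out.append((str(chain), int(pos), str(orig).upper(),
                            str(repl).upper()))
        return cls(out)

    def __len__(self) -> int:
        return len(self.variants)


def _concat_position(fs: FeatureSet, chain_id: str, pos: int) -> list[int]:
    """Concatenated 0-based columns for a chain-coordinate position.

    With multiple copies of the chain, the variant applies to every copy.
    """
    if fs.assembly is None:
        if pos < 1 or pos > len(fs):
            raise ValueError(f"position {pos} outside [1, {len(fs)}]")
        return [pos - 1]
    cols = []
    for seg in fs.assembly.chain_segments():
        if seg.chain_id != chain_id:
            continue
        offset = fs.assembly.spec_for(seg.chain_id).start_offset
        j = pos - offset
        if j < 0 or j >= seg.length:
            raise ValueError(
                f"position {chain_id}:{pos} outside the chain")
        cols.append(seg.start + j)
    if not cols:
        raise ValueError(f"no chain {chain_id!r} in the assembly plan")
    return cols


def apply_variants(fs: FeatureSet, spec: VariantSpec) -> FeatureSet:
    """Substitute residues in the query channel (sequence + MSA row 0).

    Non-query MSA rows and templates are untouched; the originals must match
    the current sequence or the edit is refused.
    """
    out = fs.copy()
    seq = list(out.query.sequence)
    for chain, pos, orig, repl in spec.variants:
        if repl not in AA_TO_INDEX:
            raise ValueError(f"unknown replacement residue {repl!r}")
        for col in _concat_position(fs, chain, pos):
            if seq[col] != orig:
                raise ValueError(
                    f"variant {chain}:{orig}{pos}{repl}: sequence has "
                    f"{seq[col]!r} at that position, not {orig!r}")
            seq[col] = repl
            out.query.aatype[col] = AA_TO_INDEX[repl]
            out.msa.rows[0, col] = AA_TO_INDEX[repl]
    out.query.sequence = "".join(seq)
    out.record("apply_variants",
               variants=[f"{c}:{o}{p}{r}" for c, p, o, r in spec.variants])
    return out


def invert(spec: VariantSpec) -> VariantSpec:
    """The spec that undoes this one (original and replacement swapped)."""
    return VariantSpec([(c, p, r, o) for c, p, o, r in spec.variants])


def revert_cycle(fs_mutant: FeatureSet, predicted: StructureModel,
                 original_sequence: str) -> FeatureSet:
    """Second step of the mutation mode: revert the query, template the result.

    Returns a new FeatureSet whose query is the original sequence and whose
    template stack contains the mutant-derived prediction relabeled with the
    (reverted) query sequence, so the original residues annotate the mutant
    geometry.  The MSA is carried over with its query row reverted.  The
    unrelaxed prediction is used verbatim.
    """
    from .template_ops import AlignmentMap, relabel_template, \
        structure_to_template
    if len(predicted) != len(fs_mutant):
        raise ValueError(
            f"prediction length {len(predicted)} != query length "
            f"{len(fs_mutant)}")
    if len(original_sequence) != len(fs_mutant):
        raise ValueError("original sequence length mismatch")
    query = QueryFeatures(
        sequence=original_sequence.upper(),
        aatype=encode_sequence(original_sequence),
        residue_index=fs_mutant.query.residue_index.copy(),
        between_segment_flags=fs_mutant.query.between_segment_flags.copy(),
    )
    msa = fs_mutant.msa.copy()
    msa.rows[0] = query.aatype
    msa.deletion_counts[0] = 0
    identity = AlignmentMap(pairs=[(i, i) for i in range(len(predicted))])
    template = structure_to_template(predicted, query, mapping=identity)
    template = relabel_template(template, "query", query)
    template.name = f"{predicted.name}_reverted"
    out = FeatureSet(query=query, msa=msa,
                     templates=fs_mutant.templates + [template],
                     assembly=fs_mutant.assembly,
                     provenance=list(fs_mutant.provenance))
    out.record("revert_cycle", template=template.name)
    return out
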