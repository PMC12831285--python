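"""Alignment parsing and the MSA manipulations used to steer predictions.

The operations here adjust the co-evolutionary signal the predictor sees:
depth reduction (keeping the top-ranked or a maximally diverse subset),
region masking (emphasising a template by silencing the alignment under it),
merging of harvested alignment blocks onto a concatenated target, and
injection of fragment libraries carrying specific local interactions.

All operations preserve the alignment width and the query row exactly, and
masking is substitution with the gap index (21) in non-query rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .feature_store import (FeatureSet, GAP_INDEX, MSABlock, QueryFeatures,
                            AA_TO_INDEX, encode_sequence)


@dataclass
class RegionSelection:
    """Chain-coordinate intervals resolving to concatenated 0-based columns.

    Each interval is ``(chain_id_or_star, start, end)``, 1-based inclusive in
    the chain's own author numbering (respecting ``ChainSpec.start_offset``).
    Without an assembly plan the target is treated as one chain numbered from
    1.  ``"*"`` selects the interval on every chain copy.
    """

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        for cid, start, end in self.intervals:
            if start > end:
                raise ValueError(f"region {cid}:{start}-{end}: start > end")

    def resolve(self, L: int, plan=None) -> np.ndarray:
        """Return the sorted unique 0-based concatenated columns selected."""
        cols: set[int] = set()
        for cid, start, end in self.intervals:
            if plan is None:
                if start < 1 or end > L:
                    raise ValueError(
                        f"region {start}-{end} outside [1, {L}]")
                cols.update(range(start - 1, end))
                continue
            segs = [s for s in plan.chain_segments()
                    if cid == "*" or s.chain_id == cid]
            if not segs:
                raise ValueError(f"region references unknown chain {cid!r}")
            for seg in segs:
                offset = plan.spec_for(seg.chain_id).start_offset
                lo, hi = start - offset, end - offset
                if lo < 0 or hi >= seg.length:
                    raise ValueError(
                        f"region {cid}:{start}-{end} outside chain "
                        f"[{offset}, {offset + seg.length - 1}]")
                cols.update(range(seg.start + lo, seg.start + hi + 1))
        out = np.array(sorted(cols), dtype=np.int64)
        if out.size and (out[0] < 0 or out[-1] >= L):
            raise ValueError("resolved region outside [0, L)")
        return out

    @classmethod
    def parse(cls, items: Sequence) -> "RegionSelection":
        """Accept ``[["A", 10, 28], ...]`` or ``["A:10-28", ...]`` forms."""
        intervals = []
        for it in items:
            if isinstance(it, str):
                cid, rng = it.split(":")
                s, e = rng.split("-")
                intervals.append((cid, int(s), int(e)))
            else:
                cid, s, e = it
                intervals.append((str(cid), int(s), int(e)))
        return cls(intervals)


# --- Parsing ----------------------------------------------------------------

def _rows_from_a3m(records: list[tuple[str, str]], query: str):
    """Convert A3M-semantics records to integer rows + deletion counts.

    Uppercase letters and '-' are match columns; lowercase letters are
    insertions counted into ``deletion_counts`` at the next match column.
    """
    L = len(query)
    rows, dels, labels = [], [], []
    for label, aligned in records:
        row = np.full(L, GAP_INDEX, dtype=np.int64)
        dele = np.zeros(L, dtype=np.int64)
        col = 0
        pending = 0
        for ch in aligned:
            if ch.islower():
                pending += 1
                continue
            if ch in (".",):
                continue  # alignment padding, not a match column
            if col >= L:
                raise ValueError(
                    f"row {label!r}: more match columns than query length {L}")
            if ch == "-":
                row[col] = GAP_INDEX
            else:
                idx = AA_TO_INDEX.get(ch.upper())
                if idx is None:
                    raise ValueError(
                        f"row {label!r}: illegal character {ch!r}")
                row[col] = idx
            dele[col] = pending
            pending = 0
            col += 1
        if col != L:
            raise ValueError(
                f"row {label!r}: {col} match columns, query has {L}")
        rows.append(row)
        dels.append(dele)
        labels.append(label)
    return rows, dels, labels


def _read_fasta_like(path) -> list[tuple[str, str]]:
    records = []
    label, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#") or not line.strip():
                continue
            if line.startswith(">"):
                if label is not None:
                    records.append((label, "".join(chunks)))
                label = line[1:].split()[0] or f"seq_{len(records)}"
                chunks = []
            else:
                chunks.append(line.strip())
    if label is not None:
        records.append((label, "".join(chunks)))
    return records


def parse_alignment(path, format: str, query) -> MSABlock:
    """Parse an alignment file into an :class:`MSABlock` with A3M semantics.

    ``format`` is one of ``a3m``, ``stockholm``, ``fasta`` (aligned FASTA).
    ``query`` is the query residue string (or :class:`QueryFeatures`); the
    file's reference sequence must match it after removing gaps/insertions.
    """
    if isinstance(query, QueryFeatures):
        query_seq = query.sequence
    else:
        query_seq = str(query).upper()
    fmt = format.lower().replace("aligned-", "")
    if fmt == "a3m":
        records = _read_fasta_like(path)
    elif fmt in ("stockholm", "sto"):
        from Bio import AlignIO
        aln = AlignIO.read(str(path), "stockholm")
        records = [(rec.id, str(rec.seq)) for rec in aln]
        records = _columns_to_a3m(records)
    elif fmt in ("fasta", "afa"):
        records = _read_fasta_like(path)
        records = _columns_to_a3m(records)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if not records:
        raise ValueError(f"no sequences in {path}")
    ref = "".join(ch for ch in records[0][1]
                  if ch.isupper() or ch.islower()).upper()
    if ref != query_seq:
        raise ValueError(
            "first alignment sequence does not match the query after "
            "removing gaps")
    rows, dels, labels = _rows_from_a3m(records, query_seq)
    labels[0] = "query"
    block = MSABlock(np.stack(rows), np.stack(dels), labels)
    # row 0 must be the gapless query
    block.rows[0] = encode_sequence(query_seq)
    block.deletion_counts[0] = 0
    return block


def _columns_to_a3m(records: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Rewrite a column-aligned (FASTA/Stockholm) block in A3M convention.

    Columns where the reference has a gap become insertions (lowercase) in
    the other rows.
    """
    ref = records[0][1]
    out = []
    for label, seq in records:
        if len(seq) != len(ref):
            raise ValueError(f"row {label!r}: width differs from reference")
        chars = []
        for rch, ch in zip(ref, seq):
            gap = ch in "-."
            if rch in "-.":
                if not gap:
                    chars.append(ch.lower())
            else:
                chars.append("-" if gap else ch.upper())
        out.append((label, "".join(chars)))
    return out


def write_a3m(msa: MSABlock, path) -> None:
    from .feature_store import INDEX_TO_AA
    with open(path, "w") as fh:
        for label, row in zip(msa.row_labels, msa.rows):
            fh.write(f">{label}\n")
            fh.write("".join(INDEX_TO_AA[int(a)] for a in row) + "\n")


# --- Manipulations ----------------------------------------------------------

def reduce_depth(msa: MSABlock, n: int, strategy: str = "top",
                 seed: int = 0) -> MSABlock:
    """Keep the query plus ``n - 1`` rows.

    ``top`` keeps the first rows in stored order (assumed search ranking);
    ``diverse`` greedily selects rows maximising the minimum Hamming distance
    (over match columns) to those already kept, seeded for reproducible
    tie-breaks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= msa.depth:
        return msa.copy()
    if strategy == "top":
        keep = np.arange(n)
    elif strategy == "diverse":
        rng = np.random.default_rng(seed)
        keep_list = [0]
        candidates = list(range(1, msa.depth))
        rows = msa.rows
        dist = np.full(msa.depth, np.inf)
        while len(keep_list) < n and candidates:
            last = keep_list[-1]
            for c in candidates:
                d = np.count_nonzero(rows[c] != rows[last])
                if d < dist[c]:
                    dist[c] = d
            best = np.max(dist[candidates])
            ties = [c for c in candidates if dist[c] == best]
            pick = ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
            keep_list.append(pick)
            candidates.remove(pick)
        keep = np.array(keep_list)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return MSABlock(msa.rows[keep].copy(), msa.deletion_counts[keep].copy(),
                    [msa.row_labels[i] for i in keep])


def mask_region(msa: MSABlock, region: RegionSelection,
                plan=None) -> MSABlock:
    """Set the selected columns to gap in every non-query row.

    Deletion counts are zeroed in the masked window (a gap cannot carry
    insertions); the query row and the column count are untouched.
    """
    cols = region.resolve(msa.width, plan)
    out = msa.copy()
    if cols.size and out.depth > 1:
        out.rows[1:, cols] = GAP_INDEX
        out.deletion_counts[1:, cols] = 0
    return out


def merge(blocks: list[tuple[MSABlock, Optional[RegionSelection]]],
          query: QueryFeatures, plan=None) -> MSABlock:
    """Stack rows from several blocks under one query row.

    A block paired with a region is placed at (or restricted to) that region:
    a block as wide as the target is restricted (cells outside the region
    become gaps); a block as wide as the region is placed into it.  Duplicate
    integer rows are dropped, keeping the first occurrence.
    """
    L = len(query)
    rows = [query.aatype.copy()]
    dels = [np.zeros(L, dtype=np.int64)]
    labels = ["query"]
    seen = {rows[0].tobytes()}
    for block, region in blocks:
        if region is None:
            if block.width != L:
                raise ValueError(
                    f"block width {block.width} != target width {L}")
            cols = np.arange(L)
            placed_width = L
        else:
            cols = region.resolve(L, plan)
            if block.width == L:
                placed_width = L
            elif block.width == cols.size:
                placed_width = cols.size
            else:
                raise ValueError(
                    f"block width {block.width} matches neither target ({L}) "
                    f"nor region ({cols.size})")
        for r in range(1, block.depth):
            row = np.full(L, GAP_INDEX, dtype=np.int64)
            dele = np.zeros(L, dtype=np.int64)
            if placed_width == L:
                row[cols] = block.rows[r, cols]
                dele[cols] = block.deletion_counts[r, cols]
            else:
                row[cols] = block.rows[r]
                dele[cols] = block.deletion_counts[r]
            key = row.tobytes()
            if key in seen:
                continue
            seen.add(key)
            rows.append(row)
            dels.append(dele)
            labels.append(block.row_labels[r])
    return MSABlock(np.stack(rows), np.stack(dels), labels)


def add_fragment_library(msa: MSABlock,
                         fragments: list[tuple[str, RegionSelection]],
                         plan=None) -> MSABlock:
    """Append one row per fragment, placed at its target region.

    Fragment sequences carry specific local interactions (e.g. strand pairs
    bridged by a disulfide); each must exactly span its target region.
    """
    out = msa.copy()
    new_rows, new_dels, new_labels = [], [], []
    for i, (seq, region) in enumerate(fragments):
        cols = region.resolve(msa.width, plan)
        if len(seq) != cols.size:
            raise ValueError(
                f"fragment {i}: length {len(seq)} != region length {cols.size}")
        frag = encode_sequence(seq)
        row = np.full(msa.width, GAP_INDEX, dtype=np.int64)
        row[cols] = frag
        new_rows.append(row)
        new_dels.append(np.zeros(msa.width, dtype=np.int64))
        new_labels.append(f"fragment_{i}")
    if not new_rows:
        return out
    return MSABlock(np.concatenate([out.rows, np.stack(new_rows)]),
                    np.concatenate([out.deletion_counts, np.stack(new_dels)]),
                    out.row_labels + new_labels)


# --- FeatureSet-level wrappers (record provenance) --------------------------

def set_msa(fs: FeatureSet, msa: MSABlock, source: str = "msa") -> FeatureSet:
    if msa.width != len(fs):
        raise ValueError("MSA width does not match FeatureSet length")
    out = fs.copy()
    out.msa = msa.copy()
    out.msa.rows[0] = out.query.aatype
    out.msa.deletion_counts[0] = 0
    out.record("set_msa", source=source, depth=msa.depth)
    return out
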