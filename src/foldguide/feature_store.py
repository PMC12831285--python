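"""Predictor-input container: query features, MSA block and template stack.

This module defines the in-memory analog of the serialized feature container
an AlphaFold2-style predictor consumes (the ``features.pkl`` dialect), the
residue alphabet shared by every other module, structural validation, and
round-trip persistence.  The native on-disk format is a NumPy ``.npz`` archive
of named arrays plus a JSON sidecar carrying strings, labels and the
append-only provenance log, so integer arrays round-trip bit-exactly and reals
exactly.  Containers written by a stock AlphaFold2 v2.2 run (pickled dict with
one-hot encodings) are accepted as an import/export dialect.
"""

from __future__ import annotations

import copy
import json
import pickle
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

# --- Residue alphabet -------------------------------------------------------
# Canonical 20 amino acids in the fixed feature order; X (unknown) = 20;
# gap/mask shares index 21 with the MSA gap (masking is substitution).
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
UNKNOWN_INDEX = 20
GAP_INDEX = 21
N_RESIDUE_CLASSES = 22

AA_TO_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
AA_TO_INDEX["X"] = UNKNOWN_INDEX
INDEX_TO_AA = {i: aa for aa, i in AA_TO_INDEX.items() if aa != "X"}
INDEX_TO_AA[UNKNOWN_INDEX] = "X"
INDEX_TO_AA[GAP_INDEX] = "-"

# HHblits-style residue numbering (alphabetical over the 20 one-letter codes),
# used by the msa/template arrays of stock AF2 containers.
_HHBLITS_ORDER = "".join(sorted(AA_ORDER))  # ACDEFGHIKLMNPQRSTVWY
HHBLITS_TO_INTERNAL = np.array(
    [AA_TO_INDEX[c] for c in _HHBLITS_ORDER] + [UNKNOWN_INDEX, GAP_INDEX],
    dtype=np.int64,
)
INTERNAL_TO_HHBLITS = np.zeros(N_RESIDUE_CLASSES, dtype=np.int64)
for _hh, _internal in enumerate(HHBLITS_TO_INTERNAL):
    INTERNAL_TO_HHBLITS[_internal] = _hh

N_ATOM_SLOTS = 37


class SequenceError(ValueError):
    """Raised for sequences containing characters outside the alphabet."""


class DialectError(ValueError):
    """Raised when a container file does not match any accepted layout."""


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a one-letter residue string into internal integer indices.

    Unknown residues must be given as ``X``; any other character is rejected
    with a message naming the offending (1-based) position.
    """
    if not sequence:
        raise SequenceError("empty sequence")
    out = np.empty(len(sequence), dtype=np.int64)
    for i, ch in enumerate(sequence):
        idx = AA_TO_INDEX.get(ch.upper())
        if idx is None:
            raise SequenceError(
                f"illegal residue character {ch!r} at position {i + 1}"
            )
        out[i] = idx
    return out


def decode_sequence(aatype: np.ndarray) -> str:
    return "".join(INDEX_TO_AA[int(a)] for a in aatype)


# --- Container types --------------------------------------------------------

@dataclass
class QueryFeatures:
    """The query channel: sequence, integer encoding and residue numbering.

    ``residue_index`` is 0-based and strictly increasing; it may jump at chain
    breaks (the index-gap device for multimer-as-monomer prediction).
    ``between_segment_flags`` marks inserted physical-linker residues.
    """

    sequence: str
    aatype: np.ndarray
    residue_index: np.ndarray
    between_segment_flags: np.ndarray

    @classmethod
    def from_sequence(cls, sequence: str) -> "QueryFeatures":
        aatype = encode_sequence(sequence)
        L = len(sequence)
        return cls(
            sequence=sequence.upper(),
            aatype=aatype,
            residue_index=np.arange(L, dtype=np.int64),
            between_segment_flags=np.zeros(L, dtype=np.int64),
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MSABlock:
    """An integer-encoded alignment block (row 0 is always the query)."""

    rows: np.ndarray            # (N_seq, L) values in [0, 21]
    deletion_counts: np.ndarray  # (N_seq, L) non-negative ints
    row_labels: list[str]

    @property
    def depth(self) -> int:
        return self.rows.shape[0]

    @property
    def width(self) -> int:
        return self.rows.shape[1]

    def copy(self) -> "MSABlock":
        return MSABlock(self.rows.copy(), self.deletion_counts.copy(),
                        list(self.row_labels))

    @classmethod
    def from_query(cls, query: QueryFeatures) -> "MSABlock":
        return cls(
            rows=query.aatype[None, :].copy(),
            deletion_counts=np.zeros((1, len(query)), dtype=np.int64),
            row_labels=["query"],
        )


@dataclass
class TemplateFeature:
    """One template aligned into the query frame.

    ``labels[i] == 21`` means the template does not cover query position i;
    the atom mask must be all-zero there.  Coordinates use the fixed 37-slot
    heavy-atom convention (see :mod:`foldguide.structures`).
    """

    labels: np.ndarray            # (L,) ints in [0, 21]
    atom_positions: np.ndarray    # (L, 37, 3) float, Angstrom
    atom_mask: np.ndarray         # (L, 37) 0/1
    name: str = "template"
    sum_prob: float = 1.0

    @property
    def covered(self) -> np.ndarray:
        """Boolean mask of query positions covered by this template."""
        return self.labels != GAP_INDEX

    def copy(self) -> "TemplateFeature":
        return TemplateFeature(self.labels.copy(), self.atom_positions.copy(),
                               self.atom_mask.copy(), self.name, self.sum_prob)

    @classmethod
    def empty(cls, L: int, name: str = "template") -> "TemplateFeature":
        return cls(
            labels=np.full(L, GAP_INDEX, dtype=np.int64),
            atom_positions=np.zeros((L, N_ATOM_SLOTS, 3), dtype=np.float64),
            atom_mask=np.zeros((L, N_ATOM_SLOTS), dtype=np.float64),
            name=name,
        )


@dataclass
class FeatureSet:
    """The complete predictor input (query + MSA + templates + provenance)."""

    query: QueryFeatures
    msa: MSABlock
    templates: list[TemplateFeature] = field(default_factory=list)
    assembly: Optional[object] = None  # AssemblyPlan, stored by reference
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.query)

    def record(self, op: str, **params) -> None:
        """Append a provenance entry for a mutating operation."""
        self.provenance.append({"op": op, "params": _jsonable(params)})

    def copy(self) -> "FeatureSet":
        return FeatureSet(
            query=QueryFeatures(
                self.query.sequence,
                self.query.aatype.copy(),
                self.query.residue_index.copy(),
                self.query.between_segment_flags.copy(),
            ),
            msa=self.msa.copy(),
            templates=[t.copy() for t in self.templates],
            assembly=self.assembly,
            provenance=copy.deepcopy(self.provenance),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# --- Operations -------------------------------------------------------------

def empty_features(sequence: str) -> FeatureSet:
    """Build a minimal-information input: query row only, zero templates.

    This is the uninformed baseline — the predictor sees nothing beyond the
    query sequence and its learned parameters.
    """
    query = QueryFeatures.from_sequence(sequence)
    fs = FeatureSet(query=query, msa=MSABlock.from_query(query))
    fs.record("empty_features", length=len(query))
    return fs


def validate(fs: FeatureSet) -> list[str]:
    """Check every container invariant; return violations as strings.

    Violations are data, not exceptions: each names the array, index and rule
    broken.  An empty list means the set is well-formed.
    """
    v: list[str] = []
    q = fs.query
    L = len(q.sequence)
    if len(q.aatype) != L:
        v.append(f"query.aatype: length {len(q.aatype)} != sequence length {L}")
    else:
        for i, ch in enumerate(q.sequence):
            expect = AA_TO_INDEX.get(ch)
            if expect is None or q.aatype[i] != expect:
                v.append(f"query.aatype[{i}]: does not encode sequence[{i}]={ch!r}")
                break
    if len(q.residue_index) != L:
        v.append("query.residue_index: wrong length")
    elif L > 1 and not np.all(np.diff(q.residue_index) > 0):
        v.append("query.residue_index: not strictly increasing")
    if len(q.between_segment_flags) != L:
        v.append("query.between_segment_flags: wrong length")
    elif not np.all(np.isin(q.between_segment_flags, (0, 1))):
        v.append("query.between_segment_flags: values outside {0,1}")

    m = fs.msa
    if m.rows.ndim != 2 or m.rows.shape[1] != L:
        v.append(f"msa.rows: width {m.rows.shape} != query length {L}")
    else:
        if m.deletion_counts.shape != m.rows.shape:
            v.append("msa.deletion_counts: shape mismatch with rows")
        if len(m.row_labels) != m.depth:
            v.append("msa.row_labels: count mismatch with rows")
        if not np.all((m.rows >= 0) & (m.rows <= GAP_INDEX)):
            v.append("msa.rows: values outside [0, 21]")
        if np.any(m.deletion_counts < 0):
            v.append("msa.deletion_counts: negative entries")
        if not np.array_equal(m.rows[0], q.aatype):
            v.append("msa.rows[0]: query row differs from query.aatype")
        if np.any(m.deletion_counts[0] != 0):
            v.append("msa.deletion_counts[0]: nonzero in query row")

    from .structures import ATOM37_INDEX  # local import avoids cycle
    ca = ATOM37_INDEX["CA"]
    for ti, t in enumerate(fs.templates):
        if t.labels.shape != (L,):
            v.append(f"templates[{ti}].labels: shape {t.labels.shape} != ({L},)")
            continue
        if t.atom_positions.shape != (L, N_ATOM_SLOTS, 3):
            v.append(f"templates[{ti}].atom_positions: bad shape")
            continue
        if t.atom_mask.shape != (L, N_ATOM_SLOTS):
            v.append(f"templates[{ti}].atom_mask: bad shape")
            continue
        if not np.all((t.labels >= 0) & (t.labels <= GAP_INDEX)):
            v.append(f"templates[{ti}].labels: values outside [0, 21]")
        uncovered = t.labels == GAP_INDEX
        if np.any(t.atom_mask[uncovered] != 0):
            idx = int(np.nonzero(np.any(t.atom_mask[uncovered] != 0, axis=1))[0][0])
            pos = int(np.nonzero(uncovered)[0][idx])
            v.append(
                f"templates[{ti}].atom_mask[{pos}]: nonzero mask at uncovered "
                f"position (labels=21)"
            )
        with_ca = t.atom_mask[:, ca] > 0
        if np.any(~np.isfinite(t.atom_positions[with_ca, ca, :])):
            v.append(f"templates[{ti}].atom_positions: non-finite CA coordinates")
        if not (0.0 <= t.sum_prob <= 1.0):
            v.append(f"templates[{ti}].sum_prob: outside [0, 1]")

    if fs.assembly is not None:
        total = fs.assembly.concatenated_length()
        if total != L:
            v.append(f"assembly: concatenated length {total} != query length {L}")
    return v


# --- Persistence ------------------------------------------------------------

_NATIVE_SIDE = ".json"


def save(fs: FeatureSet, path) -> None:
    """Write the native container: ``.npz`` arrays + JSON sidecar."""
    problems = validate(fs)
    if problems:
        raise ValueError("refusing to save invalid FeatureSet: " + "; ".join(problems))
    path = Path(path)
    arrays = {
        "aatype": fs.query.aatype,
        "residue_index": fs.query.residue_index,
        "between_segment_flags": fs.query.between_segment_flags,
        "msa_rows": fs.msa.rows,
        "msa_deletions": fs.msa.deletion_counts,
    }
    if fs.templates:
        arrays["template_labels"] = np.stack([t.labels for t in fs.templates])
        arrays["template_positions"] = np.stack(
            [t.atom_positions for t in fs.templates])
        arrays["template_masks"] = np.stack([t.atom_mask for t in fs.templates])
        arrays["template_sum_probs"] = np.array(
            [t.sum_prob for t in fs.templates], dtype=np.float64)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)
    side = {
        "sequence": fs.query.sequence,
        "row_labels": fs.msa.row_labels,
        "template_names": [t.name for t in fs.templates],
        "provenance": fs.provenance,
        "assembly": fs.assembly.to_dict() if fs.assembly is not None else None,
    }
    with open(str(path) + _NATIVE_SIDE, "w") as fh:
        json.dump(side, fh, indent=1, sort_keys=True)


def load(path) -> FeatureSet:
    """Read a container: native ``.npz``+sidecar, or a stock AF2 pickle."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if zipfile.is_zipfile(path):
        return _load_native(path)
    return _load_af2_pickle(path)


def _load_native(path: Path) -> FeatureSet:
    from .assembly import AssemblyPlan
    data = np.load(path)
    sidecar = Path(str(path) + _NATIVE_SIDE)
    if not sidecar.exists():
        raise DialectError(f"native container {path} missing sidecar {sidecar}")
    with open(sidecar) as fh:
        side = json.load(fh)
    query = QueryFeatures(
        sequence=side["sequence"],
        aatype=data["aatype"],
        residue_index=data["residue_index"],
        between_segment_flags=data["between_segment_flags"],
    )
    msa = MSABlock(data["msa_rows"], data["msa_deletions"], side["row_labels"])
    templates = []
    if "template_labels" in data:
        for i in range(data["template_labels"].shape[0]):
            templates.append(TemplateFeature(
                labels=data["template_labels"][i],
                atom_positions=data["template_positions"][i],
                atom_mask=data["template_masks"][i],
                name=side["template_names"][i],
                sum_prob=float(data["template_sum_probs"][i]),
            ))
    plan = AssemblyPlan.from_dict(side["assembly"]) if side.get("assembly") else None
    return FeatureSet(query=query, msa=msa, templates=templates,
                      assembly=plan, provenance=side.get("provenance", []))


_AF2_REQUIRED = ("aatype", "residue_index", "msa", "deletion_matrix_int")


def _load_af2_pickle(path: Path) -> FeatureSet:
    try:
        with open(path, "rb") as fh:
            raw = pickle.load(fh)
    except Exception as exc:
        raise DialectError(f"{path}: not a native container and failed to "
                           f"unpickle as an AF2 feature dict ({exc})") from exc
    if not isinstance(raw, dict):
        raise DialectError(f"{path}: pickled object is not a feature dict")
    missing = [k for k in _AF2_REQUIRED if k not in raw]
    if missing:
        raise DialectError(
            f"{path}: unknown field layout, missing fields: {', '.join(missing)}")
    return import_af2_features(raw)


def import_af2_features(raw: dict) -> FeatureSet:
    """Convert a stock AF2 v2.2 feature dict to the internal integer form.

    One-hot ``aatype`` (L x 21, canonical order) is decoded by argmax; MSA and
    template residue numbering use the HHblits convention and are remapped.
    """
    aatype = np.asarray(raw["aatype"])
    if aatype.ndim == 2:  # one-hot
        aatype = np.argmax(aatype, axis=-1)
    aatype = aatype.astype(np.int64)
    if "sequence" in raw:
        seq = raw["sequence"]
        if isinstance(seq, (bytes, np.bytes_)):
            seq = seq.decode()
        elif isinstance(seq, np.ndarray):
            seq = seq.reshape(-1)[0]
            seq = seq.decode() if isinstance(seq, (bytes, np.bytes_)) else str(seq)
    else:
        seq = decode_sequence(aatype)
    residue_index = np.asarray(raw["residue_index"]).astype(np.int64)
    bsf = np.asarray(
        raw.get("between_segment_residues", np.zeros(len(aatype)))
    ).astype(np.int64).reshape(-1)
    query = QueryFeatures(seq, aatype, residue_index, bsf)

    msa_raw = np.asarray(raw["msa"]).astype(np.int64)
    msa_rows = HHBLITS_TO_INTERNAL[msa_raw]
    msa_rows[0] = aatype  # row 0 is the query by the AF convention
    dels = np.asarray(raw["deletion_matrix_int"]).astype(np.int64)
    dels[0] = 0
    labels = [f"msa_{i}" for i in range(msa_rows.shape[0])]
    labels[0] = "query"
    msa = MSABlock(msa_rows, dels, labels)

    templates: list[TemplateFeature] = []
    if "template_aatype" in raw and len(np.asarray(raw["template_aatype"])):
        t_aatype = np.asarray(raw["template_aatype"])
        if t_aatype.ndim == 3:  # one-hot in HHblits order (T, L, 22)
            t_aatype = np.argmax(t_aatype, axis=-1)
        t_labels = HHBLITS_TO_INTERNAL[t_aatype.astype(np.int64)]
        t_pos = np.asarray(raw["template_all_atom_positions"], dtype=np.float64)
        t_mask = np.asarray(raw["template_all_atom_masks"], dtype=np.float64)
        names = raw.get("template_domain_names",
                        [f"template_{i}" for i in range(t_labels.shape[0])])
        probs = np.asarray(
            raw.get("template_sum_probs", np.ones((t_labels.shape[0], 1)))
        ).reshape(-1)
        for i in range(t_labels.shape[0]):
            name = names[i]
            if isinstance(name, (bytes, np.bytes_)):
                name = name.decode()
            lab = t_labels[i].copy()
            mask = t_mask[i].copy()
            # Positions with no atoms at all count as uncovered.
            lab[np.all(mask == 0, axis=-1)] = GAP_INDEX
            mask[lab == GAP_INDEX] = 0
            templates.append(TemplateFeature(lab, t_pos[i].copy(), mask,
                                             str(name), float(probs[i])))
    fs = FeatureSet(query=query, msa=msa, templates=templates)
    fs.record("import_af2_features", n_msa=msa.depth, n_templates=len(templates))
    return fs


def export_af2_features(fs: FeatureSet) -> dict:
    """Render the set in the stock AF2 v2.2 field layout (one-hot/HHblits)."""
    L = len(fs)
    aatype_onehot = np.zeros((L, 21), dtype=np.int32)
    aatype_onehot[np.arange(L), np.minimum(fs.query.aatype, 20)] = 1
    d = {
        "aatype": aatype_onehot,
        "sequence": np.array([fs.query.sequence.encode()], dtype=object),
        "residue_index": fs.query.residue_index.astype(np.int32),
        "between_segment_residues": fs.query.between_segment_flags.astype(np.int32),
        "seq_length": np.full(L, L, dtype=np.int32),
        "msa": INTERNAL_TO_HHBLITS[fs.msa.rows].astype(np.int32),
        "deletion_matrix_int": fs.msa.deletion_counts.astype(np.int32),
        "num_alignments": np.full(L, fs.msa.depth, dtype=np.int32),
    }
    T = len(fs.templates)
    t_onehot = np.zeros((T, L, 22), dtype=np.int32)
    for i, t in enumerate(fs.templates):
        t_onehot[i, np.arange(L), INTERNAL_TO_HHBLITS[t.labels]] = 1
    d["template_aatype"] = t_onehot
    d["template_all_atom_positions"] = np.stack(
        [t.atom_positions for t in fs.templates]
    ) if T else np.zeros((0, L, N_ATOM_SLOTS, 3))
    d["template_all_atom_masks"] = np.stack(
        [t.atom_mask for t in fs.templates]
    ) if T else np.zeros((0, L, N_ATOM_SLOTS))
    d["template_sequence"] = np.array(
        [decode_sequence(np.where(t.labels == GAP_INDEX, UNKNOWN_INDEX,
                                  t.labels)).encode()
         for t in fs.templates], dtype=object)
    d["template_domain_names"] = np.array(
        [t.name.encode() for t in fs.templates], dtype=object)
    d["template_sum_probs"] = np.array(
        [[t.sum_prob] for t in fs.templates], dtype=np.float32)
    return d
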