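"""Structure container and PDB/mmCIF I/O in the fixed 37-slot atom convention.

A :class:`StructureModel` holds per-residue chain identity, author numbering,
residue type, heavy-atom coordinates in the 37-slot layout used by AlphaFold2
feature arrays, and optional per-residue confidence (pLDDT-like, 0-100).
Reading and writing go through gemmi; the first model is used, alternate
locations resolve to blank/'A' or highest occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from .feature_store import AA_TO_INDEX, INDEX_TO_AA, UNKNOWN_INDEX

# Fixed heavy-atom slot order of the AF2 feature convention.
ATOM37 = [
    "N", "CA", "C", "CB", "O", "CG", "CG1", "CG2", "OG", "OG1", "SG", "CD",
    "CD1", "CD2", "ND1", "ND2", "OD1", "OD2", "SD", "CE", "CE1", "CE2", "CE3",
    "CZ", "CZ2", "CZ3", "NE", "NE1", "NE2", "NH1", "NH2", "NZ", "OE1", "OE2",
    "OH", "CH2", "OXT",
]
ATOM37_INDEX = {name: i for i, name in enumerate(ATOM37)}
CA = ATOM37_INDEX["CA"]
BACKBONE_CB_SLOTS = tuple(ATOM37_INDEX[n] for n in ("N", "CA", "C", "O", "CB"))

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}
ONE_TO_THREE = {one: three for three, one in THREE_TO_ONE.items()
                if three != "MSE"}
ONE_TO_THREE["X"] = "UNK"


@dataclass
class StructureModel:
    """A predicted or experimental structure in the query-compatible layout."""

    chain_ids: np.ndarray          # (L,) unicode
    residue_numbers: np.ndarray    # (L,) int
    aatype: np.ndarray             # (L,) int in [0, 20]
    atom_positions: np.ndarray     # (L, 37, 3) float
    atom_mask: np.ndarray          # (L, 37) 0/1
    confidence: Optional[np.ndarray] = None  # (L,) in [0, 100]
    name: str = "model"

    def __len__(self) -> int:
        return len(self.aatype)

    @property
    def sequence(self) -> str:
        return "".join(INDEX_TO_AA[int(a)] for a in self.aatype)

    @property
    def ca_mask(self) -> np.ndarray:
        return self.atom_mask[:, CA] > 0

    @property
    def ca_coords(self) -> np.ndarray:
        """CA coordinates for residues that have one (others excluded)."""
        return self.atom_positions[self.ca_mask, CA, :]

    def chains(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain_ids:
            if c not in seen:
                seen.append(str(c))
        return seen

    def select(self, index: np.ndarray) -> "StructureModel":
        index = np.asarray(index)
        return StructureModel(
            chain_ids=self.chain_ids[index].copy(),
            residue_numbers=self.residue_numbers[index].copy(),
            aatype=self.aatype[index].copy(),
            atom_positions=self.atom_positions[index].copy(),
            atom_mask=self.atom_mask[index].copy(),
            confidence=None if self.confidence is None
            else self.confidence[index].copy(),
            name=self.name,
        )

    def select_chain(self, chain_id: str) -> "StructureModel":
        return self.select(np.nonzero(self.chain_ids == chain_id)[0])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "StructureModel":
        out = self.select(np.arange(len(self)))
        out.atom_positions = out.atom_positions @ R.T + t
        out.atom_positions[out.atom_mask == 0] = 0.0
        return out

    def copy(self) -> "StructureModel":
        return self.select(np.arange(len(self)))

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_file(cls, path, name: Optional[str] = None) -> "StructureModel":
        """Read the first model of a PDB or mmCIF file."""
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        return cls.from_gemmi(st, name or Path(path).stem)

    @classmethod
    def from_gemmi(cls, st: gemmi.Structure, name: str) -> "StructureModel":
        model = st[0]
        chain_ids, numbers, aatypes, positions, masks, conf = [], [], [], [], [], []
        for chain in model:
            for res in chain:
                one = THREE_TO_ONE.get(res.name)
                if one is None:
                    continue  # skip waters/ligands
                pos = np.zeros((len(ATOM37), 3))
                mask = np.zeros(len(ATOM37))
                occ = np.full(len(ATOM37), -1.0)
                b_vals = []
                for atom in res:
                    slot = ATOM37_INDEX.get(atom.name)
                    if slot is None:
                        continue
                    # altloc blank/'A' preferred, else highest occupancy
                    rank = 2.0 if atom.altloc in ("", "A", "\x00") else float(atom.occ)
                    if occ[slot] < rank:
                        pos[slot] = [atom.pos.x, atom.pos.y, atom.pos.z]
                        mask[slot] = 1.0
                        occ[slot] = rank
                    b_vals.append(atom.b_iso)
                if mask.sum() == 0:
                    continue
                chain_ids.append(chain.name)
                numbers.append(res.seqid.num)
                aatypes.append(AA_TO_INDEX.get(one, UNKNOWN_INDEX))
                positions.append(pos)
                masks.append(mask)
                conf.append(float(np.mean(b_vals)) if b_vals else 0.0)
        if not positions:
            raise ValueError(f"no protein residues found in structure {name!r}")
        conf_arr = np.array(conf)
        if np.all(conf_arr == 0):
            conf_arr = None
        return cls(
            chain_ids=np.array(chain_ids, dtype="U4"),
            residue_numbers=np.array(numbers, dtype=np.int64),
            aatype=np.array(aatypes, dtype=np.int64),
            atom_positions=np.array(positions),
            atom_mask=np.array(masks),
            confidence=conf_arr,
            name=name,
        )

    def to_gemmi(self) -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = self.name
        model = gemmi.Model("1")
        chain = None
        last_chain_id = None
        for i in range(len(self)):
            cid = str(self.chain_ids[i])
            if cid != last_chain_id:
                if chain is not None:
                    model.add_chain(chain)
                chain = gemmi.Chain(cid)
                last_chain_id = cid
            res = gemmi.Residue()
            res.name = ONE_TO_THREE.get(INDEX_TO_AA[int(self.aatype[i])], "UNK")
            res.seqid = gemmi.SeqId(int(self.residue_numbers[i]), " ")
            b = 0.0 if self.confidence is None else float(self.confidence[i])
            for slot in np.nonzero(self.atom_mask[i] > 0)[0]:
                atom = gemmi.Atom()
                atom.name = ATOM37[slot]
                x, y, z = self.atom_positions[i, slot]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                atom.element = gemmi.Element(ATOM37[slot][0])
                atom.occ = 1.0
                atom.b_iso = b
                res.add_atom(atom)
            chain.add_residue(res)
        if chain is not None:
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        return st

    def to_pdb(self, path) -> None:
        st = self.to_gemmi()
        st.write_pdb(str(path))

    def to_mmcif(self, path) -> None:
        st = self.to_gemmi()
        st.make_mmcif_document().write_file(str(path))


def sequence_of(aatype: np.ndarray) -> str:
    return "".join(INDEX_TO_AA[int(a)] for a in aatype)
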