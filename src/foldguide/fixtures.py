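"""Synthetic-data generators: ideal secondary structure, hinge proteins,
two-state ensembles, toy complexes and toy MSAs.

Everything here is a geometric stand-in built from ideal backbone internal
coordinates (bond lengths N-CA 1.458, CA-C 1.525, C-N 1.329 A; helix
phi = -57, psi = -47; strand phi = -120, psi = +120; extended 180/180) with
C-beta at the ideal tetrahedral position for non-glycine residues.  All
generators are fully deterministic given their seed, and fixtures are written
as standard PDB/A3M files so tests exercise the real readers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .feature_store import AA_TO_INDEX, MSABlock, QueryFeatures, encode_sequence
from .geometry import place_atom, rotation_about_axis
from .structures import ATOM37_INDEX, CA, StructureModel

_N, _CA, _C, _CB, _O = (ATOM37_INDEX[a] for a in ("N", "CA", "C", "CB", "O"))

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
    "extended": (180.0, 180.0),
}

# bond lengths / angles of the ideal peptide unit
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_OMEGA = 180.0


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic fixture."""

    kind: str                       # helix | strand | extended |
                                    # two_block_hinge | two_state_ensemble |
                                    # toy_complex
    lengths: tuple = (40, 5, 40)    # blocks/linker for hinges, else (L,)
    hinge_angle: float = 0.0        # degrees
    delta_angle: float = 30.0       # state separation for ensembles
    noise: float = 0.0              # per-atom Gaussian sigma, A
    n_members: int = 8
    seed: int = 0
    sequence: Optional[str] = None  # defaults to poly-Ala-like pattern


def _default_sequence(n: int) -> str:
    # varied but deterministic; avoids an all-Ala degenerate alphabet
    pattern = "AEKLVDGSTR"
    return "".join(pattern[i % len(pattern)] for i in range(n))


def build_backbone(phi_psi: list[tuple[float, float]]) -> np.ndarray:
    """Backbone (n, 4, 3) -> N, CA, C, O from a per-residue phi/psi list."""
    n = len(phi_psi)
    coords = np.zeros((n, 4, 3))
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [_B_N_CA, 0.0, 0.0]
    ang = np.radians(180.0 - _A_N_CA_C)  # angle of CA->C with the +x axis
    coords[0, 2] = coords[0, 1] + _B_CA_C * np.array(
        [np.cos(ang), np.sin(ang), 0.0])
    for i in range(n):
        phi, psi = phi_psi[i]
        Ni, CAi, Ci = coords[i, 0], coords[i, 1], coords[i, 2]
        coords[i, 3] = place_atom(Ni, CAi, Ci, _B_C_O, _A_CA_C_O, psi + 180.0)
        if i + 1 < n:
            n_next = place_atom(Ni, CAi, Ci, _B_C_N, _A_CA_C_N, psi)
            ca_next = place_atom(CAi, Ci, n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
            phi_next = phi_psi[i + 1][0]
            c_next = place_atom(Ci, n_next, ca_next, _B_CA_C, _A_N_CA_C,
                                phi_next)
            coords[i + 1, 0] = n_next
            coords[i + 1, 1] = ca_next
            coords[i + 1, 2] = c_next
    return coords


def _ideal_cb(n_pos, ca_pos, c_pos) -> np.ndarray:
    # tetrahedral C-beta with L-chirality from the backbone frame
    b = ca_pos - n_pos
    c = c_pos - ca_pos
    a = np.cross(b, c)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c + ca_pos


def _assemble(sequence: str, backbone: np.ndarray, chain_id: str = "A",
              start_number: int = 1, name: str = "fixture") -> StructureModel:
    n = len(sequence)
    aatype = encode_sequence(sequence)
    pos = np.zeros((n, 37, 3))
    mask = np.zeros((n, 37))
    for i in range(n):
        pos[i, _N], pos[i, _CA], pos[i, _C], pos[i, _O] = backbone[i]
        mask[i, [_N, _CA, _C, _O]] = 1.0
        if sequence[i] != "G":
            pos[i, _CB] = _ideal_cb(backbone[i, 0], backbone[i, 1],
                                    backbone[i, 2])
            mask[i, _CB] = 1.0
    return StructureModel(
        chain_ids=np.full(n, chain_id, dtype="U4"),
        residue_numbers=np.arange(start_number, start_number + n,
                                  dtype=np.int64),
        aatype=aatype,
        atom_positions=pos,
        atom_mask=mask,
        name=name,
    )


def _two_block_backbone(lengths: tuple, hinge_angle: float) -> tuple:
    """Helix-linker-helix backbone with block 2 bent at the linker middle."""
    n1, nl, n2 = lengths
    phi_psi = ([PHI_PSI["helix"]] * n1 + [PHI_PSI["extended"]] * nl
               + [PHI_PSI["helix"]] * n2)
    backbone = build_backbone(phi_psi)
    pivot_res = n1 + nl // 2            # middle linker residue
    if abs(hinge_angle) > 1e-9:
        pivot = backbone[pivot_res, 1].copy()
        u = backbone[pivot_res, 1] - backbone[max(pivot_res - 3, 0), 1]
        u /= np.linalg.norm(u)
        axis = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.array([0.0, 1.0, 0.0])
        R = rotation_about_axis(axis, hinge_angle)
        moving = backbone[pivot_res:]
        backbone = backbone.copy()
        backbone[pivot_res:] = (moving - pivot) @ R.T + pivot
    return backbone, pivot_res


def make_structure(spec: FixtureSpec) -> StructureModel:
    """Build one synthetic structure according to the spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind in PHI_PSI:
        n = int(spec.lengths[0])
        seq = spec.sequence or _default_sequence(n)
        backbone = build_backbone([PHI_PSI[spec.kind]] * n)
        model = _assemble(seq, backbone, name=f"{spec.kind}_{n}")
    elif spec.kind == "two_block_hinge":
        n1, nl, n2 = spec.lengths
        total = n1 + nl + n2
        seq = spec.sequence or _default_sequence(total)
        backbone, _ = _two_block_backbone(spec.lengths, spec.hinge_angle)
        model = _assemble(seq, backbone,
                          name=f"hinge_{spec.hinge_angle:g}deg")
    elif spec.kind == "toy_complex":
        return make_toy_complex(spec)
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    if spec.noise > 0:
        jitter = rng.normal(scale=spec.noise,
                            size=model.atom_positions.shape)
        model.atom_positions = model.atom_positions + jitter
        model.atom_positions[model.atom_mask == 0] = 0.0
    return model


def make_toy_complex(spec: FixtureSpec) -> StructureModel:
    """Two copies of a helix packed side by side as chains A and B.

    Chain B is chain A rotated 180 degrees about the helix axis and offset
    perpendicular to it, leaving the two chains in contact — a stand-in for
    a dimer interface template.
    """
    n = int(spec.lengths[0])
    seq = spec.sequence or _default_sequence(n)
    backbone = build_backbone([PHI_PSI["helix"]] * n)
    a = _assemble(seq, backbone, chain_id="A", name="toy_complex")
    cas = a.atom_positions[:, CA, :]
    center = cas.mean(axis=0)
    u, s, vt = np.linalg.svd(cas - center)
    axis, perp = vt[0], vt[1]
    R = rotation_about_axis(axis, 180.0)
    shift = 8.5 * perp
    b = a.copy()
    b.chain_ids = np.full(n, "B", dtype="U4")
    b.atom_positions = (b.atom_positions - center) @ R.T + center + shift
    b.atom_positions[b.atom_mask == 0] = 0.0
    out = StructureModel(
        chain_ids=np.concatenate([a.chain_ids, b.chain_ids]),
        residue_numbers=np.concatenate([a.residue_numbers, b.residue_numbers]),
        aatype=np.concatenate([a.aatype, b.aatype]),
        atom_positions=np.concatenate([a.atom_positions, b.atom_positions]),
        atom_mask=np.concatenate([a.atom_mask, b.atom_mask]),
        name="toy_complex",
    )
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        out.atom_positions = out.atom_positions + rng.normal(
            scale=spec.noise, size=out.atom_positions.shape)
        out.atom_positions[out.atom_mask == 0] = 0.0
    return out


def make_two_state_ensemble(spec: FixtureSpec):
    """Hinge-protein ensemble split between two bend angles.

    Members alternate between hinge angles theta and theta + delta with
    per-atom Gaussian noise; returns ``(structures, true_labels)`` for
    parameter-recovery tests.
    """
    if spec.n_members < 4:
        raise ValueError("two-state ensemble needs at least 4 members")
    rng = np.random.default_rng(spec.seed)
    base_angle = spec.hinge_angle
    structures, labels = [], []
    n1, nl, n2 = spec.lengths
    total = n1 + nl + n2
    seq = spec.sequence or _default_sequence(total)
    for i in range(spec.n_members):
        state = i % 2
        angle = base_angle + state * spec.delta_angle
        backbone, _ = _two_block_backbone(spec.lengths, angle)
        model = _assemble(seq, backbone, name=f"member_{i}_state{state}")
        if spec.noise > 0:
            model.atom_positions = model.atom_positions + rng.normal(
                scale=spec.noise, size=model.atom_positions.shape)
            model.atom_positions[model.atom_mask == 0] = 0.0
        structures.append(model)
        labels.append(state)
    return structures, np.array(labels, dtype=np.int64)


def make_hbond_strand_pair() -> StructureModel:
    """Two four-residue strands with exactly four backbone hydrogen bonds.

    Synthetic stand-in geometry: the paired N...O atoms sit at the canonical
    2.9 A donor-acceptor distance in the antiparallel ladder pattern
    (A1.N-B4.O, A2.O-B3.N, A3.N-B2.O, A4.O-B1.N); every other cross-chain
    polar contact is kept beyond 3.5 A.  Residue spacing is exaggerated so
    the hydrogen-bond count is exactly four by construction.
    """
    def residue(n, ca, c, o):
        pos = np.zeros((37, 3))
        mask = np.zeros(37)
        for slot, xyz in ((_N, n), (_CA, ca), (_C, c), (_O, o)):
            pos[slot] = xyz
            mask[slot] = 1.0
        return pos, mask

    a_res = [residue((0, 7 * i, 0), (1.0, 7 * i + 1.5, 0),
                     (0.3, 7 * i + 3.0, 0), (0.0, 7 * i + 4.2, 0))
             for i in range(4)]
    b_res = [
        residue((2.9, 25.2, 0), (4.5, 24.5, 0), (5.0, 24.0, 0), (5.5, 23.0, 0)),
        residue((5.5, 12.0, 0), (4.5, 13.5, 0), (3.5, 13.0, 0), (2.9, 14.0, 0)),
        residue((2.9, 11.2, 0), (4.5, 10.5, 0), (5.0, 10.0, 0), (5.5, 9.0, 0)),
        residue((5.5, -2.0, 0), (4.5, -1.5, 0), (3.5, -1.0, 0), (2.9, 0.0, 0)),
    ]
    pos = np.stack([p for p, _ in a_res + b_res])
    mask = np.stack([m for _, m in a_res + b_res])
    return StructureModel(
        chain_ids=np.array(["A"] * 4 + ["B"] * 4, dtype="U4"),
        residue_numbers=np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=np.int64),
        aatype=np.full(8, AA_TO_INDEX["V"], dtype=np.int64),
        atom_positions=pos,
        atom_mask=mask,
        name="hbond_strand_pair",
    )


def make_toy_msa(query: str, n_rows: int, conservation=1.0,
                 seed: int = 0) -> MSABlock:
    """Sample alignment rows column-wise from a conservation profile.

    ``conservation`` is the per-column probability of keeping the query
    residue (scalar or length-L array); other residues are drawn uniformly
    from the remaining 19.
    """
    qf = QueryFeatures.from_sequence(query)
    L = len(query)
    profile = np.broadcast_to(np.asarray(conservation, dtype=float), (L,))
    rng = np.random.default_rng(seed)
    rows = [qf.aatype.copy()]
    labels = ["query"]
    for r in range(1, n_rows):
        row = qf.aatype.copy()
        mutate = rng.uniform(size=L) >= profile
        for j in np.nonzero(mutate)[0]:
            choices = [a for a in range(20) if a != qf.aatype[j]]
            row[j] = choices[int(rng.integers(len(choices)))]
        rows.append(row)
        labels.append(f"synthetic_{r}")
    return MSABlock(rows=np.stack(rows),
                    deletion_counts=np.zeros((n_rows, L), dtype=np.int64),
                    row_labels=labels)


def write_fixture_bundle(outdir, seed: int = 0) -> dict[str, str]:
    """Emit the named fixture files used by the demos: helix, hinge pair,
    two-state ensemble, toy dimer complex, and a toy A3M."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .msa_ops import write_a3m
    written = {}
    helix = make_structure(FixtureSpec(kind="helix", lengths=(30,), seed=seed))
    helix.to_pdb(outdir / "helix.pdb")
    written["helix"] = str(outdir / "helix.pdb")
    ensemble, labels = make_two_state_ensemble(
        FixtureSpec(kind="two_state_ensemble", hinge_angle=10.0,
                    delta_angle=30.0, noise=0.2, n_members=8, seed=seed))
    for m, lab in zip(ensemble, labels):
        p = outdir / f"{m.name}.pdb"
        m.to_pdb(p)
        written[m.name] = str(p)
    complex_ = make_toy_complex(FixtureSpec(kind="toy_complex", lengths=(24,),
                                            seed=seed))
    complex_.to_pdb(outdir / "toy_complex.pdb")
    written["toy_complex"] = str(outdir / "toy_complex.pdb")
    msa = make_toy_msa(_default_sequence(24), n_rows=20, conservation=0.8,
                       seed=seed)
    write_a3m(msa, outdir / "toy.a3m")
    written["toy_msa"] = str(outdir / "toy.a3m")
    return written
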