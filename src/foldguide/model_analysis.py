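"""Model evaluation and ranking: confidence, stereochemistry, compactness,
consistency with the provided guidance, and interface classification.

Predictions are judged on four axes — confidence (mean pLDDT), structural
soundness (Ramachandran outliers against a coarse rectangular region table,
and compactness relative to the globular radius-of-gyration power law),
consistency with the supplied information (RMSD to each template, presence of
user-declared interfaces), and interface quality (buried surface area by
Shrake-Rupley SASA difference, geometric hydrogen-bond count, external
interface energy only when an external tool is configured).  The composite
rank is lexicographic and every component is reported so users can re-weight.
"""

from __future__ import annotations

import html as html_mod
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .feature_store import FeatureSet, TemplateFeature
from .geometry import kabsch, dihedral
from .structures import ATOM37, ATOM37_INDEX, CA, StructureModel

_N, _C, _O = ATOM37_INDEX["N"], ATOM37_INDEX["C"], ATOM37_INDEX["O"]
GLY = 7  # index of G in the residue alphabet
PRO = 14


@dataclass
class Superposition:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_aligned: int


def _pair_by_numbering(a: StructureModel, b: StructureModel):
    lb = {}
    for i in range(len(b)):
        if b.atom_mask[i, CA] > 0:
            lb[(str(b.chain_ids[i]), int(b.residue_numbers[i]))] = i
    pa, pb = [], []
    for i in range(len(a)):
        if a.atom_mask[i, CA] == 0:
            continue
        j = lb.get((str(a.chain_ids[i]), int(a.residue_numbers[i])))
        if j is not None:
            pa.append(i)
            pb.append(j)
    return pa, pb


def _pair_by_alignment(a: StructureModel, b: StructureModel):
    from .template_ops import align_sequences
    amap = align_sequences(a.sequence, b.sequence)
    pa, pb = [], []
    for qi, ti in amap.pairs:
        if a.atom_mask[qi, CA] > 0 and b.atom_mask[ti, CA] > 0:
            pa.append(qi)
            pb.append(ti)
    return pa, pb


def superpose(a: StructureModel, b: StructureModel,
              selection: Optional[Sequence[tuple[str, int]]] = None
              ) -> Superposition:
    """Least-squares rigid superposition of ``a`` onto ``b`` over paired CAs.

    Residues pair by chain and author number; when numbering schemes do not
    match, pairing falls back to a sequence alignment.  The rotation is
    proper (det = +1).
    """
    pa, pb = _pair_by_numbering(a, b)
    if selection is not None:
        wanted = set(selection)
        keep = [k for k, i in enumerate(pa)
                if (str(a.chain_ids[i]), int(a.residue_numbers[i])) in wanted]
        pa = [pa[k] for k in keep]
        pb = [pb[k] for k in keep]
    if len(pa) < 3:
        pa, pb = _pair_by_alignment(a, b)
    if len(pa) < 3:
        raise ValueError(f"fewer than 3 paired CA atoms ({len(pa)})")
    P = a.atom_positions[pa, CA, :]
    Q = b.atom_positions[pb, CA, :]
    R, t, rmsd = kabsch(P, Q)
    return Superposition(rotation=R, translation=t, rmsd=rmsd,
                         n_aligned=len(pa))


# --- Ramachandran -----------------------------------------------------------
# Coarse rectangular allowed regions (phi_min, phi_max, psi_min, psi_max), a
# soundness heuristic rather than a validation-grade contour set.  The ideal
# helix (-57, -47) and strand (-120, +120) fall inside the general regions;
# glycine is unrestricted, proline restricted to the narrow phi band.
RAMA_GENERAL = [
    (-180.0, -30.0, -100.0, 60.0),    # right-handed helical basin
    (-180.0, -30.0, 60.0, 180.0),     # sheet / PPII basin
    (-180.0, -30.0, -180.0, -150.0),  # sheet basin (psi wrap)
    (20.0, 100.0, -40.0, 100.0),      # left-handed helical basin
]
RAMA_PRO = [
    (-110.0, -30.0, -70.0, 40.0),
    (-110.0, -30.0, 110.0, 180.0),
    (-110.0, -30.0, -180.0, -150.0),
]


def _in_regions(phi: float, psi: float, regions) -> bool:
    return any(p0 <= phi <= p1 and s0 <= psi <= s1
               for p0, p1, s0, s1 in regions)


_PEPTIDE_BOND_MAX = 2.5  # A; larger C-N separation means a chain break


def ramachandran_outliers(m: StructureModel):
    """Phi/psi outlier fraction over classifiable residues.

    Residues flanking chain breaks (numbering jump, missing backbone, or a
    C-N distance above 2.5 A) are skipped.  Returns ``(fraction, flags)``
    where ``flags[i]`` is True for an outlier; with no classifiable residue
    the fraction is reported as 0.0 together with ``n_classified == 0``.
    """
    n = len(m)
    flags = np.zeros(n, dtype=bool)
    classifiable = np.zeros(n, dtype=bool)
    bb_ok = (m.atom_mask[:, _N] > 0) & (m.atom_mask[:, CA] > 0) & \
            (m.atom_mask[:, _C] > 0)
    for i in range(1, n - 1):
        if not (bb_ok[i - 1] and bb_ok[i] and bb_ok[i + 1]):
            continue
        if m.chain_ids[i - 1] != m.chain_ids[i] or \
           m.chain_ids[i] != m.chain_ids[i + 1]:
            continue
        if m.residue_numbers[i] - m.residue_numbers[i - 1] != 1 or \
           m.residue_numbers[i + 1] - m.residue_numbers[i] != 1:
            continue
        prev_c = m.atom_positions[i - 1, _C]
        this_n = m.atom_positions[i, _N]
        this_c = m.atom_positions[i, _C]
        next_n = m.atom_positions[i + 1, _N]
        if np.linalg.norm(this_n - prev_c) > _PEPTIDE_BOND_MAX or \
           np.linalg.norm(next_n - this_c) > _PEPTIDE_BOND_MAX:
            continue
        phi = dihedral(prev_c, this_n, m.atom_positions[i, CA], this_c)
        psi = dihedral(this_n, m.atom_positions[i, CA], this_c, next_n)
        classifiable[i] = True
        aa = int(m.aatype[i])
        if aa == GLY:
            ok = True
        elif aa == PRO:
            ok = _in_regions(phi, psi, RAMA_PRO)
        else:
            ok = _in_regions(phi, psi, RAMA_GENERAL)
        flags[i] = not ok
    n_classified = int(classifiable.sum())
    fraction = (float(flags[classifiable].mean()) if n_classified else 0.0)
    return fraction, {"flags": flags, "classifiable": classifiable,
                      "n_classified": n_classified}


# --- Compactness ------------------------------------------------------------
# Globular proteins follow Rg ~ R0 * N^nu with nu ~ 0.4; the score is the CA
# radius of gyration over that expectation, ~1 for compact chains.
_RG_PREFACTOR = 2.2  # A
_RG_EXPONENT = 0.4


def compactness(m: StructureModel) -> float:
    cas = m.ca_coords
    if cas.shape[0] < 5:
        raise ValueError("compactness needs at least 5 CA atoms")
    rg = float(np.sqrt(np.mean(np.sum((cas - cas.mean(axis=0)) ** 2, axis=1))))
    expected = _RG_PREFACTOR * cas.shape[0] ** _RG_EXPONENT
    return rg / expected


# --- Interfaces -------------------------------------------------------------

_SASA_POINTS = 300   # Fibonacci sphere points per atom
_PROBE = 1.4         # A, water probe

# geometric hydrogen-bond rule: donor and acceptor heavy atoms within 3.5 A.
# With no hydrogens in the 37-slot representation the donor-H-acceptor angle
# is not computable, so the heavy-atom distance + element rule applies:
# donors are nitrogens and hydroxyl/thiol-free oxygens (Ser/Thr/Tyr OH),
# acceptors are oxygens.
_HBOND_MAX = 3.5
_DONOR_NAMES = {n for n in ATOM37 if n.startswith("N")} | {"OG", "OG1", "OH"}
_ACCEPTOR_NAMES = {n for n in ATOM37 if n.startswith("O")}


@dataclass
class InterfaceReport:
    chain_pair: tuple[str, str]
    buried_area: float          # A^2
    hbond_count: int
    delta_g: Optional[float]    # kcal/mol from an external tool, else None
    tier: str

    def to_dict(self) -> dict:
        return {"chain_pair": list(self.chain_pair),
                "buried_area": self.buried_area,
                "hbond_count": self.hbond_count,
                "delta_g": self.delta_g, "tier": self.tier}


def _to_biotite(m: StructureModel):
    import biotite.structure as struc
    from .feature_store import INDEX_TO_AA
    from .structures import ONE_TO_THREE
    slots = np.nonzero(m.atom_mask > 0)
    n_atoms = slots[0].size
    arr = struc.AtomArray(n_atoms)
    arr.coord = m.atom_positions[slots].astype(np.float32)
    arr.chain_id = m.chain_ids[slots[0]]
    arr.res_id = m.residue_numbers[slots[0]]
    arr.res_name = np.array(
        [ONE_TO_THREE.get(INDEX_TO_AA[int(a)], "UNK")
         for a in m.aatype[slots[0]]])
    arr.atom_name = np.array([ATOM37[s] for s in slots[1]])
    arr.element = np.array([ATOM37[s][0] for s in slots[1]])
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    return arr


def _total_sasa(m: StructureModel) -> float:
    import biotite.structure as struc
    arr = _to_biotite(m)
    sasa = struc.sasa(arr, probe_radius=_PROBE, point_number=_SASA_POINTS,
                      vdw_radii="Single")
    return float(np.nansum(sasa))


def _classify_tier(buried: float, hbonds: int) -> str:
    if buried < 100.0:
        return "none"
    if buried < 400.0 or hbonds < 2:
        return "weak"
    if buried < 800.0:
        return "moderate"
    return "extensive"


def interface_metrics(m: StructureModel, chain_pair: tuple[str, str],
                      delta_g: Optional[float] = None) -> InterfaceReport:
    """Buried area, hydrogen bonds and tier for one chain pair.

    Buried area is SASA(A) + SASA(B) - SASA(AB) over heavy atoms (probe
    1.4 A, 300 points per atom) and is symmetric in chain order.  ``delta_g``
    is filled only from an external interface-energy tool (see
    :func:`parse_pisa_xml`); it is never computed internally.
    """
    ca_id, cb_id = chain_pair
    chains = m.chains()
    for cid in chain_pair:
        if cid not in chains:
            raise ValueError(f"chain {cid!r} not in model (has {chains})")
    a = m.select_chain(ca_id)
    b = m.select_chain(cb_id)
    ab = m.select(np.nonzero(np.isin(m.chain_ids, list(chain_pair)))[0])
    buried = _total_sasa(a) + _total_sasa(b) - _total_sasa(ab)
    buried = max(buried, 0.0)
    hbonds = _count_hbonds(a, b)
    return InterfaceReport(chain_pair=(ca_id, cb_id), buried_area=buried,
                           hbond_count=hbonds, delta_g=delta_g,
                           tier=_classify_tier(buried, hbonds))


def _polar_atoms(m: StructureModel, names) -> np.ndarray:
    coords = []
    for i in range(len(m)):
        for s in np.nonzero(m.atom_mask[i] > 0)[0]:
            if ATOM37[s] in names:
                coords.append(m.atom_positions[i, s])
    return np.array(coords).reshape(-1, 3)


def _count_hbonds(a: StructureModel, b: StructureModel) -> int:
    from scipy.spatial.distance import cdist
    count = 0
    pairs: set[tuple[int, int]] = set()
    don_a, acc_a = _polar_atoms(a, _DONOR_NAMES), _polar_atoms(a, _ACCEPTOR_NAMES)
    don_b, acc_b = _polar_atoms(b, _DONOR_NAMES), _polar_atoms(b, _ACCEPTOR_NAMES)

    def add(donors, acceptors, flip):
        nonlocal count
        if donors.size == 0 or acceptors.size == 0:
            return
        d = cdist(donors, acceptors)
        for i, j in zip(*np.nonzero(d <= _HBOND_MAX)):
            key = (round(float(donors[i].sum()), 3),
                   round(float(acceptors[j].sum()), 3))
            key = key[::-1] if flip else key
            if key not in pairs:
                pairs.add(key)
                count += 1

    add(don_a, acc_b, flip=False)
    add(don_b, acc_a, flip=True)
    return count


def parse_pisa_xml(path) -> dict[tuple[str, str], float]:
    """Optional hook: read interface energies from a PISA-compatible XML.

    Returns {(chain_a, chain_b): delta_g (kcal/mol)}; absent/NULL entries are
    skipped.  The hook is null-safe — callers treat a missing file or pair as
    ``delta_g=None``.
    """
    from xml.etree import ElementTree
    out: dict[tuple[str, str], float] = {}
    root = ElementTree.parse(str(path)).getroot()
    for iface in root.iter("interface"):
        mols = [m.findtext("chain_id") for m in iface.iter("molecule")]
        dg = iface.findtext("int_solv_en") or iface.findtext("delta_g")
        if len(mols) >= 2 and dg:
            try:
                out[(mols[0], mols[1])] = float(dg)
            except ValueError:
                continue
    return out


# --- Ranking ----------------------------------------------------------------

_EXPERIMENTAL_PLDDT = 100.0  # documented default for confidence-less models


@dataclass
class RankEntry:
    name: str
    mean_plddt: float
    rama_outlier_fraction: float
    compactness_score: float
    rmsd_to_templates: dict[str, float]
    interfaces: dict[str, dict]
    missing_required_interfaces: int

    def sort_key(self):
        # lexicographic: required interactions first, then confidence,
        # then soundness, then compactness distance from 1, then name
        return (self.missing_required_interfaces,
                -self.mean_plddt,
                self.rama_outlier_fraction,
                abs(self.compactness_score - 1.0),
                self.name)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mean_plddt": self.mean_plddt,
            "rama_outlier_fraction": self.rama_outlier_fraction,
            "compactness": self.compactness_score,
            "rmsd_to_templates": self.rmsd_to_templates,
            "interfaces": self.interfaces,
            "missing_required_interfaces": self.missing_required_interfaces,
        }


@dataclass
class RankReport:
    entries: list[RankEntry]        # already in rank order
    provenance: list[dict] = field(default_factory=list)

    @property
    def best(self) -> RankEntry:
        return self.entries[0]

    def to_dict(self) -> dict:
        return {"ranking": [e.to_dict() for e in self.entries],
                "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: dict) -> "RankReport":
        entries = [RankEntry(
            name=e["name"], mean_plddt=e["mean_plddt"],
            rama_outlier_fraction=e["rama_outlier_fraction"],
            compactness_score=e["compactness"],
            rmsd_to_templates=e["rmsd_to_templates"],
            interfaces=e["interfaces"],
            missing_required_interfaces=e["missing_required_interfaces"],
        ) for e in d["ranking"]]
        return cls(entries=entries, provenance=d.get("provenance", []))


def _template_as_structure(t: TemplateFeature) -> StructureModel:
    from .feature_store import GAP_INDEX, UNKNOWN_INDEX
    idx = np.nonzero(t.covered & (t.atom_mask[:, CA] > 0))[0]
    return StructureModel(
        chain_ids=np.full(idx.size, "A", dtype="U4"),
        residue_numbers=idx.astype(np.int64) + 1,
        aatype=np.where(t.labels[idx] == GAP_INDEX, UNKNOWN_INDEX,
                        t.labels[idx]),
        atom_positions=t.atom_positions[idx].copy(),
        atom_mask=t.atom_mask[idx].copy(),
        name=t.name,
    )


def rank_models(models: Sequence[StructureModel], fs: Optional[FeatureSet] = None,
                references: Optional[Sequence[StructureModel]] = None,
                declared_interfaces: Optional[Sequence[tuple[str, str]]] = None
                ) -> RankReport:
    """Score and order predictions; deterministic under input permutation.

    Models missing a declared (required) interface rank below any model
    having it regardless of confidence; remaining ties resolve by mean
    pLDDT, then outlier fraction, then compactness, then model name.
    """
    if not models:
        raise ValueError("rank_models needs at least one model")
    declared = [tuple(p) for p in (declared_interfaces or [])]
    entries = []
    for m in models:
        plddt = (_EXPERIMENTAL_PLDDT if m.confidence is None
                 else float(np.mean(m.confidence)))
        frac, _detail = ramachandran_outliers(m)
        try:
            comp = compactness(m)
        except ValueError:
            comp = float("nan")
        rmsds = {}
        if fs is not None:
            for t in fs.templates:
                try:
                    ts = _template_as_structure(t)
                    # template frame indexes the concatenated query directly
                    mq = m.copy()
                    mq.chain_ids = np.full(len(mq), "A", dtype="U4")
                    mq.residue_numbers = np.arange(1, len(mq) + 1,
                                                   dtype=np.int64)
                    rmsds[t.name] = superpose(mq, ts).rmsd
                except ValueError:
                    rmsds[t.name] = float("nan")
        for ref in references or []:
            try:
                rmsds[f"ref:{ref.name}"] = superpose(m, ref).rmsd
            except ValueError:
                rmsds[f"ref:{ref.name}"] = float("nan")
        ifaces = {}
        missing = 0
        for pair in declared:
            try:
                rep = interface_metrics(m, pair)
                present = rep.buried_area > 0.0
                ifaces["-".join(pair)] = dict(rep.to_dict(), present=present)
                if not present:
                    missing += 1
            except ValueError:
                ifaces["-".join(pair)] = {"present": False, "error": "missing chain"}
                missing += 1
        entries.append(RankEntry(
            name=m.name, mean_plddt=plddt, rama_outlier_fraction=frac,
            compactness_score=comp, rmsd_to_templates=rmsds,
            interfaces=ifaces, missing_required_interfaces=missing))
    entries.sort(key=lambda e: e.sort_key())
    prov = list(fs.provenance) if fs is not None else []
    return RankReport(entries=entries, provenance=prov)


# --- Reporting --------------------------------------------------------------

def write_report(rank: RankReport, outdir, state=None) -> dict[str, str]:
    """Write the HTML summary, its JSON machine twin, and a plain-text
    visualization script (PyMOL-style commands)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = rank.to_dict()
    if state is not None:
        payload["state_analysis"] = state.to_dict()
    json_path = outdir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)

    rows = []
    for i, e in enumerate(rank.entries, start=1):
        rows.append(
            f"<tr><td>{i}</td><td>{html_mod.escape(e.name)}</td>"
            f"<td>{e.mean_plddt:.1f}</td>"
            f"<td>{e.rama_outlier_fraction:.3f}</td>"
            f"<td>{e.compactness_score:.2f}</td>"
            f"<td>{e.missing_required_interfaces}</td></tr>")
    prov_items = "".join(
        f"<li>{html_mod.escape(p.get('op', '?'))} "
        f"{html_mod.escape(json.dumps(p.get('params', {})))}</li>"
        for p in rank.provenance)
    html_doc = (
        "<html><head><title>prediction report</title></head><body>"
        "<h1>Model ranking</h1>"
        "<table border='1'><tr><th>rank</th><th>model</th><th>mean pLDDT</th>"
        "<th>Rama outliers</th><th>compactness</th>"
        "<th>missing interfaces</th></tr>"
        + "".join(rows) + "</table>"
        "<h2>Input provenance</h2><ul>" + prov_items + "</ul>"
        "</body></html>")
    html_path = outdir / "report.html"
    html_path.write_text(html_doc)

    pml = ["# visualization script: load models, color by confidence"]
    for e in rank.entries:
        pml.append(f"load {e.name}.pdb, {e.name}")
        pml.append(f"spectrum b, rainbow_rev, {e.name}")
    if len(rank.entries) > 1:
        best = rank.entries[0].name
        for e in rank.entries[1:]:
            pml.append(f"align {e.name}, {best}")
    pml_path = outdir / "session.pml"
    pml_path.write_text("\n".join(pml) + "\n")
    return {"json": str(json_path), "html": str(html_path),
            "pml": str(pml_path)}
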