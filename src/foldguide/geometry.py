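"""Shared geometric primitives: rigid superposition, dihedrals, atom placement."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with a proper rotation (det = +1) such that
    ``mobile @ R.T + t`` best fits ``target``.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[0] < 3:
        raise ValueError("superposition needs two equal (n>=3, 3) coordinate sets")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - ct, mobile - cm)
    R = rot.as_matrix()
    t = ct - R @ cm
    rmsd = rssd / np.sqrt(mobile.shape[0])
    return R, t, float(rmsd)


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def rmsd_static(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between paired coordinates without superposition."""
    d = np.asarray(a) - np.asarray(b)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=-1))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC sign convention)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond_length: float, bond_angle_deg: float,
               dihedral_deg: float) -> np.ndarray:
    """Place atom X bonded to ``c`` from internal coordinates.

    ``bond_angle_deg`` is the b-c-X angle; ``dihedral_deg`` the a-b-c-X
    torsion.  Standard NeRF construction.
    """
    a, b, c = (np.asarray(p, dtype=np.float64) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(bond_angle_deg)
    tor = np.radians(dihedral_deg)
    d = np.array([
        -bond_length * np.cos(ang),
        bond_length * np.sin(ang) * np.cos(tor),
        bond_length * np.sin(ang) * np.sin(tor),
    ])
    basis = np.stack([bc, m, n], axis=1)
    return c + basis @ d


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
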