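"""Independent brute-force oracles used to validate the optimised routines.

These deliberately avoid the code paths they check: superposition is an
exhaustive Euler-angle grid search (never the SVD route), the embedding
oracle a nested grid over unit-disk vectors, the alignment oracle an
enumeration of monotone mappings, and the one-hot decoder a plain Python
loop.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.transform import Rotation


def grid_superpose_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD of Q vs rotated P by multi-stage Euler-angle grid search."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    n = P.shape[0]
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    M = Pc.T @ Qc  # E(R) = SP + SQ - 2 tr(R M)
    const = float(np.sum(Pc ** 2) + np.sum(Qc ** 2))

    def eval_angles(alphas, betas, gammas):
        grid = np.array(list(itertools.product(alphas, betas, gammas)))
        Rs = Rotation.from_euler("zyz", grid, degrees=True).as_matrix()
        traces = np.einsum("kij,ji->k", Rs, M)
        E = const - 2.0 * traces
        k = int(np.argmin(E))
        return grid[k], float(E[k])

    step = 12.0
    center, best_E = eval_angles(np.arange(-180.0, 180.0, step),
                                 np.arange(0.0, 180.0 + step, step),
                                 np.arange(-180.0, 180.0, step))
    for _ in range(5):
        span = 2.0 * step
        step = step / 4.0
        center, best_E = eval_angles(
            center[0] + np.arange(-span, span + step / 2, step),
            center[1] + np.arange(-span, span + step / 2, step),
            center[2] + np.arange(-span, span + step / 2, step))
    return float(np.sqrt(max(best_E, 0.0) / n))


def grid_embed_residual_3(cc: np.ndarray) -> float:
    """Exhaustive unit-disk grid search of the 3-structure, d=2 embedding.

    Exploits rotation/reflection freedom: x1 = (r1, 0); x2 at angle
    theta in [0, pi]; x3 anywhere in the disk.  Three refinement stages.
    """
    c12, c13, c23 = cc[0, 1], cc[0, 2], cc[1, 2]

    def residual(r1, r2, th2, X3):
        x1 = np.array([r1, 0.0])
        x2 = np.array([r2 * np.cos(th2), r2 * np.sin(th2)])
        g12 = float(x1 @ x2)
        g13 = X3 @ x1
        g23 = X3 @ x2
        return (c12 - g12) ** 2 + (c13 - g13) ** 2 + (c23 - g23) ** 2

    def disk_grid(center, half, step):
        xs = np.arange(center[0] - half, center[0] + half + step / 2, step)
        ys = np.arange(center[1] - half, center[1] + half + step / 2, step)
        pts = np.array(list(itertools.product(xs, ys)))
        return pts[np.sum(pts ** 2, axis=1) <= 1.0 + 1e-12]

    best = (np.inf, None)
    r_grid = np.arange(0.0, 1.0 + 1e-9, 0.05)
    t_grid = np.arange(0.0, np.pi + 1e-9, np.pi / 36)
    X3 = disk_grid((0.0, 0.0), 1.0, 0.05)
    for r1 in r_grid:
        for r2 in r_grid:
            for th2 in t_grid:
                res = residual(r1, r2, th2, X3)
                k = int(np.argmin(res))
                if res[k] < best[0]:
                    best = (float(res[k]), (r1, r2, th2, X3[k]))
    for half, step in ((0.05, 0.005), (0.005, 0.001)):
        _, (r1c, r2c, th2c, x3c) = best
        X3 = disk_grid(x3c, half, step)
        for r1 in np.clip(r1c + np.arange(-half, half + step / 2, step), 0, 1):
            for r2 in np.clip(r2c + np.arange(-half, half + step / 2, step),
                              0, 1):
                for th2 in th2c + np.arange(-half, half + step / 2, step):
                    res = residual(r1, r2, th2, X3)
                    k = int(np.argmin(res))
                    if res[k] < best[0]:
                        best = (float(res[k]), (r1, r2, th2, X3[k]))
    return best[0]


def decode_onehot(onehot: np.ndarray) -> np.ndarray:
    """Plain-loop argmax decoding of a one-hot matrix."""
    out = []
    for row in onehot:
        best, best_v = 0, row[0]
        for j, v in enumerate(row):
            if v > best_v:
                best, best_v = j, v
        out.append(best)
    return np.array(out, dtype=np.int64)


def brute_force_alignment(query: str, template: str):
    """Best monotone full-template mapping by exhaustive enumeration.

    Scores candidate mappings by summed BLOSUM62 similarity over the pairs
    (every template residue mapped, in order); returns the argmax pair list.
    """
    from Bio.Align import substitution_matrices
    blosum = substitution_matrices.load("BLOSUM62")
    best = (-np.inf, None)
    for combo in itertools.combinations(range(len(query)), len(template)):
        score = sum(blosum[query[q], template[t]]
                    for t, q in enumerate(combo))
        if score > best[0]:
            best = (score, [(q, t) for t, q in enumerate(combo)])
    return best[1]


def a3m_row_reference(query: str, row: str):
    """Minimal independent A3M row decoder (match columns + insertions)."""
    order = "ARNDCQEGHILKMFPSTWYV"
    idx = {a: i for i, a in enumerate(order)}
    idx["X"] = 20
    out, dels = [], []
    pending = 0
    for ch in row:
        if ch.islower():
            pending += 1
        elif ch == "-":
            out.append(21)
            dels.append(pending)
            pending = 0
        else:
            out.append(idx[ch])
            dels.append(pending)
            pending = 0
    assert len(out) == len(query)
    return out, dels
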