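"""Ensemble analytics: structural correlation, state embedding, hinges.

Given an ensemble of structures sharing residues in a common frame, this
module computes

* an iterative mean-superposition frame (every member Kabsch-fitted onto the
  running mean until convergence),
* a pairwise structural correlation-coefficient (CC) matrix — the cosine
  between flattened deviation vectors from the ensemble mean,
* a low-dimensional embedding whose dot products reproduce the CC matrix
  (penalised least squares inside the unit ball, multi-start and seeded),
  with clustering of the embedded vectors by angular separation, and
* a rigid-group / hinge decomposition from pairwise difference-distance
  matrices, with per-group RMSD ranges.

The CC dialect of record is the deviation-vector cosine against the
iteratively superposed ensemble mean; it is deliberately explicit and
swappable behind the :class:`CCMatrix` contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from scipy.spatial.distance import squareform

from .geometry import apply_rigid, kabsch
from .structures import CA, StructureModel

MIN_COMMON = 10
_CONVERGENCE = 1e-6
_MAX_ITER = 50


@dataclass
class EnsembleFrame:
    """An ensemble superposed onto its converged mean over common CAs."""

    structures: list[StructureModel]
    common_keys: list[tuple[str, int]]       # (chain_id, residue_number)
    coords: np.ndarray                       # (n, |common|, 3) superposed CAs
    mean_coords: np.ndarray                  # (|common|, 3)
    n_iterations: int = 0

    @property
    def n_members(self) -> int:
        return self.coords.shape[0]

    @property
    def n_common(self) -> int:
        return self.coords.shape[1]


def _ca_lookup(s: StructureModel) -> dict[tuple[str, int], int]:
    out = {}
    for i in range(len(s)):
        if s.atom_mask[i, CA] > 0:
            out[(str(s.chain_ids[i]), int(s.residue_numbers[i]))] = i
    return out


def build_frame(structures: Sequence[StructureModel],
                selection: Optional[Sequence[tuple[str, int]]] = None
                ) -> EnsembleFrame:
    """Superpose an ensemble onto its iteratively recomputed mean.

    Residues are matched across members by (chain, author number); only
    positions with a CA in every member enter the common frame (>= 10
    required).  The first structure initialises the mean; iteration stops
    when the mean moves by less than 1e-6 A RMSD or after 50 rounds.
    """
    if len(structures) < 2:
        raise ValueError("need at least two structures")
    lookups = [_ca_lookup(s) for s in structures]
    keys = [k for k in lookups[0] if all(k in lk for lk in lookups[1:])]
    if selection is not None:
        wanted = set(selection)
        keys = [k for k in keys if k in wanted]
    if len(keys) < MIN_COMMON:
        raise ValueError(
            f"insufficient common CA positions ({len(keys)} < {MIN_COMMON})")
    coords = np.stack([
        np.array([s.atom_positions[lk[k], CA] for k in keys])
        for s, lk in zip(structures, lookups)
    ])
    mean = coords[0].copy()
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        fitted = np.empty_like(coords)
        for i in range(coords.shape[0]):
            R, t, _ = kabsch(coords[i], mean)
            fitted[i] = apply_rigid(coords[i], R, t)
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=-1))))
        coords = fitted
        mean = new_mean
        if shift < _CONVERGENCE:
            break
    return EnsembleFrame(structures=list(structures), common_keys=keys,
                         coords=coords, mean_coords=mean, n_iterations=n_iter)


@dataclass
class CCMatrix:
    """Pairwise structural correlation coefficients (symmetric, diagonal 1)."""

    values: np.ndarray
    degenerate: np.ndarray = None  # members identical to the mean, flagged

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path, labels: Optional[list[str]] = None) -> None:
        n = self.n
        labels = labels or [f"m{i}" for i in range(n)]
        with open(path, "w") as fh:
            fh.write("," + ",".join(labels) + "\n")
            for i in range(n):
                fh.write(labels[i] + "," +
                         ",".join(f"{self.values[i, j]:.6f}" for j in range(n))
                         + "\n")


def cc_matrix(frame: EnsembleFrame) -> CCMatrix:
    """Cosine of flattened deviation vectors from the ensemble mean.

    A member identical to the mean (zero deviation norm) has no direction:
    its row is set to 1 against other degenerate members and 0 elsewhere,
    and it is flagged in ``degenerate``.
    """
    n = frame.n_members
    dev = (frame.coords - frame.mean_coords[None]).reshape(n, -1)
    norms = np.linalg.norm(dev, axis=1)
    degenerate = norms < 1e-9
    cc = np.zeros((n, n))
    safe = np.where(degenerate, 1.0, norms)
    unit = dev / safe[:, None]
    cc = unit @ unit.T
    for i in np.nonzero(degenerate)[0]:
        cc[i, :] = 0.0
        cc[:, i] = 0.0
        cc[i, degenerate] = 1.0
        cc[degenerate, i] = 1.0
    np.fill_diagonal(cc, 1.0)
    cc = np.clip((cc + cc.T) / 2.0, -1.0, 1.0)
    return CCMatrix(values=cc, degenerate=degenerate)


@dataclass
class StateEmbedding:
    """Unit-ball vectors whose dot products approximate the CC matrix."""

    vectors: np.ndarray          # (n, d)
    residual: float              # sum_{i<j} (CC_ij - x_i . x_j)^2
    cluster_labels: np.ndarray   # contiguous ints from 0
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_labels.max()) + 1

    def to_csv(self, path, labels: Optional[list[str]] = None) -> None:
        n, d = self.vectors.shape
        labels = labels or [f"m{i}" for i in range(n)]
        with open(path, "w") as fh:
            fh.write("member," + ",".join(f"x{j}" for j in range(d))
                     + ",cluster\n")
            for i in range(n):
                fh.write(labels[i] + "," +
                         ",".join(f"{v:.6f}" for v in self.vectors[i]) +
                         f",{int(self.cluster_labels[i])}\n")


def _embed_residual(x: np.ndarray, cc: np.ndarray) -> float:
    g = x @ x.T
    iu = np.triu_indices(cc.shape[0], k=1)
    return float(np.sum((cc[iu] - g[iu]) ** 2))


def _objective(flat: np.ndarray, cc: np.ndarray, n: int, d: int,
               penalty: float):
    x = flat.reshape(n, d)
    g = x @ x.T
    diff = cc - g
    np.fill_diagonal(diff, 0.0)
    res = 0.5 * np.sum(diff ** 2)            # counts each pair twice / 2
    grad = -2.0 * diff @ x
    norms2 = np.sum(x * x, axis=1)
    over = np.maximum(norms2 - 1.0, 0.0)
    res += penalty * np.sum(over ** 2)
    grad += (4.0 * penalty * over)[:, None] * x
    return res, grad.ravel()


def embed(cc: CCMatrix, d: int = 2, seed: int = 0, k: Optional[int] = None,
          n_starts: int = 10) -> StateEmbedding:
    """Project structures into d dimensions reproducing the CC matrix.

    Minimises ``sum_{i<j} (CC_ij - x_i . x_j)^2`` with ``|x_i| <= 1`` by
    seeded multi-start local optimisation (one eigenvalue-based start plus
    random starts in the unit ball; best of ``n_starts``).  Systematic
    (state) differences separate vectors by angle, random noise shrinks their
    norms, so clustering is by angular separation: complete linkage on the
    pairwise angle, cut at ``k`` clusters or at the largest angular gap.
    """
    C = cc.values
    n = C.shape[0]
    rng = np.random.default_rng(seed)
    starts = []
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:d]
    eig_start = V[:, order] * np.sqrt(np.maximum(w[order], 0.0))[None, :]
    nrm = np.linalg.norm(eig_start, axis=1)
    eig_start[nrm > 1] /= nrm[nrm > 1][:, None]
    starts.append(eig_start)
    for _ in range(n_starts - 1):
        r = rng.normal(size=(n, d))
        r *= (rng.uniform(size=(n, 1)) ** (1.0 / d)) / \
            np.linalg.norm(r, axis=1, keepdims=True)
        starts.append(r)
    best_x, best_res = None, np.inf
    for s in starts:
        opt = minimize(_objective, s.ravel(), args=(C, n, d, 100.0),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": 500})
        x = opt.x.reshape(n, d)
        nrm = np.linalg.norm(x, axis=1)
        x[nrm > 1.0] /= nrm[nrm > 1.0][:, None]
        res = _embed_residual(x, C)
        if res < best_res - 1e-12:
            best_res, best_x = res, x
    labels = _angular_clusters(best_x, k)
    return StateEmbedding(vectors=best_x, residual=best_res,
                          cluster_labels=labels, seed=seed)


_MIN_SPLIT_ANGLE = 0.2  # rad; below this the ensemble is one state


def _angular_clusters(x: np.ndarray, k: Optional[int]) -> np.ndarray:
    n = x.shape[0]
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    norms = np.linalg.norm(x, axis=1)
    unit = x / np.where(norms < 1e-9, 1.0, norms)[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    ang = np.arccos(cos)
    ang[np.ix_(norms < 1e-9, np.arange(n))] = 0.0
    ang[np.ix_(np.arange(n), norms < 1e-9)] = 0.0
    np.fill_diagonal(ang, 0.0)
    ang = (ang + ang.T) / 2
    Z = linkage(squareform(ang, checks=False), method="complete")
    if k is not None:
        raw = fcluster(Z, t=k, criterion="maxclust")
    else:
        heights = Z[:, 2]
        if heights[-1] < _MIN_SPLIT_ANGLE:
            raw = np.ones(n, dtype=int)
        else:
            gaps = np.diff(np.concatenate([[0.0], heights]))
            cut_idx = int(np.argmax(gaps))
            n_clusters = n - cut_idx
            raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # renumber clusters by first appearance for determinism
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=np.int64)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap)
        out[i] = remap[c]
    return out


# --- Rigid groups / hinges --------------------------------------------------

@dataclass
class RigidDecomposition:
    """Contiguous rigid groups over the common positions, with hinges."""

    labels: np.ndarray                       # group index per common position
    hinge_boundaries: list[int]              # first common-position index of
                                             # each new group
    group_rmsd_range: dict[int, tuple[float, float]]
    common_keys: list[tuple[str, int]]

    @property
    def n_groups(self) -> int:
        return int(self.labels.max()) + 1


def _difference_distance(frame: EnsembleFrame) -> np.ndarray:
    """Max over member pairs of |d_ab(i) - d_ab(j)| for residues a, b."""
    n, m, _ = frame.coords.shape
    agg = np.zeros((m, m))
    dists = np.empty((n, m, m))
    for i in range(n):
        diff = frame.coords[i][:, None, :] - frame.coords[i][None, :, :]
        dists[i] = np.sqrt(np.sum(diff ** 2, axis=-1))
    for i in range(n):
        for j in range(i + 1, n):
            np.maximum(agg, np.abs(dists[i] - dists[j]), out=agg)
    return agg


_CORIGID_MERGE_FRACTION = 0.5


def hinges(frame: EnsembleFrame, tol: float = 1.5,
           min_segment: int = 5) -> RigidDecomposition:
    """Decompose the common frame into rigid groups separated by hinges.

    Residues a, b are co-rigid if their CA distance changes by at most
    ``tol`` (A) between every pair of members (max-aggregated
    difference-distance matrix).  The sequence is seeded with contiguous
    segments of at least ``min_segment`` residues which are agglomeratively
    merged while the co-rigid fraction between two groups exceeds 0.5 — the
    fraction criterion tolerates the noise tail that a strict diameter rule
    would amplify.  Boundaries between adjacent groups are then refined to
    residue resolution, and the hinge residues are those boundaries.
    """
    m = frame.n_common
    agg = _difference_distance(frame)
    R = agg <= tol
    n_seg = max(m // min_segment, 1)
    bounds = np.linspace(0, m, n_seg + 1).astype(int)
    segments = [np.arange(bounds[i], bounds[i + 1]) for i in range(n_seg)]
    groups: list[list[int]] = [[i] for i in range(n_seg)]

    def members(group: list[int]) -> np.ndarray:
        return np.concatenate([segments[s] for s in group])

    while len(groups) > 1:
        best = (-1.0, None)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                f = float(R[np.ix_(members(groups[gi]),
                                   members(groups[gj]))].mean())
                if f > best[0]:
                    best = (f, (gi, gj))
        if best[0] < _CORIGID_MERGE_FRACTION:
            break
        gi, gj = best[1]
        groups[gi] = groups[gi] + groups[gj]
        del groups[gj]

    labels = np.empty(m, dtype=np.int64)
    for g, group in enumerate(groups):
        for s in group:
            labels[segments[s]] = g
    labels = _renumber(labels)
    labels = _refine_boundaries(labels, R, min_segment)
    labels = _renumber(labels)
    boundaries = [int(i) for i in range(1, m) if labels[i] != labels[i - 1]]
    group_rmsd = _group_rmsd_ranges(frame, labels)
    return RigidDecomposition(labels=labels, hinge_boundaries=boundaries,
                              common_keys=frame.common_keys,
                              group_rmsd_range=group_rmsd)


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop_exclusive, label) runs along the sequence."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, int(labels[start])))
            start = i
    return runs


def _renumber(labels: np.ndarray) -> np.ndarray:
    out = np.empty_like(labels)
    remap: dict[int, int] = {}
    for start, stop, lab in _runs(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[start:stop] = remap[lab]
    return out


def _refine_boundaries(labels: np.ndarray, R: np.ndarray,
                       min_segment: int) -> np.ndarray:
    """Move each group boundary to the residue-level split that best matches
    per-residue co-rigid fractions with the flanking group cores."""
    labels = labels.copy()
    runs = _runs(labels)
    for k in range(len(runs) - 1):
        (ls, le, llab), (rs, re, rlab) = runs[k], runs[k + 1]
        if llab == rlab:
            continue
        zone_lo = max(ls, le - min_segment)
        zone_hi = min(re, rs + min_segment)
        zone = np.arange(zone_lo, zone_hi)
        core_left = np.arange(ls, zone_lo)
        core_right = np.arange(zone_hi, re)
        if core_left.size == 0 or core_right.size == 0 or zone.size == 0:
            continue
        f_left = R[np.ix_(zone, core_left)].mean(axis=1)
        f_right = R[np.ix_(zone, core_right)].mean(axis=1)
        scores = []
        for s in range(zone.size + 1):
            scores.append(float(f_left[:s].sum() + f_right[s:].sum()))
        split = int(np.argmax(scores))
        labels[zone[:split]] = llab
        labels[zone[split:]] = rlab
    return labels


def _group_rmsd_ranges(frame: EnsembleFrame, labels: np.ndarray
                       ) -> dict[int, tuple[float, float]]:
    out = {}
    for g in range(int(labels.max()) + 1):
        sel = labels == g
        if int(sel.sum()) < 3:
            out[g] = (0.0, 0.0)
            continue
        sub = frame.coords[:, sel, :]
        mean = sub.mean(axis=0)
        rmsds = []
        for i in range(sub.shape[0]):
            R, t, r = kabsch(sub[i], mean)
            rmsds.append(r)
        out[g] = (float(min(rmsds)), float(max(rmsds)))
    return out


# --- State classification ---------------------------------------------------

@dataclass
class StateReport:
    labels: list[Optional[str]]
    ambiguous: bool
    detail: dict


def classify_states(embedding: StateEmbedding,
                    reference_labels: Optional[dict[int, str]] = None
                    ) -> StateReport:
    """Assign state names to ensemble members from the embedding clusters.

    ``reference_labels`` maps member indices of known-state references (e.g.
    experimental inward/outward structures included in the ensemble) to state
    names; unlabeled members inherit their cluster's reference majority.  If
    one cluster contains references of conflicting states the report is
    flagged ambiguous and that cluster is left unassigned rather than guessed.
    """
    clusters = embedding.cluster_labels
    n = len(clusters)
    if not reference_labels:
        return StateReport(
            labels=[f"state_{int(c)}" for c in clusters],
            ambiguous=False,
            detail={"n_clusters": embedding.n_clusters, "references": 0},
        )
    ambiguous = False
    cluster_state: dict[int, Optional[str]] = {}
    for c in range(embedding.n_clusters):
        states = [reference_labels[i] for i in reference_labels
                  if clusters[i] == c]
        if not states:
            cluster_state[c] = None
        elif len(set(states)) > 1:
            cluster_state[c] = None
            ambiguous = True
        else:
            cluster_state[c] = states[0]
    labels: list[Optional[str]] = []
    for i in range(n):
        state = cluster_state[int(clusters[i])]
        labels.append(state if state is not None
                      else (None if ambiguous else f"state_{int(clusters[i])}"))
    return StateReport(labels=labels, ambiguous=ambiguous,
                       detail={"n_clusters": embedding.n_clusters,
                               "cluster_state": cluster_state,
                               "references": len(reference_labels)})


@dataclass
class StateAnalysis:
    """Bundle of the ensemble analytics for reporting."""

    frame: EnsembleFrame
    cc: CCMatrix
    embedding: StateEmbedding
    states: StateReport
    rigid: Optional[RigidDecomposition] = None

    def to_dict(self) -> dict:
        return {
            "n_members": self.frame.n_members,
            "n_common_positions": self.frame.n_common,
            "cc": self.cc.values.tolist(),
            "embedding": self.embedding.vectors.tolist(),
            "embedding_residual": self.embedding.residual,
            "cluster_labels": self.embedding.cluster_labels.tolist(),
            "state_labels": self.states.labels,
            "ambiguous": self.states.ambiguous,
            "rigid_groups": (self.rigid.labels.tolist()
                             if self.rigid is not None else None),
            "hinge_boundaries": (self.rigid.hinge_boundaries
                                 if self.rigid is not None else None),
        }


def analyze_ensemble(structures: Sequence[StructureModel], seed: int = 0,
                     k: Optional[int] = None,
                     reference_labels: Optional[dict[int, str]] = None,
                     hinge_tol: float = 1.5) -> StateAnalysis:
    """Full pipeline: frame, CC matrix, embedding, states, rigid groups."""
    frame = build_frame(structures)
    cc = cc_matrix(frame)
    emb = embed(cc, d=2, seed=seed, k=k)
    states = classify_states(emb, reference_labels)
    rigid = hinges(frame, tol=hinge_tol)
    return StateAnalysis(frame=frame, cc=cc, embedding=emb, states=states,
                         rigid=rigid)


def plot_embedding(embedding: StateEmbedding, path,
                   labels: Optional[list[str]] = None) -> None:
    """Scatter plot of the 2-D embedding coloured by cluster."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    x = embedding.vectors
    fig, ax = plt.subplots(figsize=(4, 4))
    for c in range(embedding.n_clusters):
        sel = embedding.cluster_labels == c
        ax.scatter(x[sel, 0], x[sel, 1], label=f"cluster {c}", s=30)
    circle = plt.Circle((0, 0), 1.0, fill=False, ls="--", color="grey")
    ax.add_patch(circle)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.legend(fontsize=7)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
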