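"""Pairwise-RMSD single-linkage clustering of trajectory frames.

Two frames land in the same cluster iff they are connected by a chain of
pairwise (Kabsch-aligned) RMSDs strictly below the cutoff — i.e. connected
components of the thresholded distance graph, which is what single linkage
reduces to at a fixed cutoff.  Cluster ids are ordered by decreasing
population (ties: lowest member frame index), and each cluster is summarised
by its medoid frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import kabsch_align, rmsd
from .md_model import Frame, Trajectory

__all__ = ["ClusterResult", "pairwise_rmsd_matrix", "single_linkage",
           "representative_frame"]


@dataclass
class ClusterResult:
    labels: np.ndarray            # per-frame cluster id
    populations: dict[int, int]   # id -> frame count
    representatives: dict[int, int]  # id -> frame index (medoid)
    cutoff: float


def pairwise_rmsd_matrix(trajectory: Trajectory, selection) -> np.ndarray:
    """Symmetric matrix of Kabsch-aligned RMSDs between all frame pairs.

    Each pair is superposed on ``selection`` and the RMSD measured on the
    same selection.
    """
    idx = list(selection)
    if len(idx) == 0:
        raise ValueError("selection is empty")
    n = trajectory.n_frames
    if n < 2:
        raise ValueError("need >= 2 frames")
    sub = [Frame(f.coordinates[np.asarray(idx)]) for f in trajectory]
    fit = list(range(len(idx)))
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aligned, _, _ = kabsch_align(sub[j], sub[i], fit)
            mat[i, j] = mat[j, i] = rmsd(aligned.coordinates, sub[i].coordinates)
    return mat


def single_linkage(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Cluster frames by connected components of distances strictly < cutoff."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if np.any(np.isnan(matrix)):
        raise ValueError("matrix contains NaN")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    n = matrix.shape[0]
    adj = (matrix < cutoff)
    np.fill_diagonal(adj, False)
    _, raw = connected_components(csr_matrix(adj), directed=False)
    # relabel: decreasing population, ties by lowest member frame index
    ids, counts = np.unique(raw, return_counts=True)
    first_member = {c: int(np.argmax(raw == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first_member[c]))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    populations = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
    return ClusterResult(labels=labels, populations=populations,
                         representatives={}, cutoff=float(cutoff))


def representative_frame(cluster_member_indices, matrix: np.ndarray) -> int:
    """Medoid of a cluster: the member minimising summed RMSD to the others.

    Ties break toward the lowest frame index; a singleton is its own medoid.
    """
    members = np.asarray(list(cluster_member_indices), dtype=int)
    if members.size == 0:
        raise ValueError("cluster has no members")
    if members.size == 1:
        return int(members[0])
    sub = np.asarray(matrix)[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    best = np.flatnonzero(sums == sums.min()).min()
    return int(members[best])


def cluster_trajectory(trajectory: Trajectory, selection, cutoff: float
                       ) -> tuple[ClusterResult, np.ndarray]:
    """Convenience: matrix + single linkage + medoid representatives."""
    mat = pairwise_rmsd_matrix(trajectory, selection)
    result = single_linkage(mat, cutoff)
    for cid in result.populations:
        members = np.flatnonzero(result.labels == cid)
        result.representatives[cid] = representative_frame(members, mat)
    return result, mat
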