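"""Greedy two-phase (Louvain-like) optimizer on a dense modularity matrix.

Both the single-layer and the multilayer quality functions can be written
as Q = (1/2mu) * sum_pq B_pq * delta(g_p, g_q) for a symmetric matrix B —
the modularity matrix A - gamma*k k^T/2m in the single-layer case, the
supra-modularity matrix (intra-layer modularity blocks plus interslice
couplings on node identities) in the multilayer case. The optimizer
therefore works on B directly: nodes move greedily to the community with
the largest positive quality gain (candidates scanned in a seed-randomized
order, first maximum wins), sweeps repeat until a full pass makes no move,
communities are aggregated, and the two phases repeat to convergence.
"""

from __future__ import annotations

import numpy as np

GAIN_TOL = 1e-10  # minimum quality-numerator gain that counts as a move


def canonicalize(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 0..K-1 by order of first appearance."""
    labels = np.asarray(labels)
    seen: dict = {}
    out = np.empty(labels.size, dtype=np.int64)
    for idx, lab in enumerate(labels.ravel()):
        if lab not in seen:
            seen[lab] = len(seen)
        out[idx] = seen[lab]
    return out.reshape(labels.shape)


def _local_moves(B: np.ndarray, comm: np.ndarray,
                 rng: np.random.Generator) -> bool:
    """Sweep nodes in random order until a full pass makes no move.

    Returns True if any move was made. ``comm`` is modified in place and
    may contain empty labels afterwards.
    """
    n = B.shape[0]
    improved = False
    moved_in_pass = True
    while moved_in_pass:
        moved_in_pass = False
        for i in rng.permutation(n):
            w = B[i]
            n_comm = int(comm.max()) + 1
            links = np.bincount(comm, weights=w, minlength=n_comm)
            links[comm[i]] -= w[i]  # self-weight moves with the node
            # gain of moving i from its community to c: 2*(links[c]-links[cur])
            order = rng.permutation(n_comm)
            best = order[int(np.argmax(links[order]))]
            if best != comm[i] and links[best] - links[comm[i]] > GAIN_TOL / 2:
                comm[i] = best
                improved = moved_in_pass = True
    return improved


def _aggregate(B: np.ndarray, comm: np.ndarray) -> np.ndarray:
    """Collapse communities into super-nodes: B'_ab = sum_{i in a, j in b} B_ij."""
    k = int(comm.max()) + 1
    ind = np.zeros((B.shape[0], k))
    ind[np.arange(B.shape[0]), comm] = 1.0
    return ind.T @ B @ ind


def _multilevel(B: np.ndarray, start: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """One full Louvain cycle from an initial assignment: node-level moves,
    then repeated aggregation + super-node moves until no improvement."""
    comm = start.copy()
    _local_moves(B, comm, rng)
    membership = canonicalize(comm)
    level = _aggregate(B, membership)
    while level.shape[0] > 1:
        comm = np.arange(level.shape[0])
        improved = _local_moves(level, comm, rng)
        if not improved:
            break
        comm = canonicalize(comm)
        membership = comm[membership]
        level = _aggregate(level, comm)
    return canonicalize(membership)


def greedy_modularity(B: np.ndarray, seed: int,
                      start: np.ndarray | None = None) -> tuple:
    """Maximize sum_pq B_pq delta(g_p,g_q) greedily; return (labels, raw Q).

    Louvain cycles (sweep, aggregate, repeat) alternate with node-level
    refinement of the coarse solution until a full cycle yields no gain —
    nodes merged early can still leave their community individually. The
    raw quality includes the diagonal of B (constant across partitions);
    callers divide by 2*mu for the normalized score.
    """
    B = np.asarray(B, dtype=float)
    n = B.shape[0]
    if B.shape != (n, n):
        raise ValueError("B must be square")
    rng = np.random.default_rng(int(seed))
    best_labels = np.arange(n) if start is None else canonicalize(start)
    best_raw = quality_numerator(B, best_labels)
    while True:
        labels = _multilevel(B, best_labels, rng)
        raw = quality_numerator(B, labels)
        if raw <= best_raw + GAIN_TOL:
            break
        best_labels, best_raw = labels, raw
    return best_labels, best_raw


def quality_numerator(B: np.ndarray, labels: np.ndarray) -> float:
    """sum_pq B_pq delta(g_p, g_q), diagonal included."""
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        total += float(B[np.ix_(idx, idx)].sum())
    return total
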