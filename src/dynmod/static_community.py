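"""Single-layer modularity maximization and null-model normalization.

Whole-brain segregation is quantified by Newman-Girvan modularity
Q = (1/2mu) * sum_ij (A_ij - gamma * k_i k_j / 2m) * delta(g_i, g_j)
optimized with a Louvain-like greedy algorithm, best of many seeded
restarts. Because Q depends on the total connection strength, observed
values are normalized by the mean Q of degree-preserving rewired null
networks (Maslov-Sneppen double-edge swaps with weights riding on the
swapped edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from ._louvain import canonicalize, greedy_modularity, quality_numerator
from ._seeds import derive_seeds

__all__ = [
    "ModularityResult",
    "LouvainCommunities",
    "modularity_score",
    "louvain",
    "best_of_runs",
    "rewire_null",
    "normalized_modularity",
]


def _validate_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative (rectify first)")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have zero diagonal")
    if A.sum() <= 0:
        raise ValueError("empty graph: total weight is zero")
    return A


def _modularity_matrix(A: np.ndarray, gamma: float) -> np.ndarray:
    k = A.sum(axis=1)
    two_m = k.sum()
    return A - gamma * np.outer(k, k) / two_m


def modularity_score(A: np.ndarray, partition, gamma: float = 1.0) -> float:
    """Q of a given partition under the configuration null model.

    The double sum runs over all ordered pairs including i = j, so the
    all-in-one partition scores exactly 0 at gamma = 1.
    """
    A = _validate_adjacency(A)
    labels = canonicalize(np.asarray(partition))
    if labels.size != A.shape[0]:
        raise ValueError("partition must assign every node")
    B = _modularity_matrix(A, gamma)
    return quality_numerator(B, labels) / A.sum()


@dataclass(frozen=True)
class ModularityResult:
    """Best partition with raw and null-normalized modularity."""

    partition: np.ndarray
    Q: float
    Q_normalized: float | None
    n_runs: int
    n_null: int
    gamma: float
    seed: int

    @property
    def n_modules(self) -> int:
        return int(self.partition.max()) + 1


class LouvainCommunities(ClusterMixin, BaseEstimator):
    """Louvain-like community detection, best of ``n_runs`` restarts.

    Parameters
    ----------
    gamma : float, default 1.0
        Structural resolution; larger values favor smaller modules.
    n_runs : int, default 100
        Independent seeded restarts; the partition with the highest Q wins
        (ties broken by lowest run index).
    n_null : int, default 0
        If positive, Q is additionally normalized by the mean Q of this
        many rewired null networks, each scored with the same ``n_runs``
        protocol.
    swaps_per_edge : int, default 10
        Double-edge swap attempts per edge when building null networks.
    random_state : int, default 0
        Master seed; all restarts and nulls derive from it.

    Attributes
    ----------
    labels_ : ndarray
        Module label per node, canonicalized by first appearance.
    modularity_ : float
        Q of the best partition.
    normalized_modularity_ : float or None
        Q / mean(null Q), set when ``n_null > 0``.
    null_modularities_ : ndarray or None
        The null distribution of Q values.
    """

    def __init__(self, gamma: float = 1.0, n_runs: int = 100,
                 n_null: int = 0, swaps_per_edge: int = 10,
                 random_state: int = 0):
        self.gamma = gamma
        self.n_runs = n_runs
        self.n_null = n_null
        self.swaps_per_edge = swaps_per_edge
        self.random_state = random_state

    def fit(self, X, y=None, null_matrices=None):
        """Detect communities on a symmetric nonnegative adjacency ``X``.

        ``null_matrices`` optionally supplies explicit null networks in
        place of random rewirings (used for controlled normalization).
        """
        A = _validate_adjacency(X)
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        B = _modularity_matrix(A, self.gamma)
        two_mu = A.sum()

        run_seeds = derive_seeds(self.random_state, self.n_runs)
        n = A.shape[0]
        best_raw, best_labels = -np.inf, None
        for r, s in enumerate(run_seeds):
            # odd restarts begin from a random partition: single-node moves
            # from singletons share one basin on some graphs, and diverse
            # starts let the restart protocol escape it
            start = None
            if r % 2:
                rng = np.random.default_rng(int(s))
                start = rng.integers(0, int(rng.integers(1, n + 1)), n)
            labels, raw = greedy_modularity(B, int(s), start=start)
            if raw > best_raw + 1e-15:
                best_raw, best_labels = raw, labels
        self.labels_ = best_labels
        self.modularity_ = best_raw / two_mu

        self.normalized_modularity_ = None
        self.null_modularities_ = None
        if null_matrices is None and self.n_null > 0:
            null_seeds = derive_seeds(self.random_state + 1, self.n_null)
            null_matrices = [rewire_null(A, int(s), self.swaps_per_edge)
                             for s in null_seeds]
        if null_matrices is not None:
            null_qs = []
            for j, N in enumerate(null_matrices):
                sub = LouvainCommunities(
                    gamma=self.gamma, n_runs=self.n_runs,
                    random_state=int(derive_seeds(self.random_state + 2,
                                                  j + 1)[-1]))
                sub.fit(N)
                null_qs.append(sub.modularity_)
            self.null_modularities_ = np.asarray(null_qs)
            mean_null = float(self.null_modularities_.mean())
            if mean_null == 0:
                raise ValueError("null modularity mean is zero; "
                                 "cannot normalize")
            self.normalized_modularity_ = self.modularity_ / mean_null
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).labels_

    def result_(self) -> ModularityResult:
        return ModularityResult(
            partition=self.labels_, Q=self.modularity_,
            Q_normalized=self.normalized_modularity_,
            n_runs=self.n_runs, n_null=self.n_null, gamma=self.gamma,
            seed=self.random_state)


def louvain(A, gamma: float = 1.0, seed: int = 0):
    """One greedy optimization; returns (partition labels, Q)."""
    A = _validate_adjacency(A)
    B = _modularity_matrix(A, gamma)
    labels, raw = greedy_modularity(B, seed)
    return labels, raw / A.sum()


def best_of_runs(A, gamma: float = 1.0, n_runs: int = 100,
                 seed: int = 0) -> ModularityResult:
    """Best partition over ``n_runs`` seeded restarts."""
    est = LouvainCommunities(gamma=gamma, n_runs=n_runs,
                             random_state=seed).fit(A)
    return est.result_()


def rewire_null(A, seed: int = 0, swaps_per_edge: int = 10) -> np.ndarray:
    """Degree-preserving rewiring with edge weights riding on the edges.

    Maslov-Sneppen double-edge swaps on the nonzero-edge topology: pick
    edges (u,v) and (x,y), rewire to (u,x) and (v,y) when that creates no
    self-loop or duplicate edge. The unweighted degree sequence, the total
    weight and the multiset of edge weights are preserved exactly. Graphs
    too dense to swap (no valid swap found) fall back, with a warning, to
    shuffling the weights over the fixed topology.
    """
    A = _validate_adjacency(A)
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    present = A[iu] > 0
    edges = list(zip(iu[0][present], iu[1][present]))
    weights = list(A[iu][present])
    rng = np.random.default_rng(int(seed))
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")

    edge_set = {frozenset(e) for e in edges}
    target = swaps_per_edge * n_edges
    max_attempts = 100 * target
    done = attempts = 0
    # draw candidate pairs and orientation flips in batches: the swap loop
    # itself is cheap, the per-call RNG overhead is not
    batch = max(1024, 4 * n_edges)
    pair_buf = flip_buf = None
    buf_pos = batch
    while done < target and attempts < max_attempts:
        if buf_pos >= batch:
            pair_buf = rng.integers(0, n_edges, size=(batch, 2))
            flip_buf = rng.random(batch) < 0.5
            buf_pos = 0
        e1, e2 = pair_buf[buf_pos]
        flip = flip_buf[buf_pos]
        buf_pos += 1
        attempts += 1
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flip:
            x, y = y, x
        # propose (u,x) and (v,y)
        if u == x or v == y:
            continue
        new1, new2 = frozenset((u, x)), frozenset((v, y))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((u, v)))
        edge_set.discard(frozenset((x, y)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = (u, x)
        edges[e2] = (v, y)
        done += 1

    out = np.zeros_like(A)
    if done == 0:
        warnings.warn("graph too dense/small to swap; shuffling weights "
                      "over the fixed topology instead", stacklevel=2)
        perm = rng.permutation(n_edges)
        for (u, v), w in zip(edges, [weights[p] for p in perm]):
            out[u, v] = out[v, u] = w
        return out
    for (u, v), w in zip(edges, weights):
        out[u, v] = out[v, u] = w
    return out


def normalized_modularity(A, gamma: float = 1.0, n_runs: int = 100,
                          n_null: int = 100, seed: int = 0,
                          swaps_per_edge: int = 10,
                          null_matrices=None) -> ModularityResult:
    """Q of the best partition divided by the mean Q of rewired nulls."""
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    est = LouvainCommunities(gamma=gamma, n_runs=n_runs, n_null=n_null,
                             swaps_per_edge=swaps_per_edge,
                             random_state=seed)
    est.fit(A, null_matrices=null_matrices)
    return est.result_()
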