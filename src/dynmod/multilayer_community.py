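"""Multilayer modularity maximization across task-block layers.

Per-block connectivity matrices are stacked as layers of a categorical
multilayer network: every node is linked to itself in every other layer
with coupling omega, chosen by condition match (omega = 1 between blocks
of the same task condition, 0.5 between different conditions, reflecting
an alternating block design where same-condition blocks are never
adjacent). The quality function generalizes Newman-Girvan modularity with
a per-slice configuration null:

    Q_ML = (1/2mu) sum_ijsr [(A_ijs - gamma_s k_is k_js / 2m_s) delta_sr
                             + delta_ij omega_sr] delta(g_is, g_jr)

and is optimized by a generalized Louvain-like greedy algorithm on the
supra-modularity matrix whose nodes are (node, layer) pairs. Interslice
couplings enter as +omega only — they carry no configuration-null penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._louvain import canonicalize, greedy_modularity
from ._seeds import derive_seeds
from .connectivity import BlockStack
from .static_community import _modularity_matrix, _validate_adjacency

__all__ = [
    "MultilayerNetwork",
    "MultilayerPartition",
    "MultilayerCommunities",
    "omega_for_pair",
    "multilayer_quality",
    "generalized_louvain",
    "run_ensemble",
]


def omega_for_pair(cond_s, cond_r, omega_same: float = 1.0,
                   omega_diff: float = 0.5, known_labels=None) -> float:
    """Interslice coupling for a layer pair: ``omega_same`` when both
    layers share a condition label, ``omega_diff`` otherwise."""
    if known_labels is not None:
        for c in (cond_s, cond_r):
            if c not in known_labels:
                raise ValueError(f"unknown condition label: {c!r}")
    if omega_same < 0 or omega_diff < 0:
        raise ValueError("couplings must be nonnegative")
    return omega_same if cond_s == cond_r else omega_diff


@dataclass
class MultilayerNetwork:
    """Node-aligned stack of connectivity layers with condition labels."""

    layers: np.ndarray  # T x N x N
    layer_conditions: list
    gamma: float = 1.0
    omega_same: float = 1.0
    omega_diff: float = 0.5

    def __post_init__(self):
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("layers must be a T x N x N stack")
        if len(self.layer_conditions) != self.n_layers:
            raise ValueError("one condition label per layer required")
        for t in range(self.n_layers):
            _validate_adjacency(self.layers[t])
        if self.omega_same < 0 or self.omega_diff < 0:
            raise ValueError("couplings must be nonnegative")

    @classmethod
    def from_stack(cls, stack: BlockStack, gamma: float = 1.0,
                   omega_same: float = 1.0, omega_diff: float = 0.5
                   ) -> "MultilayerNetwork":
        return cls(layers=stack.weights, layer_conditions=list(
            stack.conditions), gamma=gamma, omega_same=omega_same,
            omega_diff=omega_diff)

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]

    def omega(self, s: int, r: int) -> float:
        if s == r:
            return 0.0
        return omega_for_pair(self.layer_conditions[s],
                              self.layer_conditions[r],
                              self.omega_same, self.omega_diff)

    def coupling_matrix(self) -> np.ndarray:
        """T x T matrix of pairwise interslice couplings (zero diagonal)."""
        T = self.n_layers
        W = np.zeros((T, T))
        for s in range(T):
            for r in range(T):
                W[s, r] = self.omega(s, r)
        return W

    def two_mu(self) -> float:
        """2mu = sum over nodes and layers of (intra-layer strength +
        summed interslice coupling)."""
        intra = sum(self.layers[t].sum() for t in range(self.n_layers))
        coupling = self.n_nodes * self.coupling_matrix().sum()
        return float(intra + coupling)

    def supra_modularity_matrix(self) -> np.ndarray:
        """(N*T) x (N*T) matrix B with intra-layer modularity blocks on the
        diagonal and omega couplings on node identities off the diagonal;
        supra index = s * N + i."""
        N, T = self.n_nodes, self.n_layers
        B = np.zeros((N * T, N * T))
        for s in range(T):
            B[s * N:(s + 1) * N, s * N:(s + 1) * N] = _modularity_matrix(
                self.layers[s], self.gamma)
        W = self.coupling_matrix()
        eye = np.eye(N)
        for s in range(T):
            for r in range(T):
                if s != r and W[s, r]:
                    B[s * N:(s + 1) * N, r * N:(r + 1) * N] = W[s, r] * eye
        return B


@dataclass(frozen=True)
class MultilayerPartition:
    """Node x layer module assignment with its quality."""

    assignment: np.ndarray  # N x T integer labels, global across layers
    quality: float
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_layers(self) -> int:
        return self.assignment.shape[1]


def multilayer_quality(network: MultilayerNetwork,
                       assignment: np.ndarray) -> float:
    """Q_ML of a given node x layer assignment, computed directly from the
    quality function (per-layer modularity terms plus coupling terms)."""
    g = np.asarray(assignment)
    N, T = network.n_nodes, network.n_layers
    if g.shape != (N, T):
        raise ValueError("assignment must be n_nodes x n_layers")
    two_mu = network.two_mu()
    if two_mu <= 0:
        raise ValueError("zero total weight")
    total = 0.0
    for s in range(T):
        B_s = _modularity_matrix(network.layers[s], network.gamma)
        same = g[:, s][:, None] == g[:, s][None, :]
        total += float(B_s[same].sum())
    W = network.coupling_matrix()
    for s in range(T):
        for r in range(T):
            if s != r and W[s, r]:
                total += W[s, r] * float(np.count_nonzero(g[:, s] == g[:, r]))
    return total / two_mu


def _decoupled_optimize(network: MultilayerNetwork,
                        seed: int) -> np.ndarray:
    # omega = 0 factorizes the problem into independent per-layer runs
    from .static_community import louvain

    N, T = network.n_nodes, network.n_layers
    g = np.empty((N, T), dtype=np.int64)
    offset = 0
    for t, s in enumerate(derive_seeds(seed, T)):
        labels, _ = louvain(network.layers[t], network.gamma, int(s))
        g[:, t] = labels + offset
        offset = int(g[:, t].max()) + 1
    return g


def _conditionwise_start(network: MultilayerNetwork,
                         seed: int) -> np.ndarray:
    """Warm start from partitions of the condition-mean matrices.

    Same-condition layers are averaged (reducing per-block estimation
    noise) and partitioned independently; every layer starts from its
    condition's partition. This coordinates the initial labels across
    same-condition layers, which greedy single-node moves cannot do on
    their own once interslice coupling is strong.
    """
    from .static_community import louvain

    N, T = network.n_nodes, network.n_layers
    conds = list(dict.fromkeys(network.layer_conditions))
    start = np.empty(N * T, dtype=np.int64)
    offset = 0
    for cond, child in zip(conds, derive_seeds(seed, len(conds))):
        idx = [t for t in range(T)
               if network.layer_conditions[t] == cond]
        mean_A = network.layers[idx].mean(axis=0)
        labels, _ = louvain(mean_A, network.gamma, int(child))
        for t in idx:
            start[t * N:(t + 1) * N] = labels + offset
        offset = int(labels.max()) + 1 + offset
    return start


def generalized_louvain(network: MultilayerNetwork, seed: int = 0,
                        init: str = "singleton") -> MultilayerPartition:
    """One greedy optimization of Q_ML on the supra-graph.

    ``init`` selects the starting assignment: ``"singleton"`` (every
    (node, layer) its own module) or ``"conditionwise"`` (warm start from
    condition-mean partitions; see :func:`_conditionwise_start`). Module
    labels are global across layers; the returned quality equals
    :func:`multilayer_quality` of the assignment.
    """
    N, T = network.n_nodes, network.n_layers
    if network.omega_same == 0 and network.omega_diff == 0:
        g = _decoupled_optimize(network, seed)
    else:
        B = network.supra_modularity_matrix()
        if init == "singleton":
            start = None
        elif init == "conditionwise":
            start = _conditionwise_start(network, seed)
        else:
            raise ValueError(f"unknown init {init!r}")
        labels, _ = greedy_modularity(B, seed, start=start)
        g = labels.reshape(T, N).T
    g = canonicalize(g)
    return MultilayerPartition(assignment=g,
                               quality=multilayer_quality(network, g),
                               seed=int(seed))


def run_ensemble(network: MultilayerNetwork, n_opt: int = 100,
                 seed: int = 0) -> list:
    """``n_opt`` independent optimizations (all retained, for allegiance).

    Starting assignments alternate between singleton and condition-wise
    warm starts so the ensemble samples both optimization basins; each
    member's quality is evaluated exactly either way.
    """
    if n_opt < 1:
        raise ValueError("n_opt must be >= 1")
    inits = ("singleton", "conditionwise")
    return [generalized_louvain(network, int(s), init=inits[o % 2])
            for o, s in enumerate(derive_seeds(seed, n_opt))]


class MultilayerCommunities:
    """Generalized Louvain over task-block layers, sklearn-style.

    Parameters mirror the quality function: ``gamma`` (per-slice
    resolution), ``omega_same``/``omega_diff`` (condition-dependent
    interslice coupling), ``n_optimizations`` (ensemble size) and
    ``random_state`` (master seed).

    Attributes
    ----------
    ensemble_ : list of MultilayerPartition
        All retained optimizations.
    assignment_ : ndarray
        Node x layer labels of the highest-quality optimization.
    quality_ : float
        Its Q_ML.
    """

    def __init__(self, gamma: float = 1.0, omega_same: float = 1.0,
                 omega_diff: float = 0.5, n_optimizations: int = 100,
                 random_state: int = 0):
        self.gamma = gamma
        self.omega_same = omega_same
        self.omega_diff = omega_diff
        self.n_optimizations = n_optimizations
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"gamma": self.gamma, "omega_same": self.omega_same,
                "omega_diff": self.omega_diff,
                "n_optimizations": self.n_optimizations,
                "random_state": self.random_state}

    def set_params(self, **params):
        for key, val in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    def _as_network(self, X) -> MultilayerNetwork:
        if isinstance(X, MultilayerNetwork):
            return X
        if isinstance(X, BlockStack):
            return MultilayerNetwork.from_stack(
                X, gamma=self.gamma, omega_same=self.omega_same,
                omega_diff=self.omega_diff)
        raise TypeError("X must be a MultilayerNetwork or BlockStack")

    def fit(self, X, y=None):
        network = self._as_network(X)
        self.network_ = network
        self.ensemble_ = run_ensemble(network, self.n_optimizations,
                                      self.random_state)
        best = max(range(len(self.ensemble_)),
                   key=lambda i: self.ensemble_[i].quality)
        self.assignment_ = self.ensemble_[best].assignment
        self.quality_ = self.ensemble_[best].quality
        self.qualities_ = np.array([p.quality for p in self.ensemble_])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).assignment_
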