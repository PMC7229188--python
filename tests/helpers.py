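"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: exhaustive
enumeration over all set partitions, and direct brute-force evaluation of
the multilayer quality sum.
"""

import numpy as np


def set_partitions(n: int):
    """Yield every partition of range(n) as a label array (restricted
    growth strings)."""
    labels = np.zeros(n, dtype=np.int64)

    def rec(i: int, max_label: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0) if n > 1 else iter([labels.copy()])


def exhaustive_modularity_max(A: np.ndarray, gamma: float = 1.0) -> float:
    """Global maximum of Newman-Girvan modularity by enumeration."""
    k = A.sum(axis=1)
    two_m = k.sum()
    B = A - gamma * np.outer(k, k) / two_m
    best = -np.inf
    for labels in set_partitions(A.shape[0]):
        q = 0.0
        for lab in np.unique(labels):
            idx = labels == lab
            q += B[np.ix_(idx, idx)].sum()
        best = max(best, q / two_m)
    return best


def brute_force_multilayer_quality(layers, conditions, assignment,
                                   gamma=1.0, omega_same=1.0,
                                   omega_diff=0.5) -> float:
    """Direct summation of the multilayer quality over all i, j, s, r."""
    layers = np.asarray(layers, float)
    g = np.asarray(assignment)
    T, N = layers.shape[0], layers.shape[1]

    def omega(s, r):
        if s == r:
            return 0.0
        return omega_same if conditions[s] == conditions[r] else omega_diff

    total = 0.0
    for s in range(T):
        A = layers[s]
        k = A.sum(axis=1)
        two_m = k.sum()
        for r in range(T):
            for i in range(N):
                for j in range(N):
                    if g[i, s] != g[j, r]:
                        continue
                    if s == r:
                        total += A[i, j] - gamma * k[i] * k[j] / two_m
                    if i == j:
                        total += omega(s, r)
    two_mu = 0.0
    for s in range(T):
        k = layers[s].sum(axis=1)
        c = sum(omega(s, r) for r in range(T))
        two_mu += float(k.sum()) + N * c
    return total / two_mu
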