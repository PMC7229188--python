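"""Module-allegiance cartography: recruitment and integration of
large-scale systems.

An ensemble of multilayer partitions is summarized by the allegiance
matrix P, where P_ij is the fraction of (optimization x layer) instances
in which nodes i and j share a module. Given an atlas of predefined
systems, recruitment R_S averages P within a system (stability of its
modular membership) and integration I_kl averages P between two systems
(how often they merge). Because both are biased by system size, observed
coefficients are divided by their mean over a permutation null in which
the ROI -> system labeling is shuffled (system sizes preserved).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .synthgen import SystemAtlas

__all__ = [
    "AllegianceMatrix",
    "CartographyResult",
    "allegiance",
    "recruitment",
    "integration",
    "permutation_normalize",
]


@dataclass(frozen=True)
class AllegianceMatrix:
    """Node x node co-assignment probabilities from an ensemble."""

    P: np.ndarray
    n_optimizations: int
    n_layers: int

    def __post_init__(self):
        P = self.P
        if not np.allclose(P, P.T):
            raise ValueError("allegiance must be symmetric")
        if P.min() < 0 or P.max() > 1:
            raise ValueError("allegiance entries must lie in [0, 1]")


def allegiance(ensemble) -> AllegianceMatrix:
    """P_ij = fraction of (optimization, layer) pairs co-assigning i and j."""
    if not ensemble:
        raise ValueError("empty ensemble")
    N, T = ensemble[0].n_nodes, ensemble[0].n_layers
    P = np.zeros((N, N))
    for part in ensemble:
        g = part.assignment
        if g.shape != (N, T):
            raise ValueError("inconsistent dimensions across ensemble")
        for t in range(T):
            col = g[:, t]
            P += col[:, None] == col[None, :]
    P /= len(ensemble) * T
    np.fill_diagonal(P, 1.0)  # a node always shares its own module
    return AllegianceMatrix(P=P, n_optimizations=len(ensemble), n_layers=T)


def _as_P(P) -> np.ndarray:
    if isinstance(P, AllegianceMatrix):
        return P.P
    return np.asarray(P, dtype=float)


def _membership(atlas: SystemAtlas) -> tuple:
    systems = atlas.systems
    labels = np.asarray(atlas.labels, dtype=object)
    M = np.zeros((len(labels), len(systems)))
    for k, s in enumerate(systems):
        M[labels == s, k] = 1.0
    return M, list(systems)


def _coefficients(P: np.ndarray, M: np.ndarray) -> tuple:
    """System-block sums of P -> (recruitment vector, integration matrix)."""
    sizes = M.sum(axis=0)
    S = M.T @ P @ M
    R = np.diag(S) / sizes ** 2
    I = S / np.outer(sizes, sizes)
    return R, I


def recruitment(P, atlas: SystemAtlas, system) -> float:
    """R_S: mean allegiance over all ordered pairs within ``system``
    (diagonal terms included)."""
    P = _as_P(P)
    idx = atlas.members(system)
    return float(P[np.ix_(idx, idx)].mean())


def integration(P, atlas: SystemAtlas, system_k, system_l) -> float:
    """I_kl: mean allegiance over pairs spanning two distinct systems."""
    if system_k == system_l:
        raise ValueError("integration needs two distinct systems; "
                         "use recruitment for a single system")
    P = _as_P(P)
    return float(P[np.ix_(atlas.members(system_k),
                          atlas.members(system_l))].mean())


@dataclass(frozen=True)
class CartographyResult:
    """Raw and permutation-normalized recruitment/integration."""

    table: pd.DataFrame  # measure, system(s), raw, normalized
    n_perm: int
    seed: int

    def value(self, measure: str, *systems, column: str = "normalized"
              ) -> float:
        key = "|".join(str(s) for s in sorted(systems, key=str))
        sel = self.table[(self.table["measure"] == measure)
                         & (self.table["systems"] == key)]
        if len(sel) != 1:
            raise KeyError(f"no unique entry for {measure} {key}")
        return float(sel[column].iloc[0])


def permutation_normalize(P, atlas: SystemAtlas, n_perm: int = 1000,
                          seed: int = 0, permutations=None
                          ) -> CartographyResult:
    """Normalize recruitment/integration by their permutation-null means.

    Each permutation shuffles the whole ROI -> system label vector (system
    sizes preserved) and recomputes every coefficient; the null mean
    captures what system size alone would produce. ``permutations`` may
    supply explicit index arrays (overriding random generation), e.g. the
    identity permutation for degenerate-null checks.
    """
    P = _as_P(P)
    M, systems = _membership(atlas)
    R_obs, I_obs = _coefficients(P, M)

    if permutations is None:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(int(seed))
        permutations = [rng.permutation(P.shape[0]) for _ in range(n_perm)]
    permutations = list(permutations)

    R_null = np.zeros_like(R_obs)
    I_null = np.zeros_like(I_obs)
    for perm in permutations:
        Rp, Ip = _coefficients(P, M[np.asarray(perm)])
        R_null += Rp
        I_null += Ip
    R_null /= len(permutations)
    I_null /= len(permutations)
    if np.any(R_null == 0) or np.any(
            I_null[~np.eye(len(systems), dtype=bool)] == 0):
        raise ValueError("zero null mean; cannot normalize")

    rows = []
    for k, s in enumerate(systems):
        rows.append({"measure": "recruitment", "systems": str(s),
                     "raw": R_obs[k], "normalized": R_obs[k] / R_null[k]})
    for k, l in combinations(range(len(systems)), 2):
        key = "|".join(str(s) for s in sorted(
            (systems[k], systems[l]), key=str))
        rows.append({"measure": "integration", "systems": key,
                     "raw": I_obs[k, l],
                     "normalized": I_obs[k, l] / I_null[k, l]})
    return CartographyResult(table=pd.DataFrame(rows),
                             n_perm=len(permutations), seed=int(seed))
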