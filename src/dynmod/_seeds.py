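"""Deterministic derivation of child seeds from a master seed.

Every stochastic stage (Louvain restarts, null rewirings, ensemble
optimizations, permutation nulls, per-block simulation streams) draws its
own child seed from a master seed by counter, so a single integer
reproduces the whole analysis.
"""

from __future__ import annotations

import numpy as np

_MASK31 = (1 << 31) - 1  # keep derived seeds in signed-int32 range


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """Return ``n`` child seeds deterministically derived from ``seed``.

    Children are independent streams (numpy SeedSequence counters) folded
    into [0, 2**31); identical (seed, n) always yields identical children.
    """
    if n < 1:
        raise ValueError("need at least one child seed")
    ss = np.random.SeedSequence(int(seed))
    return ss.generate_state(int(n)).astype(np.int64) & _MASK31
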