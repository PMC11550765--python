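"""Independent brute-force oracles, kept free of the production code paths.

These re-derive the observed-profile contact sum and the Kullback-Leibler
divergence with explicit Python double loops so the vectorized production
implementations can be checked against them.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_levitt_weight(r: float, cutoff: float) -> float:
    if r > cutoff:
        return 0.0
    t = r / cutoff
    return 1.0 - 0.5 * (7.0 * t**2 - 9.0 * t**4 + 5.0 * t**6 - t**8)


def oracle_observed(
    positions: np.ndarray,
    h: np.ndarray,
    cutoff: float = 9.0,
    include_self: bool = True,
) -> np.ndarray:
    """Double-loop observed profile, normalized to unit sum."""
    n = len(h)
    raw = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j and not include_self:
                continue
            r = math.dist(positions[i], positions[j])
            if r <= cutoff:
                raw[i] += (h[i] + h[j]) * oracle_levitt_weight(r, cutoff)
    return raw / raw.sum()


def oracle_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Loop-based D_KL(p|q) in bits with the 0 log 0 = 0 convention."""
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0.0:
            total += pi * math.log2(pi / qi)
    return total
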