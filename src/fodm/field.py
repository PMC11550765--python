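"""The environment-modified (FOD-M) expected distribution and the K fit.

The aqueous field T is blended with its complement (T_max - T_i, the field
a hydrophobic environment such as a membrane interior would impose) weighted
by the non-negative parameter K:

    M(K) = normalize( T + K * normalize(T_max - T) )

K = 0 reproduces T exactly (pure water); as K grows, the central peak
flattens and the surface gains hydrophobicity, approaching the normalized
complement in the limit. K is fitted per structure as the minimizer of
D_KL(O | M(K)) over a one-dimensional grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateComplementError
from .profiles import Profile

__all__ = ["KFit", "complement_field", "modified_profile", "fit_k"]

logger = logging.getLogger(__name__)

# Floor applied to the reference (M) profile inside D_KL to keep the
# divergence finite when K and the complement conspire to produce a zero.
_EPS_FLOOR = 1e-12

DEFAULT_K_GRID = (0.0, 10.0, 0.001)


@dataclass(frozen=True)
class KFit:
    """Result of the grid search for the environment parameter K."""

    k_opt: float                  # argmin at grid resolution
    k_rounded: float              # k_opt rounded to 1 decimal (reporting precision)
    dkl_om_min: float             # bits, at k_opt
    curve: np.ndarray             # (n_grid, 2) columns (K, D_KL(O|M(K)))
    grid: tuple[float, float, float]
    boundary: bool = False        # argmin hit the upper grid edge
    degenerate: bool = False      # uniform T: fit restricted to K = 0


def complement_field(t: Profile | np.ndarray) -> np.ndarray:
    """The raw complement c_i = max(T) - T_i (all >= 0, argmax(T) maps to 0)."""
    tv = t.values if isinstance(t, Profile) else np.asarray(t, dtype=float)
    return tv.max() - tv


def _normalized_complement(t: Profile) -> np.ndarray:
    c = complement_field(t)
    total = c.sum()
    if total <= 0.0:
        raise DegenerateComplementError(
            "T is uniform: complement field is identically zero"
        )
    return c / total


def modified_profile(t: Profile, k: float) -> Profile:
    """M(K): T plus K times the unit-sum complement, renormalized.

    K = 0 returns T exactly (relabeled kind "M").

    Raises
    ------
    DegenerateComplementError
        If K > 0 and T is uniform (complement identically zero).
    """
    if k < 0.0:
        raise ValueError(f"K must be non-negative, got {k}")
    if k == 0.0:
        return Profile(kind="M", values=t.values.copy(), residue_refs=t.residue_refs)
    cn = _normalized_complement(t)
    combined = t.values + k * cn
    return Profile(kind="M", values=combined / combined.sum(), residue_refs=t.residue_refs)


def _kl_floored(o: np.ndarray, m: np.ndarray) -> float:
    mask = o > 0.0
    ref = m[mask]
    if np.any(ref < _EPS_FLOOR):
        logger.debug("epsilon floor %.0e applied to M reference in D_KL", _EPS_FLOOR)
        ref = np.maximum(ref, _EPS_FLOOR)
    return float(np.sum(o[mask] * np.log2(o[mask] / ref)))


def fit_k(
    o: Profile,
    t: Profile,
    grid: tuple[float, float, float] = DEFAULT_K_GRID,
    chunk: int = 1024,
) -> KFit:
    """Fit K by exhaustive grid search on D_KL(O | M(K)).

    Ties are broken toward smaller K (the water-dominant explanation). If T
    is uniform the complement is degenerate and the fit is restricted to
    K = 0. ``boundary`` flags an argmin at the upper grid edge, meaning the
    true minimum may lie beyond the grid.
    """
    if len(o) != len(t):
        raise ValueError("O and T profiles must have the same length")
    k_min, k_max, step = grid
    if not (k_min >= 0.0 and k_max > k_min and step > 0.0):
        raise ValueError(f"invalid K grid {grid}")

    ov, tv = o.values, t.values
    n_steps = int(round((k_max - k_min) / step))
    ks = k_min + step * np.arange(n_steps + 1)

    try:
        cn = _normalized_complement(t)
    except DegenerateComplementError:
        dkl0 = _kl_floored(ov, tv)
        curve = np.array([[0.0, dkl0]])
        return KFit(
            k_opt=0.0, k_rounded=0.0, dkl_om_min=dkl0,
            curve=curve, grid=grid, degenerate=True,
        )

    dkls = np.empty(ks.size)
    mask = ov > 0.0
    o_pos = ov[mask]
    for start in range(0, ks.size, chunk):
        kk = ks[start : start + chunk]
        m = tv[None, :] + kk[:, None] * cn[None, :]
        m /= m.sum(axis=1, keepdims=True)
        ref = np.maximum(m[:, mask], _EPS_FLOOR)
        dkls[start : start + kk.size] = np.sum(
            o_pos[None, :] * np.log2(o_pos[None, :] / ref), axis=1
        )

    best = int(np.argmin(dkls))  # first minimum -> smallest K on ties
    k_opt = float(ks[best])
    return KFit(
        k_opt=k_opt,
        k_rounded=round(k_opt, 1),
        dkl_om_min=float(dkls[best]),
        curve=np.column_stack([ks, dkls]),
        grid=grid,
        boundary=best == ks.size - 1,
    )
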