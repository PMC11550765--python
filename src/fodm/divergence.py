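"""Kullback-Leibler divergence, the RD statistic, and environment classes.

RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R)) locates the observed distribution
between the idealized micelle (T) and the structureless uniform reference
(R): RD < 0.5 means a hydrophobic core is present. The environment label
bins the fitted K parameter into the ranges observed across protein
classes, from pure water (K near 0) through membranes to chaperonin-grade
external fields (K > 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DivergenceError, SelectionError, UndefinedRDError
from .profiles import Profile
from .structure import ResidueRef

__all__ = [
    "FodResult",
    "kl_divergence",
    "relative_distance",
    "restrict_profile",
    "fragment_rd",
    "classify",
    "K_BINS",
    "RD_CORE_THRESHOLD",
]

RD_CORE_THRESHOLD = 0.5

# Half-open K bins [lo, hi) with environment labels; the K = 0 ideal-water
# case is folded into the first bin.
K_BINS: tuple[tuple[float, float, str], ...] = (
    (0.0, 0.5, "WATER"),
    (0.5, 0.9, "INTERMEDIATE"),
    (0.9, 1.5, "MEMBRANE-CHAPERONE"),
    (1.5, 3.0, "MEMBRANE"),
    (3.0, float("inf"), "CHAPERONIN-LIKE"),
)


@dataclass(frozen=True)
class FodResult:
    """RD/K characterization of a structure or fragment."""

    dkl_ot: float                 # bits
    dkl_or: float                 # bits
    rd: float
    k: float | None = None        # filled by the K fit
    dkl_om: float | None = None   # bits, at fitted K
    scope: str = "whole"

    @property
    def has_core(self) -> bool:
        return self.rd < RD_CORE_THRESHOLD


def kl_divergence(p: Profile | np.ndarray, q: Profile | np.ndarray) -> float:
    """D_KL(p|q) in bits: sum of p_i log2(p_i / q_i), with 0 log 0 = 0.

    Raises
    ------
    DivergenceError
        If q_i = 0 somewhere p_i > 0 (infinite divergence).
    """
    pv = p.values if isinstance(p, Profile) else np.asarray(p, dtype=float)
    qv = q.values if isinstance(q, Profile) else np.asarray(q, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError(f"profile length mismatch: {pv.shape} vs {qv.shape}")
    mask = pv > 0.0
    if np.any(qv[mask] <= 0.0):
        raise DivergenceError("reference profile is zero where p > 0 (D_KL infinite)")
    return float(np.sum(pv[mask] * np.log2(pv[mask] / qv[mask])))


def relative_distance(o: Profile, t: Profile, r: Profile) -> FodResult:
    """RD statistic: D_KL(O|T) / (D_KL(O|T) + D_KL(O|R)).

    RD = 0 iff O = T; RD = 1 iff O = R with O != T.

    Raises
    ------
    UndefinedRDError
        If O = T = R exactly (both divergences zero).
    """
    dkl_ot = kl_divergence(o, t)
    dkl_or = kl_divergence(o, r)
    denom = dkl_ot + dkl_or
    if denom == 0.0:
        raise UndefinedRDError("O = T = R exactly; RD is 0/0")
    return FodResult(dkl_ot=dkl_ot, dkl_or=dkl_or, rd=dkl_ot / denom)


def restrict_profile(profile: Profile, indices: Sequence[int]) -> Profile:
    """Restrict a profile to a residue subset and renormalize to unit sum."""
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise SelectionError("empty residue subset")
    vals = profile.values[idx]
    total = vals.sum()
    if total <= 0.0:
        raise DivergenceError(f"restricted {profile.kind} profile sums to zero")
    refs = tuple(profile.residue_refs[i] for i in idx) if profile.residue_refs else ()
    return Profile(kind=profile.kind, values=vals / total, residue_refs=refs)


def _subset_indices(refs: Sequence[ResidueRef], subset: Sequence[ResidueRef]) -> list[int]:
    lookup = {ref: i for i, ref in enumerate(refs)}
    indices = []
    for ref in subset:
        if ref not in lookup:
            raise SelectionError(f"residue {ref} not present in profiles")
        indices.append(lookup[ref])
    return sorted(set(indices))


def fragment_rd(
    o: Profile, t: Profile, r: Profile, subset: Sequence[ResidueRef]
) -> FodResult:
    """RD for a fragment: restrict T/O/R to the subset, renormalize, apply RD.

    The subset is given as residue references present in the profiles.
    """
    if len(subset) == 0:
        raise SelectionError("empty fragment selection")
    indices = _subset_indices(o.residue_refs, subset)
    o_f = restrict_profile(o, indices)
    t_f = restrict_profile(t, indices)
    r_f = restrict_profile(r, indices)
    res = relative_distance(o_f, t_f, r_f)
    return FodResult(
        dkl_ot=res.dkl_ot, dkl_or=res.dkl_or, rd=res.rd,
        scope=f"fragment[{len(indices)}]",
    )


def classify(rd: float, k: float) -> tuple[str, str]:
    """Map (RD, K) to a hydrophobic-core status and an environment label.

    Status is ``hydrophobic-core-present`` iff RD < 0.5; the environment
    label comes from the half-open K bins in :data:`K_BINS`. Total and
    deterministic for every RD in [0, 1] and K >= 0.
    """
    if not (0.0 <= rd <= 1.0):
        raise ValueError(f"RD must lie in [0, 1], got {rd}")
    if k < 0.0:
        raise ValueError(f"K must be non-negative, got {k}")
    status = "hydrophobic-core-present" if rd < RD_CORE_THRESHOLD else "no-hydrophobic-core"
    for lo, hi, label in K_BINS:
        if lo <= k < hi:
            return status, label
    raise AssertionError("unreachable: K bins cover [0, inf)")
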