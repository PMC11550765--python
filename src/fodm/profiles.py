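"""The three reference hydrophobicity distributions of the fuzzy-oil-drop model.

T (theoretical): the 3D Gaussian envelope evaluated at each effective-atom
position — the idealized micelle, hydrophobic center and polar surface.

O (observed): each residue's actual hydrophobic contact density, summing
(H_i + H_j) over neighbor pairs within a 9 Å cutoff with Levitt's empirical
distance weight.

R (reference/uniform): 1/N per residue — the structureless alternative.

All profiles are normalized to unit sum so they can be compared as
probability distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .envelope import GaussianEnvelope
from .errors import NormalizationError
from .structure import ResidueRef, StructureModel

__all__ = [
    "Profile",
    "levitt_weight",
    "theoretical_profile",
    "observed_profile",
    "uniform_profile",
    "compute_profiles",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 9.0  # Å


@dataclass(frozen=True)
class Profile:
    """A normalized per-residue distribution of kind T, O, R or M."""

    kind: str
    values: np.ndarray
    residue_refs: tuple[ResidueRef, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("profile values must be 1-D")
        if np.any(vals < 0):
            raise ValueError(f"{self.kind} profile has negative values")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{self.kind} profile does not sum to 1 (sum = {vals.sum()!r})"
            )
        if self.residue_refs and len(self.residue_refs) != vals.size:
            raise ValueError("residue_refs length does not match values")
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size


def _normalize(raw: np.ndarray, kind: str) -> np.ndarray:
    total = raw.sum()
    if total <= 0.0:
        raise NormalizationError(f"raw {kind} values sum to {total}; cannot normalize")
    return raw / total


def levitt_weight(r, cutoff: float = DEFAULT_CUTOFF):
    """Levitt's hydrophobic-contact distance weight.

    w(r) = 1 - 1/2 (7 t^2 - 9 t^4 + 5 t^6 - t^8) with t = r / cutoff for
    r <= cutoff, and 0 beyond. w(0) = 1 and w(cutoff) = 0, so the
    contribution vanishes continuously at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    t2 = (r / cutoff) ** 2
    w = 1.0 - 0.5 * (7.0 * t2 - 9.0 * t2**2 + 5.0 * t2**3 - t2**4)
    return np.where(r <= cutoff, w, 0.0)


def theoretical_profile(
    oriented_positions: np.ndarray,
    envelope: GaussianEnvelope,
    refs: Sequence[ResidueRef] = (),
) -> Profile:
    """T profile: the normalized 3D Gaussian at each effective-atom position.

    Positions must already be in the envelope's centered principal-axis
    frame (as returned by :func:`fodm.envelope.fit_envelope`).
    """
    pos = np.asarray(oriented_positions, dtype=float)
    sig = np.asarray(envelope.sigmas, dtype=float)
    # log-space for numerical safety with extreme aspect ratios
    log_t = -0.5 * np.sum((pos / sig) ** 2, axis=1)
    raw = np.exp(log_t - log_t.max())
    return Profile(kind="T", values=_normalize(raw, "T"), residue_refs=tuple(refs))


def observed_profile(
    positions: np.ndarray,
    hydrophobicities: np.ndarray,
    refs: Sequence[ResidueRef] = (),
    cutoff: float = DEFAULT_CUTOFF,
    include_self: bool = True,
) -> Profile:
    """O profile: pairwise hydrophobic-contact sums with Levitt's weight.

    O_i is proportional to the sum over residues j with r_ij <= cutoff of
    (H_i + H_j) * w(r_ij). The self pair (j = i, weight 1, contributing
    2 H_i) is included by default; set ``include_self=False`` to restrict to
    j != i.
    """
    pos = np.asarray(positions, dtype=float)
    h = np.asarray(hydrophobicities, dtype=float)
    n = pos.shape[0]
    if n < 2:
        raise ValueError("observed profile needs at least 2 residues")
    if np.any(h < 0):
        raise ValueError("intrinsic hydrophobicities must be non-negative")

    dists = squareform(pdist(pos))
    w = levitt_weight(dists, cutoff=cutoff)
    if not include_self:
        np.fill_diagonal(w, 0.0)
    raw = ((h[:, None] + h[None, :]) * w).sum(axis=1)
    return Profile(kind="O", values=_normalize(raw, "O"), residue_refs=tuple(refs))


def uniform_profile(n: int, refs: Sequence[ResidueRef] = ()) -> Profile:
    """R profile: equal hydrophobicity 1/N per residue."""
    if n < 2:
        raise ValueError(f"uniform profile needs N >= 2, got {n}")
    return Profile(kind="R", values=np.full(n, 1.0 / n), residue_refs=tuple(refs))


def compute_profiles(
    model: StructureModel,
    cutoff: float = DEFAULT_CUTOFF,
    include_self: bool = True,
) -> tuple[Profile, Profile, Profile, GaussianEnvelope]:
    """Fit the envelope and compute T, O and R for a structure model."""
    from .envelope import fit_envelope

    oriented, env = fit_envelope(model.positions)
    refs = model.refs
    t = theoretical_profile(oriented, env, refs)
    o = observed_profile(
        model.positions, model.hydrophobicities, refs,
        cutoff=cutoff, include_self=include_self,
    )
    r = uniform_profile(len(model), refs)
    return t, o, r, env
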