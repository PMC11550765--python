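"""Synthetic structure fixtures with controlled hydrophobicity geometry.

Each fixture is a seeded point cloud inside a 3-sigma ellipsoid, with
residue identities chosen so that the intrinsic hydrophobicity read from the
active scale produces a prescribed observed-vs-theoretical relationship:

ideal-micelle
    the observed profile tracks the Gaussian envelope (hydrophobic center,
    polar surface) — a water-soluble protein with a well-formed core; RD
    well below 0.5 and fitted K near 0.
inverted
    the observed profile tracks the complement of the Gaussian (hydrophobic
    surface) — the membrane-protein pattern; large fitted K.
uniform
    the observed profile tracks the uniform reference; RD near 1.
planted-outlier
    a muted micelle plus one fully hydrophobic residue at the most
    surface-exposed position — a single localized disruption that deprives
    the structure of its hydrophobic-core signal and is removed first by
    the elimination procedure.

Intrinsic hydrophobicities are chosen by inverting the contact operator:
the observed profile is linear in the per-residue hydrophobicities
(O_raw = (diag(row sums of w) + w) h with w the Levitt weight matrix), so
solving that system for the target profile, clipping at zero, makes O track
the target as closely as the 20 discrete residue levels allow.

Point density mimics globular-protein packing (about 160 Å^3 per residue,
several neighbors inside the 9 Å contact cutoff). Hydrophobicity is encoded
through residue identity so fixtures exercise the same scale-lookup path as
real PDB input. The same seed always produces byte-identical PDB files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import FixtureError
from .scales import ONE_TO_THREE, HydrophobicityScale, get_scale
from .structure import EffectiveAtom, ResidueRef, StructureModel

__all__ = ["FixtureSpec", "generate", "write_pdb", "MODES"]

MODES = ("ideal-micelle", "inverted", "uniform", "planted-outlier")

_VOLUME_PER_RESIDUE = 160.0  # Å^3, globular-protein effective-atom packing
_PLANTED_BACKGROUND = 0.35   # core muting factor for the planted-outlier mode


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure; the seed fully determines the output."""

    n_residues: int
    mode: str = "ideal-micelle"
    aspect: tuple[float, float, float] = (1.6, 1.25, 1.0)
    seed: int = 0
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise FixtureError(f"unknown mode {self.mode!r}; choose from {MODES}")
        min_n = 4 if self.mode == "planted-outlier" else 3
        if self.n_residues < min_n:
            raise FixtureError(
                f"mode {self.mode!r} needs at least {min_n} residues, got {self.n_residues}"
            )
        if self.noise < 0:
            raise FixtureError("noise must be non-negative")
        if any(a <= 0 for a in self.aspect):
            raise FixtureError("aspect ratios must be positive")


def _sample_ellipsoid(rng: np.random.Generator, n: int, semi_axes: np.ndarray) -> np.ndarray:
    """Rejection-sample n points uniformly inside an axis-aligned ellipsoid."""
    points = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - filled) + 8, 3))
        keep = cand[(cand**2).sum(axis=1) <= 1.0]
        take = min(keep.shape[0], n - filled)
        points[filled : filled + take] = keep[:take]
        filled += take
    return points * semi_axes


def generate(
    spec: FixtureSpec, scale: HydrophobicityScale | str | None = None
) -> tuple[StructureModel, dict]:
    """Build a fixture StructureModel plus a descriptor of expected behavior."""
    if isinstance(scale, str) or scale is None:
        scale = get_scale(scale)
    rng = np.random.default_rng(spec.seed)

    aspect = np.asarray(spec.aspect, dtype=float)
    # semi-axes with the requested aspect and protein-like per-residue volume
    s = (3.0 * spec.n_residues * _VOLUME_PER_RESIDUE / (4.0 * np.pi * aspect.prod())) ** (1.0 / 3.0)
    semi_axes = s * aspect
    pos = _sample_ellipsoid(rng, spec.n_residues, semi_axes)
    n = spec.n_residues

    # The exact theoretical profile of the sampled cloud, via the same
    # envelope fit the analysis pipeline applies.
    from .envelope import fit_envelope
    from .profiles import theoretical_profile

    oriented, _env = fit_envelope(pos)
    t_like = theoretical_profile(oriented, _env).values

    if spec.mode == "uniform":
        target = np.full(n, 1.0 / n)
    elif spec.mode == "inverted":
        comp = t_like.max() - t_like
        target = comp / comp.sum()
    else:  # ideal-micelle and planted-outlier
        target = t_like

    # Invert the linear contact operator so O_raw is proportional to the
    # target profile; clip at zero and rescale so the most hydrophobic
    # residue sits at the top of the scale.
    from scipy.spatial.distance import pdist, squareform

    from .profiles import levitt_weight

    w = levitt_weight(squareform(pdist(pos)))
    operator = w + np.diag(w.sum(axis=1))
    desired, *_ = np.linalg.lstsq(operator, target, rcond=None)
    desired = np.clip(desired, 0.0, None)
    if desired.max() <= 0.0:
        raise FixtureError("degenerate fixture: solved hydrophobicities are all zero")
    desired /= desired.max()

    planted_index: int | None = None
    if spec.mode == "planted-outlier":
        # Mute the core so the single hot spot carries the divergence, then
        # plant a fully hydrophobic residue at the most surface-exposed
        # (minimum-T) position.
        desired *= _PLANTED_BACKGROUND
        planted_index = int(np.argmin(t_like))
        desired[planted_index] = 1.0

    if spec.noise > 0:
        noise = rng.normal(0.0, spec.noise, size=n)
        if planted_index is not None:
            noise[planted_index] = 0.0  # keep the planted signal clean
        desired = np.clip(desired + noise, 0.0, 1.0)

    atoms = []
    for i in range(spec.n_residues):
        aa1 = scale.nearest_residue(float(desired[i]))
        aa3 = ONE_TO_THREE[aa1]
        ref = ResidueRef(chain_id="A", seq_number=i + 1, insertion_code="", aa_code=aa3)
        atoms.append(
            EffectiveAtom(ref=ref, position=pos[i], intrinsic_h=scale.level(aa1))
        )
    model = StructureModel(
        id=f"synthetic-{spec.mode}-n{spec.n_residues}-s{spec.seed}",
        atoms=tuple(atoms),
        source_format="synthetic",
        scale_name=scale.name,
    )

    expect: dict = {"mode": spec.mode, "seed": spec.seed, "n": spec.n_residues}
    if spec.mode == "ideal-micelle":
        expect.update(rd="<0.5", k="~0")
    elif spec.mode == "inverted":
        expect.update(rd=">0.5", k="large")
    elif spec.mode == "uniform":
        expect.update(rd=">0.9")
    else:
        expect.update(planted=model.atoms[planted_index].ref, planted_index=planted_index)
    return model, expect


def write_pdb(model: StructureModel, path) -> Path:
    """Write a fixture as a single-model PDB, one CA record per effective atom.

    Round-trips through :func:`fodm.structure.load_structure` to the same
    model (positions at PDB precision, 1e-3 Å).
    """
    n = len(model)
    arr = struc.AtomArray(n)
    arr.coord = model.positions.astype(np.float32)
    arr.chain_id = np.array([a.ref.chain_id for a in model.atoms])
    arr.res_id = np.array([a.ref.seq_number for a in model.atoms])
    arr.res_name = np.array([a.ref.aa_code for a in model.atoms])
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))

    path = Path(path)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
    return path
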