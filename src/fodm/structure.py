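"""Reading macromolecular structures and reducing residues to effective atoms.

The unit of all downstream analysis is the *effective atom*: one point per
residue at the arithmetic mean of the residue's heavy (non-hydrogen) atom
positions, carrying the residue's intrinsic hydrophobicity under the active
scale. Hydrogens, waters, ligands and other heteroatoms are excluded;
alternate locations are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as _cif_get_structure

from .errors import ParseError, ResidueError, SelectionError
from .scales import THREE_TO_ONE, HydrophobicityScale, get_scale

__all__ = [
    "ResidueRef",
    "EffectiveAtom",
    "StructureModel",
    "load_structure",
    "effective_atom_position",
    "parse_selection",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Identity of one residue in author numbering."""

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    aa_code: str = "UNK"

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.aa_code}{self.seq_number}{self.insertion_code}"


@dataclass(frozen=True)
class EffectiveAtom:
    """One point per residue: mean heavy-atom position + intrinsic hydrophobicity."""

    ref: ResidueRef
    position: np.ndarray  # shape (3,), Å
    intrinsic_h: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"invalid position for {self.ref}: {self.position}")
        object.__setattr__(self, "position", pos)
        if self.intrinsic_h < 0:
            raise ValueError(f"negative intrinsic hydrophobicity for {self.ref}")


@dataclass(frozen=True)
class StructureModel:
    """An ordered effective-atom representation of a structure or fragment."""

    id: str
    atoms: tuple[EffectiveAtom, ...]
    source_format: str = "pdb"
    scale_name: str = "kyte-doolittle"

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of effective-atom positions."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def hydrophobicities(self) -> np.ndarray:
        """(N,) array of intrinsic hydrophobicities."""
        return np.array([a.intrinsic_h for a in self.atoms], dtype=float)

    @property
    def refs(self) -> tuple[ResidueRef, ...]:
        return tuple(a.ref for a in self.atoms)


def effective_atom_position(coords) -> np.ndarray:
    """Mean position of a residue's atoms (all heavy atoms, backbone + side chain)."""
    arr = np.asarray(coords, dtype=float)
    if arr.size == 0:
        raise ResidueError("residue has no atoms")
    arr = arr.reshape(-1, 3)
    return arr.mean(axis=0)


def parse_selection(expr: str) -> dict[str, list[tuple[int, int]] | None]:
    """Parse ``CHAIN`` / ``CHAIN:start-end[,start-end...]`` selection terms.

    Multiple terms are separated by whitespace or ';'. Residue ranges use
    author numbering and are inclusive on both ends; a bare number selects a
    single residue. A chain mapped to None means "whole chain".
    """
    out: dict[str, list[tuple[int, int]] | None] = {}
    terms = [t for t in expr.replace(";", " ").split() if t]
    if not terms:
        raise SelectionError(f"empty selection expression: {expr!r}")
    for term in terms:
        if ":" in term:
            chain, _, ranges = term.partition(":")
            spans: list[tuple[int, int]] = []
            for part in ranges.split(","):
                part = part.strip()
                if not part:
                    continue
                if "-" in part[1:]:  # allow negative start numbers
                    lo_s, hi_s = part.rsplit("-", 1)
                    lo, hi = int(lo_s), int(hi_s)
                else:
                    lo = hi = int(part)
                if hi < lo:
                    raise SelectionError(f"inverted range {part!r} in {term!r}")
                spans.append((lo, hi))
            if not spans:
                raise SelectionError(f"no ranges in selection term {term!r}")
            if chain in out:
                if out[chain] is not None:  # whole-chain term supersedes ranges
                    out[chain] = out[chain] + spans
            else:
                out[chain] = spans
        else:
            out[term] = None
    return out


def _selected(sel, chain: str, seq: int) -> bool:
    if sel is None:
        return True
    if chain not in sel:
        return False
    spans = sel[chain]
    if spans is None:
        return True
    return any(lo <= seq <= hi for lo, hi in spans)


def _read_atom_array(path: Path):
    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif"):
            cif = CIFFile.read(str(path))
            arr = _cif_get_structure(cif, model=1, altloc="occupancy")
            fmt = "mmcif"
        else:
            pdb = PDBFile.read(str(path))
            arr = pdb.get_structure(model=1, altloc="occupancy")
            fmt = "pdb"
    except Exception as exc:  # biotite raises various parse exceptions
        raise ParseError(f"cannot parse structure file {path}: {exc}") from exc
    return arr, fmt


def load_structure(
    path,
    selection: str | None = None,
    scale: HydrophobicityScale | str | None = None,
    residue_map: dict[str, str] | None = None,
) -> StructureModel:
    """Load a PDB/mmCIF file and reduce it to effective atoms.

    Parameters
    ----------
    path
        A ``.pdb``/``.ent`` or ``.cif`` file.
    selection
        Optional ``CHAIN[:start-end,...]`` expression (author numbering,
        inclusive). None selects every protein chain.
    scale
        Hydrophobicity scale or built-in scale name (default Kyte-Doolittle).
    residue_map
        Optional mapping of non-standard 3-letter codes to standard ones,
        e.g. ``{"MSE": "MET"}``. Unmapped non-standard residues in ATOM
        records raise :class:`ResidueError`.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if isinstance(scale, str) or scale is None:
        scale = get_scale(scale)
    residue_map = residue_map or {}
    sel = parse_selection(selection) if selection else None

    arr, fmt = _read_atom_array(path)
    # Heavy protein atoms only: drop hydrogens/deuterium and HETATM records
    # (waters, ligands, and modified residues deposited as hetero).
    mask = (~arr.hetero) & (arr.element != "H") & (arr.element != "D")
    arr = arr[mask]
    if arr.array_length() == 0:
        raise SelectionError(f"no protein ATOM records in {path}")

    atoms: list[EffectiveAtom] = []
    for start, stop in _residue_runs(arr):
        chain = str(arr.chain_id[start])
        seq = int(arr.res_id[start])
        icode = str(arr.ins_code[start]) if "ins_code" in arr.get_annotation_categories() else ""
        name = str(arr.res_name[start]).upper()
        if not _selected(sel, chain, seq):
            continue
        name = residue_map.get(name, name)
        if name not in THREE_TO_ONE:
            raise ResidueError(
                f"non-standard residue {name} at {chain}:{seq}{icode} "
                f"(provide residue_map to translate or exclude it)"
            )
        coords = arr.coord[start:stop]
        if coords.shape[0] == 0:
            logger.warning("residue %s:%s%s has no atoms; skipped", chain, seq, icode)
            continue
        ref = ResidueRef(chain_id=chain, seq_number=seq, insertion_code=icode.strip(), aa_code=name)
        atoms.append(
            EffectiveAtom(
                ref=ref,
                position=effective_atom_position(coords),
                intrinsic_h=scale.level(name),
            )
        )

    if sel is not None and not atoms:
        raise SelectionError(f"selection {selection!r} matched no residues in {path}")
    if len(atoms) < 2:
        raise SelectionError(
            f"selection yields {len(atoms)} residue(s); at least 2 required"
        )
    return StructureModel(
        id=path.stem, atoms=tuple(atoms), source_format=fmt, scale_name=scale.name
    )


def _residue_runs(arr):
    """Yield (start, stop) index runs of consecutive identical residues, in file order."""
    n = arr.array_length()
    keys = list(
        zip(
            arr.chain_id,
            arr.res_id,
            arr.ins_code if "ins_code" in arr.get_annotation_categories() else [""] * n,
        )
    )
    start = 0
    for i in range(1, n + 1):
        if i == n or keys[i] != keys[start]:
            yield start, i
            start = i
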