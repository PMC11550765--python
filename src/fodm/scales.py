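"""Intrinsic amino-acid hydrophobicity scales.

Any published scale can drive the observed-hydrophobicity profile; what
matters downstream is only the *relative* ordering, because profiles are
normalized to unit sum. Scales are min-max rescaled to [0, 1] so that every
intrinsic hydrophobicity is non-negative and normalized distributions are
well defined (the raw Kyte-Doolittle scale, for instance, is signed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "HydrophobicityScale",
    "get_scale",
    "available_scales",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Raw (published) values; rescaled on construction.
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
_EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}
_FAUCHERE_PLISKA = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}


def _rescale(raw: dict[str, float]) -> dict[str, float]:
    lo, hi = min(raw.values()), max(raw.values())
    span = hi - lo
    return {aa: (v - lo) / span for aa, v in raw.items()}


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named map from 1-letter amino-acid code to a level in [0, 1].

    Values must cover all 20 standard residues; they are assumed already
    rescaled so min = 0 and max = 1 (use :func:`HydrophobicityScale.from_raw`
    for a raw published scale).
    """

    name: str
    values: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(ONE_TO_THREE) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")
        if any(v < 0.0 or v > 1.0 for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} has values outside [0, 1]")

    @classmethod
    def from_raw(cls, name: str, raw: dict[str, float]) -> "HydrophobicityScale":
        """Min-max rescale a raw published scale to [0, 1]."""
        return cls(name=name, values=_rescale(raw))

    def level(self, aa: str) -> float:
        """Hydrophobicity of a residue given as 1- or 3-letter code."""
        code = THREE_TO_ONE.get(aa.upper(), aa.upper())
        try:
            return self.values[code]
        except KeyError:
            raise KeyError(f"unknown residue {aa!r} for scale {self.name!r}") from None

    def nearest_residue(self, level: float) -> str:
        """1-letter code whose level is closest to ``level``.

        Ties are broken alphabetically for determinism.
        """
        return min(sorted(self.values), key=lambda aa: abs(self.values[aa] - level))


_SCALES = {
    "kyte-doolittle": HydrophobicityScale.from_raw("kyte-doolittle", _KYTE_DOOLITTLE),
    "eisenberg": HydrophobicityScale.from_raw("eisenberg", _EISENBERG),
    "fauchere-pliska": HydrophobicityScale.from_raw("fauchere-pliska", _FAUCHERE_PLISKA),
}

DEFAULT_SCALE = "kyte-doolittle"


def available_scales() -> list[str]:
    return sorted(_SCALES)


def get_scale(name: str | None = None) -> HydrophobicityScale:
    """Return a built-in scale by name (default: Kyte-Doolittle)."""
    key = (name or DEFAULT_SCALE).lower()
    try:
        return _SCALES[key]
    except KeyError:
        raise KeyError(
            f"unknown scale {name!r}; available: {available_scales()}"
        ) from None
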