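"""Exception hierarchy for the fodm package."""


class FodError(Exception):
    """Base class for all fodm errors."""


class ParseError(FodError):
    """A structure file could not be read or parsed."""


class SelectionError(FodError):
    """A chain/residue selection matched too few residues or none at all."""


class ResidueError(FodError):
    """A residue is unusable: non-standard without mapping, or has no atoms."""


class GeometryError(FodError):
    """The effective-atom cloud is degenerate (collinear, planar, too small)."""


class NormalizationError(FodError):
    """A raw hydrophobicity vector sums to zero and cannot be normalized."""


class DivergenceError(FodError):
    """Kullback-Leibler divergence is infinite (reference zero where p > 0)."""


class UndefinedRDError(FodError):
    """RD is 0/0: the observed profile equals both references exactly."""


class DegenerateComplementError(FodError):
    """The complement field T_max - T is identically zero (uniform T)."""


class FixtureError(FodError):
    """A synthetic-fixture specification cannot be satisfied."""
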