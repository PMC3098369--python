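"""Exception hierarchy for the chondronmr pipeline."""


class ChondroError(Exception):
    """Base class for all package-specific errors."""


class UnknownResidueKindError(ChondroError, ValueError):
    """A residue kind other than GlcA/GalNAc was requested."""


class UndefinedTorsionError(ChondroError, ValueError):
    """Dihedral undefined: coincident or collinear defining points."""


class StructuralError(ChondroError, ValueError):
    """A named atom or ring required by an operation is missing/broken."""


class InputError(ChondroError, ValueError):
    """Invalid numeric input (non-positive intensity, bad multiplicity, ...)."""


class MissingPeakError(ChondroError, KeyError):
    """An expected NOESY cross-peak is absent from the peak table."""


class ConfigurationError(ChondroError, ValueError):
    """A required parameter set (e.g. Karplus coefficients) is not configured."""


class ParseError(ChondroError, ValueError):
    """A structured input file could not be parsed."""
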