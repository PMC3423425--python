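"""Exception taxonomy shared across the package."""


class MRCGBSAError(Exception):
    """Base class for all package errors."""


class FormatError(MRCGBSAError):
    """A structure file record could not be parsed."""


class ParameterizationError(MRCGBSAError):
    """An atom has no entry (and no element wildcard) in the parameter table."""


class MappingError(MRCGBSAError):
    """Atom correspondence between two structures could not be established."""


class ShapeError(MRCGBSAError, ValueError):
    """Mismatched array shapes or point counts."""


class DomainError(MRCGBSAError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConditioningError(MRCGBSAError):
    """A numerically degenerate configuration (e.g. collinear points in superposition)."""


class SingularEnergyError(MRCGBSAError):
    """Coincident atoms on a nonbonded pair make the energy singular."""


class InstabilityError(MRCGBSAError):
    """A trajectory or line search produced a non-finite energy."""


class GenerationError(MRCGBSAError):
    """Conformer or fixture generation failed irrecoverably."""


class DataError(MRCGBSAError):
    """An energy grid or table is incomplete or inconsistent."""


class ConfigurationError(MRCGBSAError):
    """A run configuration is invalid or underdetermined."""


class SizeError(MRCGBSAError):
    """A brute-force computation exceeds its enumeration budget."""


class UndefinedCorrelationError(DomainError):
    """Correlation requested on a zero-variance input."""
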