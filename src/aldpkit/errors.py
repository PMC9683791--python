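"""Exception hierarchy shared across the toolkit."""


class AldpkitError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(AldpkitError):
    """Coordinate file could not be parsed; message names the offending input."""


class EmptyModelError(AldpkitError):
    """A parsed structure contains zero polymer residues."""


class ChainNotFoundError(AldpkitError, KeyError):
    pass


class ResidueNotFoundError(AldpkitError, KeyError):
    pass


class ComponentNotFoundError(AldpkitError, KeyError):
    """Requested hetero component absent; message lists available codes."""


class ValidationError(AldpkitError, ValueError):
    pass


class PairingError(AldpkitError):
    """Point sets (or residue sets) cannot be paired for superposition."""


class ConditioningError(AldpkitError):
    """Degenerate geometry (e.g. collinear points) makes a transform ill-defined."""


class EmptySubsetError(AldpkitError):
    """Requested atom subset (e.g. glycine side chain) is empty."""


class NoTransitionError(AldpkitError):
    """Melt curve shows no unfolding transition."""


class FitError(AldpkitError):
    """Nonlinear fit failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateDataError(AldpkitError):
    pass


class NormalizationError(AldpkitError):
    pass


class GeneratorError(AldpkitError):
    """A synthetic-fixture generator could not honour its contract."""


class SchemaError(AldpkitError):
    """Tabular input or config does not match the declared schema."""
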