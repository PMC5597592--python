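"""Exception hierarchy shared across the package."""


class CrossResError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CrossResError):
    """A file could not be parsed under its declared format."""


class ShapeError(CrossResError, ValueError):
    """Array dimensions do not match the operation's contract."""


class TopologyError(CrossResError):
    """Molecule copies that must be identical are not."""


class EmptySelectionError(CrossResError):
    """A selection matched no particles."""


class GeometryError(CrossResError):
    """Degenerate geometry (collinear/coincident fit selection)."""


class ValidationError(CrossResError, ValueError):
    """Input violates a numerical precondition (NaN, asymmetry, ...)."""


class InsufficientDataError(CrossResError):
    """Too few conformations/samples for the requested statistic."""


class FitError(CrossResError):
    """A least-squares fit has too few eligible points."""


class UnresolvedTimescaleError(CrossResError):
    """Autocorrelation does not decay; no characteristic time exists."""


class MappingDefinitionError(CrossResError):
    """Malformed mapping file (empty bead, undeclared atom, ...)."""


class ConfigError(CrossResError):
    """Run configuration is invalid."""


class PipelineStageError(CrossResError):
    """A pipeline stage failed; carries stage and simulation label."""

    def __init__(self, stage: str, label: str, cause: BaseException):
        self.stage = stage
        self.label = label
        self.cause = cause
        super().__init__(f"stage '{stage}' failed for simulation '{label}': {cause}")
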