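"""Exception hierarchy for plgic.

Every error raised on a user-facing code path derives from :class:`PlgicError`
so that the CLI can catch one type and exit with a stage-labelled message.
"""


class PlgicError(Exception):
    """Base class for all plgic errors."""


class ParseError(PlgicError):
    """A coordinate file could not be parsed."""


class EmptyStructureError(ParseError):
    """A coordinate file parsed but contained no atoms."""


class ConfigurationError(PlgicError):
    """A config (roles / chain mapping / domain definition) is inconsistent."""


class AnnotationError(PlgicError):
    """Role/domain annotation failed validation against the model."""


class SelectionError(PlgicError):
    """An atom/domain selection referenced something that does not exist."""


class DegenerateGeometryError(PlgicError):
    """Too few or collinear points for a superposition or axis fit."""


class CorrespondenceError(PlgicError):
    """Residue pairing between models is missing, ambiguous, or too sparse."""


class CoverageError(PlgicError):
    """A pore profile does not cover a requested gate window."""


class SpecError(PlgicError):
    """A synthetic-data specification is internally inconsistent."""


class TrajectoryError(PlgicError):
    """A trajectory violates the fixed-topology contract."""
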