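"""Exception hierarchy for pipeline failure modes."""


class RDAUNetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RDAUNetError):
    """A file could not be read in the requested format."""


class ContentError(RDAUNetError):
    """A file parsed but its content is not usable (e.g. non-grayscale)."""


class PairingError(RDAUNetError):
    """An image and mask do not correspond (shape or identity mismatch)."""


class ParameterError(RDAUNetError, ValueError):
    """An argument is outside its valid domain."""


class UndefinedMetricError(RDAUNetError):
    """A metric is undefined for the given inputs (e.g. empty masks)."""


class SpecError(RDAUNetError, ValueError):
    """A phantom specification is infeasible."""
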