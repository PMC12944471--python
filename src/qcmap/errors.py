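"""Exception hierarchy for the qcmap package."""


class QcmapError(Exception):
    """Base class for all qcmap errors."""


class FormatError(QcmapError):
    """A file could not be parsed as the expected format."""


class ShapeError(QcmapError):
    """Array dimensions do not match what the operation requires."""


class ParameterError(QcmapError):
    """A numeric parameter is outside its admissible range."""


class GeometryError(QcmapError):
    """A phantom region does not fit the simulation grid."""


class DegenerateInputError(QcmapError):
    """Input is formally valid but carries no usable information
    (e.g. all-zero magnitude, all-equal regressor)."""
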