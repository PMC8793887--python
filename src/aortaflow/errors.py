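"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ParameterError -> 2, DataError and
GeometryError -> 3.
"""


class AortaflowError(Exception):
    """Base class for all package errors."""


class ParameterError(AortaflowError, ValueError):
    """Invalid user-supplied parameter or configuration value."""


class DataError(AortaflowError):
    """Input data missing, malformed, or inconsistent."""


class GeometryError(AortaflowError):
    """Segmentation mask or centerline violates geometric preconditions."""
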