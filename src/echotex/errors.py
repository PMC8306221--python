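"""Typed errors raised by the pipeline.

Degenerate inputs raise one of these instead of propagating NaNs, so a
failing stage can always be attributed in pipeline logs.
"""


class EchotexError(Exception):
    """Base class for all package errors."""


class InputError(EchotexError):
    """Malformed, unreadable, or inconsistent user input."""


class UnsupportedFormatError(InputError):
    """Image format the loader does not handle (color/multi-frame DICOM...)."""


class TooSmallROIError(InputError):
    """ROI has too few (valid) pixels for the requested computation."""


class DegenerateMatrixError(EchotexError):
    """A co-occurrence matrix could not be formed (zero valid pixel pairs)."""


class CollinearityError(EchotexError):
    """Design matrix is rank deficient; offending columns are named."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; offending columns: {self.columns}")


class UndefinedICCError(EchotexError):
    """ICC undefined (zero between-subject variance)."""


class EmptyModelError(EchotexError):
    """All candidate features were filtered out before model fitting."""

    def __init__(self, stage, message=""):
        self.stage = stage
        super().__init__(message or f"no features survive stage '{stage}'")
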