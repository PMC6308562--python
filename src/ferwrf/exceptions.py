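"""Exception hierarchy for ferwrf.

All package errors derive from :class:`FerError` so callers can catch one
base class at the CLI boundary.
"""


class FerError(Exception):
    """Base class for all ferwrf errors."""


class LandmarkFormatError(FerError):
    """A landmark table row or record violates the 68-point schema."""


class LabelVocabularyError(FerError):
    """An expression label is outside the closed 6-class vocabulary."""


class DegenerateGeometryError(FerError):
    """A landmark triple produced a (near-)zero-length vector."""


class ContractError(FerError):
    """An internal API contract was violated (dimension mismatch, bad partition)."""


class TrainingFailureError(FerError):
    """Forest training could not reach the requested number of surviving trees."""

    def __init__(self, message: str, attempts: int = 0, survivors: int = 0):
        super().__init__(message)
        self.attempts = attempts
        self.survivors = survivors


class ProtocolError(FerError):
    """A cross-validation protocol requirement cannot be met."""
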