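"""Exception hierarchy for sigcite.

All library errors derive from :class:`SigciteError` so callers can catch a
single base class; specific subclasses map one-to-one to the distinct failure
modes of signature handling, storage, resolution, and graph construction.
"""

from __future__ import annotations


class SigciteError(Exception):
    """Base class for all sigcite errors."""


class UnsupportedAlgorithmError(SigciteError):
    """The hash algorithm token is not registered."""


class NotASignatureError(SigciteError):
    """The text does not use any recognized content-signature scheme."""


class MalformedPayloadError(SigciteError):
    """The payload contains characters illegal for its declared encoding,
    or has an impossible length for the declared algorithm."""


class ImpossibleTranslationError(SigciteError):
    """Translation between schemes was requested across different hash
    algorithms; a hash can never be re-expressed under another algorithm
    without re-hashing the content."""


class InvalidLengthError(SigciteError):
    """A truncation length or keyspace exponent is out of range."""


class UnsupportedCombinationError(SigciteError):
    """The requested (scheme, encoding) pair cannot represent the payload,
    e.g. base64url for a hex prefix whose bit length is not a multiple of 6."""


class EncodingError(SigciteError):
    """Collection text could not be encoded with the required codec."""


class StorageError(SigciteError):
    """An I/O failure occurred while reading or writing the content store."""


class CorruptionError(StorageError):
    """Stored bytes no longer hash to the signature they are filed under."""


class NotFoundError(SigciteError):
    """No stored content matches the requested signature."""


class AmbiguousPrefixError(SigciteError):
    """A signature prefix matched more than one stored item."""

    def __init__(self, prefix: str, candidates: list[str]):
        self.prefix = prefix
        self.candidates = candidates
        super().__init__(
            f"prefix {prefix!r} is ambiguous: matches {', '.join(candidates)}"
        )


class ValidationError(SigciteError):
    """A URI, timestamp, or record field failed validation."""


class InvalidComparisonError(SigciteError):
    """Two registry records for different locations were compared."""


class UnresolvableError(SigciteError):
    """Every source was tried and none produced verified content."""

    def __init__(self, message: str, attempts=None):
        self.attempts = list(attempts or [])
        super().__init__(message)


class NoAliasError(SigciteError):
    """A URL has no successful registry observation to alias a signature."""


class ContradictionError(SigciteError):
    """A relation claim is self-contradictory (e.g. different-from(s, s))."""
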