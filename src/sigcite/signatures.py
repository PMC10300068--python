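"""Content signatures: compute, parse, format, translate, truncate, verify.

A *content signature* pairs a cryptographic hash of exact bytes with the name
of the algorithm that produced it.  Its canonical text form is a content-hash
URI, ``hash://<algorithm>/<hex digest>``, where the digest is lowercase
hexadecimal (4 bits per character).  Because the digest is a pure function of
the bytes, anyone holding the content can recompute the signature and thereby
detect content drift; because the identifier carries no location, the content
may move freely between repositories without invalidating citations.

Supported identifier dialects:

* content-hash URI  — ``hash://sha256/29d30b…``
* named information — ``ni:///sha256;29d30b…`` (hex or base64url payload)
* human-oriented    — ``nih:sha256;29d30b…;<check digit>`` with an optional
  Luhn mod-16 check digit for transcription-error detection.

All three carry the same digest bits and translate freely into one another;
translation never crosses hash algorithms (an md5 digest can never become a
sha256 digest without re-hashing the content itself).
"""

from __future__ import annotations

import base64
import hashlib
import re
import warnings
from dataclasses import dataclass
from typing import BinaryIO, Callable, Iterable, Union
from urllib.parse import unquote

from .errors import (
    ImpossibleTranslationError,
    InvalidLengthError,
    MalformedPayloadError,
    NotASignatureError,
    UnsupportedAlgorithmError,
    UnsupportedCombinationError,
)

__all__ = [
    "HashAlgorithm",
    "ContentSignature",
    "SignaturePrefix",
    "ParsedSignature",
    "VerificationOutcome",
    "WeakAlgorithmWarning",
    "ShortPrefixWarning",
    "register_algorithm",
    "get_algorithm",
    "registered_algorithms",
    "compute_signature",
    "parse_signature",
    "format_signature",
    "translate",
    "truncate_signature",
    "matches",
    "keyspace_size",
    "compute_check_digit",
    "verify_check_digit",
    "verify_content",
]

_CHUNK = 65536
_HEX_RE = re.compile(r"^[0-9a-f]+$")
_B64_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789-_"
)


class WeakAlgorithmWarning(UserWarning):
    """Raised when hashing with an algorithm no longer collision-resistant."""


class ShortPrefixWarning(UserWarning):
    """Raised when a signature is truncated below 16 hex characters."""


# ---------------------------------------------------------------------------
# Algorithm registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HashAlgorithm:
    """A registered cryptographic hash algorithm.

    Parameters
    ----------
    token:
        Short lowercase name used inside identifiers (``sha256``).
    digest_bits:
        Output size in bits; the hex form has ``digest_bits // 4`` characters.
    factory:
        Zero-argument callable returning a hashlib-style object with
        ``update``/``digest`` methods.
    weak:
        True for algorithms kept only for interoperability with legacy
        repositories (md5, sha1); hashing with them emits a warning.
    """

    token: str
    digest_bits: int
    factory: Callable[[], "hashlib._Hash"]
    weak: bool = False

    @property
    def hex_length(self) -> int:
        return self.digest_bits // 4

    @property
    def digest_size(self) -> int:
        return self.digest_bits // 8


_REGISTRY: dict[str, HashAlgorithm] = {}


def register_algorithm(
    token: str,
    digest_bits: int,
    factory: Callable[[], "hashlib._Hash"],
    *,
    weak: bool = False,
) -> HashAlgorithm:
    """Register a hash algorithm under ``token`` (lowercased)."""
    alg = HashAlgorithm(token.lower(), digest_bits, factory, weak)
    _REGISTRY[alg.token] = alg
    return alg


def get_algorithm(token: str) -> HashAlgorithm:
    # RFC 6920 spells tokens with a dash ("sha-256"); fold it away.
    key = token.lower().replace("-", "")
    try:
        return _REGISTRY[key]
    except KeyError:
        raise UnsupportedAlgorithmError(
            f"unknown hash algorithm {token!r}; registered: "
            f"{sorted(_REGISTRY)}"
        ) from None


def registered_algorithms() -> list[str]:
    return sorted(_REGISTRY)


register_algorithm("sha256", 256, hashlib.sha256)
register_algorithm("sha1", 160, hashlib.sha1, weak=True)
register_algorithm("md5", 128, hashlib.md5, weak=True)


# ---------------------------------------------------------------------------
# Core value types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContentSignature:
    """A full digest plus the token of the algorithm that produced it."""

    algorithm: str
    digest: bytes

    def __post_init__(self):
        alg = get_algorithm(self.algorithm)
        object.__setattr__(self, "algorithm", alg.token)
        if len(self.digest) != alg.digest_size:
            raise MalformedPayloadError(
                f"{alg.token} digest must be {alg.digest_size} bytes, "
                f"got {len(self.digest)}"
            )

    @property
    def hex(self) -> str:
        return self.digest.hex()

    @property
    def uri(self) -> str:
        """Canonical content-hash URI (lowercase hex)."""
        return f"hash://{self.algorithm}/{self.hex}"

    @classmethod
    def from_hex(cls, algorithm: str, hex_digest: str) -> "ContentSignature":
        return cls(algorithm, bytes.fromhex(hex_digest))

    def __str__(self) -> str:
        return self.uri


@dataclass(frozen=True)
class SignaturePrefix:
    """A leading fragment of a digest's hex form.

    Truncation trades collision resistance for readability: an ``n``-character
    prefix still spans a keyspace of 16**n.
    """

    algorithm: str
    prefix_hex: str

    def __post_init__(self):
        alg = get_algorithm(self.algorithm)
        object.__setattr__(self, "algorithm", alg.token)
        object.__setattr__(self, "prefix_hex", self.prefix_hex.lower())
        if not _HEX_RE.match(self.prefix_hex):
            raise MalformedPayloadError(
                f"prefix {self.prefix_hex!r} is not lowercase hexadecimal"
            )
        if len(self.prefix_hex) > alg.hex_length:
            raise MalformedPayloadError(
                f"prefix longer ({len(self.prefix_hex)}) than full "
                f"{alg.token} hex length ({alg.hex_length})"
            )

    @property
    def hex(self) -> str:
        return self.prefix_hex

    @property
    def is_full(self) -> bool:
        return len(self.prefix_hex) == get_algorithm(self.algorithm).hex_length

    @property
    def uri(self) -> str:
        return f"hash://{self.algorithm}/{self.prefix_hex}"

    def __str__(self) -> str:
        return self.uri


Payload = Union[ContentSignature, SignaturePrefix]


@dataclass(frozen=True)
class ParsedSignature:
    """Result of parsing one identifier string.

    ``payload`` holds the digest (full or prefix); ``scheme`` and ``encoding``
    record the dialect the string used, so that re-formatting reproduces the
    source text up to scheme-token case and percent-encoding.
    """

    payload: Payload
    scheme: str      # "hash-uri" | "ni" | "nih"
    encoding: str    # "hex" | "base64url"
    source_text: str

    @property
    def algorithm(self) -> str:
        return self.payload.algorithm

    @property
    def is_full(self) -> bool:
        return isinstance(self.payload, ContentSignature)

    @property
    def signature(self) -> ContentSignature:
        """The full signature; raises if only a prefix was given."""
        if not isinstance(self.payload, ContentSignature):
            raise MalformedPayloadError(
                f"{self.source_text!r} is a prefix, not a full signature"
            )
        return self.payload

    @property
    def uri(self) -> str:
        return self.payload.uri


@dataclass(frozen=True)
class VerificationOutcome:
    """Outcome of checking content bytes against a cited signature."""

    status: str  # "match" | "prefix_match" | "mismatch"
    observed: ContentSignature

    def __bool__(self) -> bool:
        return self.status in ("match", "prefix_match")


# ---------------------------------------------------------------------------
# Hashing
# ---------------------------------------------------------------------------

ContentLike = Union[bytes, bytearray, memoryview, BinaryIO, Iterable[bytes]]


def compute_signature(content: ContentLike, algorithm: str = "sha256") -> ContentSignature:
    """Hash ``content`` and return its signature.

    ``content`` may be a bytes-like object, a binary file object (read in
    bounded chunks, so arbitrarily large files use constant memory), or an
    iterable of byte chunks.  Chunking never affects the result: the digest
    depends only on the concatenated byte stream.
    """
    alg = get_algorithm(algorithm)
    if alg.weak:
        warnings.warn(
            f"{alg.token} is not collision-resistant; use it only for "
            "interoperability with legacy repositories",
            WeakAlgorithmWarning,
            stacklevel=2,
        )
    h = alg.factory()
    if isinstance(content, (bytes, bytearray, memoryview)):
        h.update(content)
    elif hasattr(content, "read"):
        while chunk := content.read(_CHUNK):
            h.update(chunk)
    else:
        for chunk in content:
            h.update(chunk)
    return ContentSignature(alg.token, h.digest())


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_HASH_URI_RE = re.compile(r"^hash://([A-Za-z0-9-]+)/(.*)$", re.IGNORECASE)
_NI_RE = re.compile(r"^ni:///([A-Za-z0-9-]+);(.*)$", re.IGNORECASE)
_NIH_RE = re.compile(
    r"^nih:([A-Za-z0-9-]+);([0-9A-Fa-f]+)(?:;([0-9A-Fa-f]))?$", re.IGNORECASE
)
_B64_RE = re.compile(r"^[A-Za-z0-9+/_-]+=*$")


def _decode_payload(alg: HashAlgorithm, raw: str) -> tuple[Payload, str]:
    """Interpret a payload string as hex or base64(url).

    Hexadecimal interpretation takes precedence: any all-hex payload no longer
    than the algorithm's hex length is read as hex (full or prefix).  Anything
    else must be valid base64; the standard alphabet (+, /) is folded onto the
    URL-safe one, padding is optional.
    """
    payload = unquote(raw)
    if not payload:
        raise MalformedPayloadError("empty payload")
    lowered = payload.lower()
    if _HEX_RE.match(lowered):
        if len(lowered) > alg.hex_length:
            raise MalformedPayloadError(
                f"hex payload of {len(lowered)} characters exceeds the "
                f"{alg.hex_length}-character {alg.token} digest"
            )
        if len(lowered) == alg.hex_length:
            return ContentSignature.from_hex(alg.token, lowered), "hex"
        return SignaturePrefix(alg.token, lowered), "hex"
    if not _B64_RE.match(payload):
        raise MalformedPayloadError(
            f"payload {payload!r} is neither hexadecimal nor base64"
        )
    body = payload.replace("+", "-").replace("/", "_").rstrip("=")
    full_chars = (alg.digest_bits + 5) // 6  # unpadded base64 length
    if len(body) > full_chars:
        raise MalformedPayloadError(
            f"base64 payload of {len(body)} characters exceeds the "
            f"{full_chars}-character {alg.token} digest"
        )
    if len(body) == full_chars:
        try:
            digest = base64.urlsafe_b64decode(body + "=" * (-len(body) % 4))
        except Exception as exc:  # binascii.Error
            raise MalformedPayloadError(f"invalid base64 payload {payload!r}") from exc
        if len(digest) != alg.digest_size:
            raise MalformedPayloadError(f"base64 payload {payload!r} has wrong size")
        return ContentSignature(alg.token, digest), "base64url"
    # A shorter payload is a prefix; it must span a whole number of hex
    # characters (two base64 chars carry exactly three hex chars), else some
    # trailing bits are unattributable and the prefix is malformed.
    if len(body) % 2:
        raise MalformedPayloadError(
            f"base64 prefix {payload!r} does not align to hex characters"
        )
    value = 0
    for ch in body:
        value = (value << 6) | _B64_ALPHABET.index(ch)
    n_hex = 3 * len(body) // 2
    return SignaturePrefix(alg.token, format(value, f"0{n_hex}x")), "base64url"


def parse_signature(text: str) -> ParsedSignature:
    """Parse one identifier in any supported dialect.

    Scheme tokens match case-insensitively (prose may capitalize
    ``Hash://…`` at sentence start); the digest is canonicalized to lowercase
    hex internally.  Payloads shorter than the algorithm's full length parse
    as prefixes.  Percent-escapes in the payload are decoded first.
    """
    stripped = text.strip()
    m = _HASH_URI_RE.match(stripped)
    if m:
        alg = get_algorithm(m.group(1))
        payload, encoding = _decode_payload(alg, m.group(2))
        return ParsedSignature(payload, "hash-uri", encoding, stripped)
    m = _NI_RE.match(stripped)
    if m:
        alg = get_algorithm(m.group(1))
        payload, encoding = _decode_payload(alg, m.group(2))
        return ParsedSignature(payload, "ni", encoding, stripped)
    m = _NIH_RE.match(stripped)
    if m:
        alg = get_algorithm(m.group(1))
        payload, encoding = _decode_payload(alg, m.group(2).lower())
        if m.group(3) is not None:
            if not verify_check_digit(m.group(2).lower(), m.group(3).lower()):
                raise MalformedPayloadError(
                    f"check digit {m.group(3)!r} does not verify for "
                    f"payload {m.group(2)!r}"
                )
        return ParsedSignature(payload, "nih", encoding, stripped)
    raise NotASignatureError(
        f"{text!r} does not use a recognized signature scheme "
        "(hash://, ni:///, nih:)"
    )


# ---------------------------------------------------------------------------
# Formatting and translation
# ---------------------------------------------------------------------------

def _hex_to_base64url(hex_str: str) -> str:
    """Bit-level base64url of a hex string (no padding).

    Only defined when the bit length (4 per hex char) is a multiple of 6;
    otherwise the trailing bits of the last character would be unspecified
    and the encoding would not round-trip.
    """
    bits = 4 * len(hex_str)
    if bits % 6:
        raise UnsupportedCombinationError(
            f"a {len(hex_str)}-character hex prefix spans {bits} bits, "
            "not a multiple of 6; cannot encode as base64url"
        )
    value = int(hex_str, 16)
    return "".join(
        _B64_ALPHABET[(value >> shift) & 63]
        for shift in range(bits - 6, -1, -6)
    )


def _encode_payload(payload: Payload, encoding: str) -> str:
    if encoding == "hex":
        return payload.hex
    if encoding == "base64url":
        if isinstance(payload, ContentSignature):
            return base64.urlsafe_b64encode(payload.digest).decode().rstrip("=")
        return _hex_to_base64url(payload.prefix_hex)
    raise UnsupportedCombinationError(f"unknown encoding {encoding!r}")


def _percent_encode(s: str) -> str:
    # The base64 symbols reserved in URIs.
    return s.replace("%", "%25").replace("+", "%2B").replace("/", "%2F").replace("=", "%3D")


def format_signature(
    payload: Payload,
    scheme: str = "hash-uri",
    encoding: str = "hex",
    percent_encode: bool = False,
) -> str:
    """Render a digest (full or prefix) in one of the identifier dialects.

    Hex output is lowercase; base64url output is unpadded.  With
    ``percent_encode`` the URI-reserved symbols ``+``, ``/`` and ``=`` in the
    payload are rendered as percent escapes.  The ``nih`` dialect is hex-only
    and always carries its Luhn mod-16 check digit.
    """
    scheme = scheme.lower().replace("_", "-")
    if scheme in ("hash", "hash-uri"):
        body = _encode_payload(payload, encoding)
        if percent_encode:
            body = _percent_encode(body)
        return f"hash://{payload.algorithm}/{body}"
    if scheme == "ni":
        body = _encode_payload(payload, encoding)
        if percent_encode:
            body = _percent_encode(body)
        return f"ni:///{payload.algorithm};{body}"
    if scheme == "nih":
        if encoding != "hex":
            raise UnsupportedCombinationError(
                "nih identifiers are hex-only (human-oriented dialect)"
            )
        body = payload.hex
        return f"nih:{payload.algorithm};{body};{compute_check_digit(body)}"
    raise UnsupportedCombinationError(f"unknown scheme {scheme!r}")


def translate(
    text: str,
    scheme: str,
    encoding: str = "hex",
    percent_encode: bool = False,
    algorithm: str | None = None,
) -> str:
    """Re-express a signature string in another dialect, digest preserved.

    Translation is purely syntactic: the digest bits never change, and the
    hash algorithm can never change (pass ``algorithm`` to assert the
    expected one; a mismatch raises, since re-expressing an md5 hash as a
    sha256 hash would require re-hashing content this function never sees).
    """
    parsed = parse_signature(text)
    if algorithm is not None and get_algorithm(algorithm).token != parsed.algorithm:
        raise ImpossibleTranslationError(
            f"cannot translate a {parsed.algorithm} signature into "
            f"{algorithm}: hashes from different algorithms are not "
            "interchangeable"
        )
    return format_signature(parsed.payload, scheme, encoding, percent_encode)


# ---------------------------------------------------------------------------
# Truncation and prefix matching
# ---------------------------------------------------------------------------

def truncate_signature(sig: ContentSignature, n_chars: int) -> SignaturePrefix:
    """Keep the first ``n_chars`` hex characters of a signature.

    Shortening trades collision resistance for readability: the keyspace
    drops from 16**64 to 16**n.  Prefixes under 16 characters (keyspace
    below 2**64) trigger a warning, not an error.
    """
    full_len = get_algorithm(sig.algorithm).hex_length
    if not isinstance(n_chars, int) or not 1 <= n_chars <= full_len:
        raise InvalidLengthError(
            f"truncation length must be an integer in 1..{full_len}, got {n_chars!r}"
        )
    if n_chars < 16:
        warnings.warn(
            f"a {n_chars}-character prefix spans only 16^{n_chars} "
            f"({keyspace_size(n_chars):.2e}) possible hashes; collisions "
            "become plausible",
            ShortPrefixWarning,
            stacklevel=2,
        )
    return SignaturePrefix(sig.algorithm, sig.hex[:n_chars])


def matches(candidate: Payload, full: ContentSignature) -> bool:
    """True iff ``candidate`` (full signature or prefix) identifies ``full``.

    A full-length candidate is an equality test; a prefix matches when it is
    a leading substring of the full hex digest under the same algorithm.
    """
    if candidate.algorithm != full.algorithm:
        return False
    return full.hex.startswith(candidate.hex)


def keyspace_size(n_chars: int) -> int:
    """Number of distinct digests an ``n_chars`` hex prefix can express: 16**n."""
    if not isinstance(n_chars, int) or n_chars < 1:
        raise InvalidLengthError(f"prefix length must be a positive integer, got {n_chars!r}")
    return 16 ** n_chars


# ---------------------------------------------------------------------------
# Luhn mod-16 check digits (nih dialect)
# ---------------------------------------------------------------------------

def compute_check_digit(hex_payload: str) -> str:
    """Luhn mod-16 check digit of a hex payload.

    Convention: map each character to its value 0–15; walking right to left,
    double every second value starting with the rightmost, folding doubled
    values v >= 16 to (v div 16) + (v mod 16); the check digit is
    (16 - sum mod 16) mod 16, rendered as one lowercase hex character.
    """
    payload = hex_payload.lower()
    if not payload or not _HEX_RE.match(payload):
        raise MalformedPayloadError(
            f"check digits are defined for nonempty hex payloads, got {hex_payload!r}"
        )
    total = 0
    for i, ch in enumerate(reversed(payload)):
        v = int(ch, 16)
        if i % 2 == 0:
            v *= 2
            if v >= 16:
                v = (v >> 4) + (v & 0xF)
        total += v
    return "0123456789abcdef"[(16 - total % 16) % 16]


def verify_check_digit(hex_payload: str, digit: str) -> bool:
    """True iff ``digit`` is the Luhn mod-16 check digit of ``hex_payload``."""
    return compute_check_digit(hex_payload) == digit.lower()


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------

def verify_content(content: ContentLike, cited: Payload) -> VerificationOutcome:
    """Recompute the content's signature and compare with the cited one.

    A mismatch is a *result*, not an error: it is precisely how content drift
    is detected.  The outcome always carries the observed full signature so
    callers can report what the bytes actually are.
    """
    observed = compute_signature(content, cited.algorithm)
    if isinstance(cited, SignaturePrefix) and not cited.is_full:
        status = "prefix_match" if matches(cited, observed) else "mismatch"
    else:
        status = "match" if observed.hex == cited.hex else "mismatch"
    return VerificationOutcome(status, observed)
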