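"""Signed citations and citable collection descriptions.

A signed citation is a customary citation — creators, date, title, optional
access locations — extended with the content signature of the cited bytes.
Collections of such citations can themselves be serialized to a canonical
byte stream and signed, so that one signature robustly cites every item the
collection references (and, recursively, everything *they* reference).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import EncodingError
from .signatures import (
    ContentSignature,
    ParsedSignature,
    compute_signature,
    parse_signature,
)

__all__ = [
    "AccessEvent",
    "SignedCitation",
    "CollectionDescription",
    "render_signed_citation",
    "extract_signatures",
    "package_collection",
]


@dataclass(frozen=True)
class AccessEvent:
    """One retrieval of the cited content: where and when."""

    location: str
    accessed: str  # ISO 8601 date


@dataclass(frozen=True)
class SignedCitation:
    """A citation carrying exactly one full content signature.

    Access events are optional: the signature is location-agnostic, so a
    citation remains verifiable even when every listed location has rotted.
    """

    creators: tuple[str, ...]
    date: str
    title: str
    signature: ContentSignature
    access_events: tuple[AccessEvent, ...] = ()

    def __init__(self, creators, date, title, signature, access_events=()):
        object.__setattr__(self, "creators", tuple(creators))
        object.__setattr__(self, "date", str(date))
        object.__setattr__(self, "title", title)
        object.__setattr__(self, "signature", signature)
        object.__setattr__(
            self,
            "access_events",
            tuple(
                e if isinstance(e, AccessEvent) else AccessEvent(*e)
                for e in access_events
            ),
        )


@dataclass(frozen=True)
class CollectionDescription:
    """An ordered reference list with its canonical bytes and signature.

    Order matters: the hash of {a, b} differs from the hash of {b, a}, so two
    collections with the same members in different order are distinct content.
    """

    entries: tuple[str, ...]
    canonical_bytes: bytes
    signature: ContentSignature


def render_signed_citation(c: SignedCitation) -> str:
    """Render a citation as one line of prose.

    Layout: ``<Creators>. <Date>. <Title> <hash-uri>`` followed by one
    ``Accessed at <location> on <date>.`` clause per access event.  With no
    access events the text ends right after the signature.
    """
    parts = [f"{', '.join(c.creators)}. {c.date}. {c.title} {c.signature.uri}"]
    for event in c.access_events:
        parts.append(f" Accessed at {event.location} on {event.accessed}.")
    return "".join(parts)


# Candidate tokens for each dialect; trailing sentence punctuation is not
# part of any payload alphabet except that '.' never occurs in payloads,
# so it is safe to strip from the right.
_CANDIDATE_RE = re.compile(
    r"(?:hash://[A-Za-z0-9-]+/[A-Za-z0-9%+/_=-]+"
    r"|ni:///[A-Za-z0-9-]+;[A-Za-z0-9%+/_=-]+"
    r"|nih:[A-Za-z0-9-]+;[0-9A-Fa-f]+(?:;[0-9A-Fa-f])?)",
    re.IGNORECASE,
)
_STRIP_TRAILING = ".,)]}>\"'"


def extract_signatures(
    text: str, diagnostics: list | None = None
) -> list[ParsedSignature]:
    """Find every signature token in free text, in order of appearance.

    Duplicates are preserved (a graph may cite one item twice).  Candidates
    that look like signatures but fail to parse are skipped; pass a list as
    ``diagnostics`` to collect ``(token, error)`` pairs for them.
    """
    found: list[ParsedSignature] = []
    for m in _CANDIDATE_RE.finditer(text):
        token = m.group(0).rstrip(_STRIP_TRAILING)
        try:
            found.append(parse_signature(token))
        except Exception as exc:
            if diagnostics is not None:
                diagnostics.append((token, exc))
    return found


def package_collection(
    entries: Sequence[str] | Iterable[str],
    *,
    sort: bool = False,
    allow_utf8: bool = False,
    algorithm: str = "sha256",
) -> CollectionDescription:
    """Serialize citation texts into one canonical, signable byte stream.

    Canonical form: entries joined by one blank line, LF line endings
    (CR/CRLF normalized), a single trailing LF; an empty entry list yields
    the empty byte stream.  Entries must be ASCII — the reference-list format
    is meant to survive copy-paste across systems — unless ``allow_utf8``
    explicitly relaxes that.  With ``sort`` the entries are ordered
    lexicographically first, giving a canonical *set* representation for
    collections whose order carries no meaning.
    """
    items = [e.replace("\r\n", "\n").replace("\r", "\n") for e in entries]
    if sort:
        items = sorted(items)
    codec = "utf-8" if allow_utf8 else "ascii"
    encoded = []
    for i, item in enumerate(items):
        try:
            encoded.append(item.encode(codec))
        except UnicodeEncodeError as exc:
            raise EncodingError(
                f"entry {i} is not {codec.upper()}-encodable: {item[:60]!r}"
            ) from exc
    canonical = b"\n\n".join(encoded) + b"\n" if encoded else b""
    return CollectionDescription(
        entries=tuple(items),
        canonical_bytes=canonical,
        signature=compute_signature(canonical, algorithm),
    )
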