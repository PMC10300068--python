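"""Content repository, location registry, and verified resolution.

The two services a signed-citation ecosystem needs are deliberately small:

* a *content repository* stores bytes under their own signature and returns
  them only after re-verification — it can never silently serve drifted
  content;
* a *content registry* keeps lightweight append-only records, each just a
  timestamp, a URL, and the signature observed there (or a failure marker),
  from which link rot and content drift are classified and alternative
  locations discovered.

Resolution ties them together: given a signature, try the local store, then
every registry-known location through an injectable fetcher, verifying every
candidate's bytes before returning them.
"""

from __future__ import annotations

import enum
import os
import tempfile
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Sequence, Union

from .errors import (
    AmbiguousPrefixError,
    CorruptionError,
    InvalidComparisonError,
    NoAliasError,
    NotFoundError,
    StorageError,
    UnresolvableError,
    ValidationError,
)
from .signatures import (
    ContentSignature,
    SignaturePrefix,
    VerificationOutcome,
    compute_signature,
    get_algorithm,
    matches,
    parse_signature,
    verify_content,
)

__all__ = [
    "RegistryRecord",
    "DriftStatus",
    "ResolvedContent",
    "Attempt",
    "ContentStore",
    "Registry",
    "classify_observation",
    "classify_location_history",
    "StoreSource",
    "RegistrySource",
    "HttpFetcher",
    "resolve",
    "resolve_location",
]

FAILED = "FAILED"  # registry marker for an unreachable location


# ---------------------------------------------------------------------------
# Records and statuses
# ---------------------------------------------------------------------------

def _parse_timestamp(value: Union[str, datetime]) -> datetime:
    if isinstance(value, datetime):
        dt = value
    else:
        try:
            dt = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
        except ValueError as exc:
            raise ValidationError(f"unparseable timestamp {value!r}") from exc
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def _validate_uri(location: str) -> str:
    parts = urllib.parse.urlparse(location)
    if not parts.scheme or (not parts.netloc and not parts.path):
        raise ValidationError(f"{location!r} is not a valid URI")
    return location


@dataclass(frozen=True, order=True)
class RegistryRecord:
    """One observation: at ``observed_at`` the ``location`` served content
    with ``outcome`` signature, or was unreachable (``outcome is None``)."""

    observed_at: datetime
    location: str
    outcome: Optional[ContentSignature]

    @property
    def ok(self) -> bool:
        return self.outcome is not None

    def outcome_text(self) -> str:
        return self.outcome.uri if self.outcome else FAILED


class DriftStatus(enum.Enum):
    """Classification of one location transition between two observations."""

    INITIAL = "initial"
    UNCHANGED = "unchanged"
    CONTENT_DRIFT = "content_drift"
    LINK_ROT = "link_rot"


def classify_observation(
    previous: Optional[RegistryRecord], current: RegistryRecord
) -> DriftStatus:
    """Classify what happened at a location between two observations.

    Truth table (previous outcome → current outcome):

    ==============  ==========  =================
    previous        current     status
    ==============  ==========  =================
    (none)          success     INITIAL
    (none)          failure     INITIAL
    success         same sig    UNCHANGED
    success         other sig   CONTENT_DRIFT
    success         failure     LINK_ROT
    failure         failure     LINK_ROT
    failure         success     INITIAL (re-observed; nothing to compare)
    ==============  ==========  =================

    If the bits differ, the content must differ — drift detection needs no
    judgement call beyond comparing signatures.
    """
    if previous is not None and previous.location != current.location:
        raise InvalidComparisonError(
            f"cannot compare observations of {previous.location!r} "
            f"and {current.location!r}"
        )
    if previous is None or (not previous.ok and current.ok):
        return DriftStatus.INITIAL
    if not current.ok:
        return DriftStatus.LINK_ROT
    if previous.outcome == current.outcome:
        return DriftStatus.UNCHANGED
    return DriftStatus.CONTENT_DRIFT


def classify_location_history(records: Sequence[RegistryRecord]) -> DriftStatus:
    """Summarize a location's chronological record sequence.

    The first change event wins: a location is CONTENT_DRIFT if any
    transition drifted before any rot, LINK_ROT if it rotted first,
    UNCHANGED if observations repeated the same signature, INITIAL if only
    one observation exists.
    """
    ordered = sorted(records, key=lambda r: r.observed_at)
    previous: Optional[RegistryRecord] = None
    summary = DriftStatus.INITIAL
    for record in ordered:
        status = classify_observation(previous, record)
        if status in (DriftStatus.CONTENT_DRIFT, DriftStatus.LINK_ROT):
            return status
        if status is DriftStatus.UNCHANGED:
            summary = DriftStatus.UNCHANGED
        previous = record
    return summary


@dataclass(frozen=True)
class ResolvedContent:
    """Bytes returned by the store or a resolver, always post-verification.

    The invariant is absolute: ``verification.status == "match"`` (or
    ``prefix_match`` for prefix queries) — unverified bytes are never
    returned to a caller.
    """

    content: bytes
    source: str
    verification: VerificationOutcome

    @property
    def signature(self) -> ContentSignature:
        return self.verification.observed


# ---------------------------------------------------------------------------
# Content store
# ---------------------------------------------------------------------------

class ContentStore:
    """Filesystem content repository addressed by signature.

    Layout: ``<root>/<algorithm>/<hex[0:2]>/<hex[2:4]>/<hex>`` — a two-level
    fan-out that keeps directory sizes bounded (standard content-addressed
    practice; digests shorter than 4 hex characters fall back to a flat
    layout).  Writes are atomic (temp file + rename) and idempotent; reads
    re-hash the bytes and raise :class:`CorruptionError` on any mismatch
    rather than ever returning drifted content.
    """

    def __init__(self, root: Union[str, Path], algorithm: str = "sha256"):
        self.root = Path(root)
        self.algorithm = get_algorithm(algorithm).token
        try:
            self.root.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise StorageError(f"cannot create store root {self.root}: {exc}") from exc

    def _path(self, sig: ContentSignature) -> Path:
        h = sig.hex
        if len(h) >= 4:
            return self.root / sig.algorithm / h[0:2] / h[2:4] / h
        return self.root / sig.algorithm / h

    def put(self, content, algorithm: Optional[str] = None) -> ContentSignature:
        """Store bytes under their own signature; returns the signature.

        Re-putting identical content is a no-op.  Finding different bytes
        already filed under the same signature raises a corruption alarm
        (with a collision-resistant hash this indicates on-disk tampering,
        not a genuine collision).
        """
        if not isinstance(content, (bytes, bytearray, memoryview)):
            content = content.read() if hasattr(content, "read") else b"".join(content)
        content = bytes(content)
        sig = compute_signature(content, algorithm or self.algorithm)
        path = self._path(sig)
        if path.exists():
            if path.read_bytes() != content:
                raise CorruptionError(
                    f"store already holds different bytes under {sig.uri}"
                )
            return sig
        try:
            path.parent.mkdir(parents=True, exist_ok=True)
            fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp-")
            with os.fdopen(fd, "wb") as fh:
                fh.write(content)
            os.replace(tmp, path)
        except OSError as exc:
            raise StorageError(f"failed to store {sig.uri}: {exc}") from exc
        return sig

    def _resolve_prefix(self, prefix: SignaturePrefix) -> ContentSignature:
        hits = [
            s for s in self.iter_signatures(prefix.algorithm)
            if s.hex.startswith(prefix.prefix_hex)
        ]
        if not hits:
            raise NotFoundError(f"no stored content matches {prefix.uri}")
        if len(hits) > 1:
            raise AmbiguousPrefixError(prefix.uri, sorted(s.uri for s in hits))
        return hits[0]

    def get(self, sig: Union[ContentSignature, SignaturePrefix, str]) -> ResolvedContent:
        """Return verified bytes for a signature or unambiguous prefix."""
        if isinstance(sig, str):
            sig = parse_signature(sig).payload
        requested = sig
        if isinstance(sig, SignaturePrefix):
            sig = self._resolve_prefix(sig)
        path = self._path(sig)
        if not path.exists():
            raise NotFoundError(f"no stored content for {sig.uri}")
        content = path.read_bytes()
        outcome = verify_content(content, requested)
        if outcome.status == "mismatch":
            raise CorruptionError(
                f"stored bytes for {sig.uri} hash to {outcome.observed.uri}"
            )
        return ResolvedContent(content, str(path), outcome)

    def __contains__(self, sig: ContentSignature) -> bool:
        return self._path(sig).exists()

    def iter_signatures(self, algorithm: Optional[str] = None) -> Iterator[ContentSignature]:
        tokens = [get_algorithm(algorithm).token] if algorithm else None
        for alg_dir in sorted(self.root.iterdir()) if self.root.exists() else []:
            if not alg_dir.is_dir():
                continue
            if tokens and alg_dir.name not in tokens:
                continue
            for path in sorted(alg_dir.rglob("*")):
                if path.is_file() and not path.name.startswith("."):
                    try:
                        yield ContentSignature.from_hex(alg_dir.name, path.name)
                    except Exception:
                        continue


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

class Registry:
    """Append-only log of (timestamp, location, signature-or-FAILED) rows.

    Serialized as TSV with a header; timestamps are UTC ISO 8601 with
    seconds.  Records are never mutated or removed: older signatures for a
    location remain queryable as its version history.
    """

    COLUMNS = ("observed_at", "location", "outcome")

    def __init__(self, records: Iterable[RegistryRecord] = ()):
        self.records: list[RegistryRecord] = list(records)

    def register(
        self,
        location: str,
        outcome: Union[ContentSignature, str, None],
        observed_at: Union[str, datetime],
    ) -> RegistryRecord:
        """Append one observation; ``outcome`` may be a signature, its text
        form, or None/"FAILED" for an unreachable location."""
        _validate_uri(location)
        when = _parse_timestamp(observed_at)
        if isinstance(outcome, str):
            outcome = None if outcome == FAILED else parse_signature(outcome).signature
        record = RegistryRecord(when, location, outcome)
        self.records.append(record)
        return record

    def by_location(self, location: str) -> list[RegistryRecord]:
        return sorted(
            (r for r in self.records if r.location == location),
            key=lambda r: r.observed_at,
        )

    def by_signature(self, sig: ContentSignature) -> list[RegistryRecord]:
        """Every observation, at any location, that served this content."""
        return sorted(
            (r for r in self.records if r.outcome == sig),
            key=lambda r: r.observed_at,
        )

    def locations(self) -> list[str]:
        return sorted({r.location for r in self.records})

    def latest_per_location(self) -> list[RegistryRecord]:
        latest: dict[str, RegistryRecord] = {}
        for r in self.records:
            old = latest.get(r.location)
            if old is None or r.observed_at >= old.observed_at:
                latest[r.location] = r
        return [latest[loc] for loc in sorted(latest)]

    def latest_successful(self, location: str) -> Optional[RegistryRecord]:
        hits = [r for r in self.by_location(location) if r.ok]
        return hits[-1] if hits else None

    def classify_latest(self) -> dict[str, DriftStatus]:
        """Latest-vs-previous classification for every known location."""
        out = {}
        for loc in self.locations():
            history = self.by_location(loc)
            prev = history[-2] if len(history) > 1 else None
            out[loc] = classify_observation(prev, history[-1])
        return out

    def summarize(self) -> dict[str, DriftStatus]:
        """Whole-history classification for every known location."""
        return {
            loc: classify_location_history(self.by_location(loc))
            for loc in self.locations()
        }

    # -- serialization ------------------------------------------------------

    def save_tsv(self, path: Union[str, Path]) -> None:
        lines = ["\t".join(self.COLUMNS)]
        for r in self.records:
            stamp = r.observed_at.strftime("%Y-%m-%dT%H:%M:%SZ")
            lines.append(f"{stamp}\t{r.location}\t{r.outcome_text()}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="ascii")

    @classmethod
    def load_tsv(cls, path: Union[str, Path]) -> "Registry":
        reg = cls()
        with open(path, encoding="ascii") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != cls.COLUMNS:
                raise ValidationError(f"unexpected registry header {header!r} in {path}")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValidationError(f"{path}:{lineno}: expected 3 fields")
                reg.register(fields[1], fields[2], fields[0])
        return reg


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Attempt:
    """One candidate tried during resolution and how it went."""

    source: str
    outcome: str  # "match" | "mismatch" | "unavailable"
    observed: Optional[ContentSignature] = None
    detail: str = ""


Fetcher = Callable[[str], bytes]


class HttpFetcher:
    """Minimal HTTP(S) fetcher plug-in with a timeout; raises on any failure.

    Network use is always opt-in: nothing in the library constructs this
    fetcher implicitly.
    """

    def __init__(self, timeout: float = 30.0):
        self.timeout = timeout

    def __call__(self, url: str) -> bytes:
        with urllib.request.urlopen(url, timeout=self.timeout) as resp:
            return resp.read()


class StoreSource:
    """Resolution source backed by a local content store."""

    def __init__(self, store: ContentStore):
        self.store = store

    def candidates(self, sig: ContentSignature) -> Iterator[tuple[str, Optional[bytes], str]]:
        path = self.store._path(sig)
        if path.exists():
            yield str(path), path.read_bytes(), ""
        else:
            yield str(path), None, "not in local store"


class RegistrySource:
    """Resolution source that fetches from registry-known locations.

    Locations that ever served the signature are tried most-recent first
    (the registry itself does not rank locations; recency is this package's
    documented tie-break).
    """

    def __init__(self, registry: Registry, fetcher: Fetcher):
        self.registry = registry
        self.fetcher = fetcher

    def candidates(self, sig: ContentSignature) -> Iterator[tuple[str, Optional[bytes], str]]:
        records = sorted(
            self.registry.by_signature(sig),
            key=lambda r: r.observed_at,
            reverse=True,
        )
        seen: set[str] = set()
        for record in records:
            if record.location in seen:
                continue
            seen.add(record.location)
            try:
                yield record.location, self.fetcher(record.location), ""
            except Exception as exc:
                yield record.location, None, f"fetch failed: {exc}"


Source = Union[ContentStore, StoreSource, RegistrySource]


def _as_source(source: Source):
    return StoreSource(source) if isinstance(source, ContentStore) else source


def resolve(
    sig: Union[ContentSignature, str], sources: Sequence[Source]
) -> ResolvedContent:
    """Find verified bytes for a signature across an ordered source list.

    Every candidate's bytes are re-hashed; the first verified match is
    returned together with its provenance.  If all sources are exhausted an
    :class:`UnresolvableError` is raised carrying the full attempt log, so
    callers can distinguish drifted copies from plain unavailability.
    """
    if isinstance(sig, str):
        sig = parse_signature(sig).signature
    if not sources:
        raise UnresolvableError(f"no sources given for {sig.uri}", [])
    attempts: list[Attempt] = []
    for source in sources:
        for where, content, detail in _as_source(source).candidates(sig):
            if content is None:
                attempts.append(Attempt(where, "unavailable", None, detail))
                continue
            outcome = verify_content(content, sig)
            if outcome.status == "match":
                return ResolvedContent(content, where, outcome)
            attempts.append(
                Attempt(where, "mismatch", outcome.observed, "content drift")
            )
    raise UnresolvableError(
        f"{sig.uri} could not be resolved from {len(attempts)} candidate(s)",
        attempts,
    )


def resolve_location(
    url: str, registry: Registry, sources: Sequence[Source]
) -> ResolvedContent:
    """Treat a URL as an alias for the content last observed there.

    The URL itself is *not* re-fetched first: it is mapped to the signature
    of its most recent successful observation, and that signature is
    resolved through the usual verified path.  This keeps workflows pinned
    to the cited bytes even after the live location drifts.
    """
    record = registry.latest_successful(url)
    if record is None:
        raise NoAliasError(
            f"{url!r} has no successful observation in the registry; "
            "cannot alias it to a content signature"
        )
    return resolve(record.outcome, sources)
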