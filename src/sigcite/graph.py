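"""Recursive citation graphs with PROV acquisition provenance.

Content that embeds the signatures of other content forms a Merkle-style
directed acyclic graph: each edge is a hash of exact bytes, so altering any
node's bytes changes the signature required to cite it and provably detaches
it from every existing citation path.  This module builds and re-verifies
such graphs from a resolver, renders human-readable reference lists from
them, and records how content was acquired as N-Quads using a minimal PROV
dialect (``prov:used``, ``prov:generated``, ``prov:startedAtTime``).

Emitted provenance uses only IRIs and URNs (no blank nodes) so the output
is byte-stable and independently re-hashable.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Mapping, Optional, Union

from rdflib import Dataset

from .citations import SignedCitation, extract_signatures, render_signed_citation
from .errors import (
    ContradictionError,
    CorruptionError,
    NotFoundError,
    UnresolvableError,
    ValidationError,
)
from .signatures import ContentSignature, parse_signature
from .store import ContentStore, ResolvedContent, resolve as _resolve_sig

__all__ = [
    "PROV",
    "AcquisitionEvent",
    "CitationGraph",
    "VerificationReport",
    "RelationClaim",
    "new_activity_id",
    "record_acquisition",
    "build_graph",
    "verify_graph",
    "render_reference_list",
    "tally_resources",
    "assert_relation",
]

PROV = "http://www.w3.org/ns/prov#"
_XSD_DATETIME = "http://www.w3.org/2001/XMLSchema#dateTime"
_RELATION_IRIS = {
    "same-as": "http://www.w3.org/2002/07/owl#sameAs",
    "different-from": "http://www.w3.org/2002/07/owl#differentFrom",
    "derived-from": PROV + "wasDerivedFrom",
}
_IRI_FORBIDDEN = set(' <>"{}|^`\\')


def _check_iri(iri: str) -> str:
    if not iri or any(c in _IRI_FORBIDDEN for c in iri) or ":" not in iri:
        raise ValidationError(f"{iri!r} is not a legal IRI for N-Quads output")
    return iri


def _timestamp(value: Union[str, datetime]) -> str:
    if isinstance(value, datetime):
        if value.tzinfo is None:
            value = value.replace(tzinfo=timezone.utc)
        return value.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    return str(value)


def _escape_literal(text: str) -> str:
    return (
        text.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
    )


def new_activity_id() -> str:
    """A fresh ``urn:uuid:…`` activity identifier."""
    return f"urn:uuid:{uuid.uuid4()}"


# ---------------------------------------------------------------------------
# Acquisition provenance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionEvent:
    """One content acquisition: which location was read, what signature the
    retrieved bytes had, and when the activity started."""

    used_location: str
    generated: ContentSignature
    started_at: Union[str, datetime]
    activity_id: str = field(default_factory=new_activity_id)


def record_acquisition(event: AcquisitionEvent) -> str:
    """Serialize one acquisition as exactly three N-Quads lines.

    The graph label (fourth position) is the activity URN itself, making
    each acquisition a self-contained named graph.  Line order is fixed:
    used, generated, startedAtTime.
    """
    act = _check_iri(event.activity_id)
    loc = _check_iri(event.used_location)
    stamp = _escape_literal(_timestamp(event.started_at))
    return (
        f"<{act}> <{PROV}used> <{loc}> <{act}> .\n"
        f"<{act}> <{PROV}generated> <{event.generated.uri}> <{act}> .\n"
        f'<{act}> <{PROV}startedAtTime> "{stamp}"^^<{_XSD_DATETIME}> <{act}> .\n'
    )


# ---------------------------------------------------------------------------
# Graph building and verification
# ---------------------------------------------------------------------------

@dataclass
class CitationGraph:
    """Signature nodes plus containment edges extracted from verified bytes.

    ``nodes`` is kept in first-visit (depth-first) order; ``edges`` are
    ``(container uri, referenced uri, medium)`` with medium ``"text"`` or
    ``"rdf"``; ``unresolved`` lists ``(uri, reason)`` for cited content that
    could not be verified, without aborting traversal.
    """

    root: str
    nodes: list[str] = field(default_factory=list)
    edges: list[tuple[str, str, str]] = field(default_factory=list)
    unresolved: list[tuple[str, str]] = field(default_factory=list)

    @property
    def node_set(self) -> set[str]:
        return set(self.nodes)

    def children(self, uri: str) -> list[str]:
        return [ref for container, ref, _ in self.edges if container == uri]

    def leaves(self) -> list[str]:
        containers = {container for container, _, _ in self.edges}
        return [n for n in self.nodes if n not in containers]


@dataclass(frozen=True)
class VerificationReport:
    """Per-node re-verification outcome for a citation graph.

    Statuses: ``verified`` (bytes resolved and hash matches), ``drifted``
    (bytes were produced somewhere but no longer hash to the citation),
    ``unreachable`` (no source produced bytes at all).
    """

    root: str
    statuses: dict[str, str]

    @property
    def counts(self) -> dict[str, int]:
        out = {"verified": 0, "drifted": 0, "unreachable": 0}
        for status in self.statuses.values():
            out[status] = out.get(status, 0) + 1
        return out

    @property
    def all_verified(self) -> bool:
        return all(s == "verified" for s in self.statuses.values())

    def with_status(self, status: str) -> list[str]:
        return [uri for uri, s in self.statuses.items() if s == status]


Resolver = Union[ContentStore, Callable[[ContentSignature], ResolvedContent]]


def _resolver_fn(resolver: Resolver):
    if isinstance(resolver, ContentStore):
        return resolver.get
    if hasattr(resolver, "resolve"):
        return resolver.resolve
    if isinstance(resolver, (list, tuple)):
        sources = list(resolver)
        return lambda sig: _resolve_sig(sig, sources)
    return resolver


def _looks_like_nquads(text: str) -> bool:
    try:
        ds = Dataset()
        ds.parse(data=text, format="nquads")
        return len(list(ds.quads((None, None, None, None)))) > 0
    except Exception:
        return False


def _extract_children(content: bytes) -> tuple[list[ContentSignature], str]:
    """Pull embedded full signatures out of verified content, in order.

    RDF content (parseable N-Quads) is medium ``"rdf"``: hash-scheme IRIs
    appear in subject/object position but are also present verbatim in the
    serialization, so a single in-order textual scan covers IRIs and
    literals alike.  Any other decodable text is scanned the same way with
    medium ``"text"``.  Undecodable bytes are an opaque leaf.  Prefix-only
    tokens are ignored for traversal: a prefix does not identify unique
    bytes to recurse into.
    """
    try:
        text = content.decode("utf-8")
    except UnicodeDecodeError:
        return [], "binary"
    medium = "rdf" if _looks_like_nquads(text) else "text"
    children = [p.payload for p in extract_signatures(text) if p.is_full]
    return children, medium


def _walk(root: Union[ContentSignature, str], resolver: Resolver):
    """Shared depth-first traversal; yields (uri, resolved-or-None, reason,
    children) with a visited set guaranteeing termination."""
    if isinstance(root, str):
        root = parse_signature(root).signature
    fn = _resolver_fn(resolver)
    visited: set[str] = set()
    stack: list[ContentSignature] = [root]
    while stack:
        sig = stack.pop()
        if sig.uri in visited:
            continue
        visited.add(sig.uri)
        try:
            resolved = fn(sig)
        except CorruptionError as exc:
            yield sig, None, "drifted", [], str(exc)
            continue
        except UnresolvableError as exc:
            drifted = any(a.outcome == "mismatch" for a in exc.attempts)
            yield sig, None, "drifted" if drifted else "unreachable", [], str(exc)
            continue
        except NotFoundError as exc:
            yield sig, None, "unreachable", [], str(exc)
            continue
        children, medium = _extract_children(resolved.content)
        yield sig, resolved, medium, children, ""
        for child in reversed(children):
            if child.uri not in visited:
                stack.append(child)


def build_graph(root: Union[ContentSignature, str], resolver: Resolver) -> CitationGraph:
    """Build the citation graph reachable from ``root``.

    The root is resolved and verified, its embedded signatures extracted,
    and the traversal recurses depth-first in order of appearance.  A
    visited set makes traversal terminate on any input, and unresolvable
    children are recorded without stopping the walk.  An unresolvable root
    yields an empty graph with the root listed in ``unresolved``.
    """
    root_uri = (
        root.uri if isinstance(root, ContentSignature)
        else parse_signature(root).signature.uri
    )
    graph = CitationGraph(root=root_uri)
    for sig, resolved, medium_or_reason, children, _detail in _walk(root, resolver):
        if resolved is None:
            graph.unresolved.append((sig.uri, "not-found" if medium_or_reason == "unreachable" else medium_or_reason))
            continue
        graph.nodes.append(sig.uri)
        for child in children:
            graph.edges.append((sig.uri, child.uri, medium_or_reason))
    return graph


def verify_graph(root: Union[ContentSignature, str], resolver: Resolver) -> VerificationReport:
    """Re-verify every node reachable from ``root``.

    Only verified content is expanded (drifted bytes cannot be trusted to
    name their children), so the report covers exactly the subgraph whose
    integrity chain from the root is intact, plus the first failing node on
    each broken path.  For a fixed resolver state the report is
    deterministic.
    """
    root_uri = (
        root.uri if isinstance(root, ContentSignature)
        else parse_signature(root).signature.uri
    )
    statuses: dict[str, str] = {}
    for sig, resolved, medium_or_reason, _children, _detail in _walk(root, resolver):
        statuses[sig.uri] = "verified" if resolved is not None else medium_or_reason
    return VerificationReport(root_uri, statuses)


# ---------------------------------------------------------------------------
# Rendering and tallying
# ---------------------------------------------------------------------------

MetadataLookup = Union[Mapping[str, Mapping], Callable[[str], Optional[Mapping]]]


def render_reference_list(graph: CitationGraph, metadata: MetadataLookup = None) -> str:
    """Render one signed citation per leaf, in traversal order.

    ``metadata`` maps a node's canonical hash URI to citation fields
    (``creators``, ``date``, ``title``, ``access_events``); leaves without
    metadata get explicit placeholders, never silence.  The returned text
    uses the collection canonical form (blank-line separated, trailing LF)
    so it can be signed and cited as a new collection description.
    """
    if metadata is None:
        lookup = lambda uri: None
    elif callable(metadata):
        lookup = metadata
    else:
        lookup = metadata.get
    entries = []
    for uri in graph.leaves():
        meta = lookup(uri) or {}
        citation = SignedCitation(
            creators=meta.get("creators", ("Unknown creator",)),
            date=meta.get("date", "n.d."),
            title=meta.get("title", "Untitled content."),
            signature=parse_signature(uri).signature,
            access_events=meta.get("access_events", ()),
        )
        entries.append(render_signed_citation(citation))
    return "\n\n".join(entries) + "\n" if entries else ""


def tally_resources(
    quads_text: str, pattern: str, diagnostics: list | None = None
) -> int:
    """Count distinct resource IRIs matching ``pattern`` in an N-Quads text.

    Subjects and objects are both considered; matching is by substring.
    Lines are parsed independently so one malformed line is skipped (and
    reported through ``diagnostics`` as ``(line number, line)``) without
    discarding the rest of the document.
    """
    seen: set[str] = set()
    for lineno, line in enumerate(quads_text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        ds = Dataset()
        try:
            ds.parse(data=stripped, format="nquads")
            quads = list(ds.quads((None, None, None, None)))
            if not quads:
                raise ValueError("no quad on line")
        except Exception:
            if diagnostics is not None:
                diagnostics.append((lineno, line))
            continue
        for s, _p, o, _g in quads:
            for term in (s, o):
                term_text = str(term)
                if pattern in term_text:
                    seen.add(term_text)
    return len(seen)


# ---------------------------------------------------------------------------
# Relation claims
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelationClaim:
    """An assertion about two distinct digital assets.

    Claims are opinions *about* content, recorded separately from the
    structural graph: they never alter what a signature identifies.  The
    relation is one of ``same-as``, ``different-from``, ``derived-from``,
    or any custom IRI.
    """

    subject: ContentSignature
    relation: str
    object: ContentSignature
    asserter: str
    asserted_at: Union[str, datetime]


def assert_relation(claim: RelationClaim) -> str:
    """Serialize a relation claim as N-Quads.

    Emits the claim triple with hash-URI subject and object inside a
    deterministic claim-specific named graph, plus attribution and timestamp
    quads.  ``different-from`` between equal signatures is a contradiction:
    one signature identifies exactly one byte stream.
    """
    relation_iri = _RELATION_IRIS.get(claim.relation, claim.relation)
    _check_iri(relation_iri)
    if relation_iri == _RELATION_IRIS["different-from"] and claim.subject == claim.object:
        raise ContradictionError(
            f"{claim.subject.uri} cannot be different from itself: a content "
            "signature identifies exactly one byte stream"
        )
    stamp = _timestamp(claim.asserted_at)
    key = f"{claim.subject.uri}|{relation_iri}|{claim.object.uri}|{claim.asserter}|{stamp}"
    ctx = f"urn:uuid:{uuid.uuid5(uuid.NAMESPACE_URL, key)}"
    asserter = _escape_literal(claim.asserter)
    return (
        f"<{claim.subject.uri}> <{relation_iri}> <{claim.object.uri}> <{ctx}> .\n"
        f'<{ctx}> <{PROV}wasAttributedTo> "{asserter}" <{ctx}> .\n'
        f'<{ctx}> <{PROV}generatedAtTime> "{_escape_literal(stamp)}"^^<{_XSD_DATETIME}> <{ctx}> .\n'
    )
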