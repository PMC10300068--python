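"""Deterministic synthetic corpora and a simulated drifting/rotting web.

Two generators back the test surface of the whole package:

* :func:`generate_corpus` builds a nested collection tree — random byte
  blobs as leaves, signed collection descriptions (alternating plain-text
  reference lists and N-Quads provenance per level) as internal nodes — and
  stores everything in a content store, returning a signed citation of the
  root.  This mirrors the structure of real image-collection manifests:
  one signature at the root robustly cites every item below it.

* :func:`simulate_timeline` emulates a set of web locations observed over
  several epochs, with a seeded fraction of locations drifting (bytes
  altered) or rotting (location failing) at a random epoch.  The injected
  truth is returned alongside the registry of observations, so classifiers
  can be scored against known rates.

A single integer seed drives one ``random.Random`` generator per call: equal
specs give byte-identical corpora, timelines, and registries across runs and
platforms.  The simulated alteration under drift is a minimal one: a single
seeded byte of the original content is flipped, the smallest perturbation a
copy error can make and still the easiest for a hash to catch.
"""

from __future__ import annotations

import random
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional

from .citations import (
    AccessEvent,
    SignedCitation,
    package_collection,
    render_signed_citation,
)
from .errors import ValidationError
from .graph import AcquisitionEvent, record_acquisition
from .signatures import ContentSignature, compute_signature
from .store import ContentStore, DriftStatus, Registry

__all__ = [
    "CorpusSpec",
    "CorpusNode",
    "Corpus",
    "TimelineSpec",
    "LocationTruth",
    "SimulatedWeb",
    "generate_corpus",
    "simulate_timeline",
    "recovered_rates",
]


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusSpec:
    """Shape of a synthetic collection tree.

    ``depth`` counts tiers including the root: a depth-3, fanout-3 tree has
    1 + 3 + 9 = 13 nodes with the 9 blobs as leaves; depth 1 is a single
    blob.  ``blob_size`` bounds the leaf sizes (bytes, inclusive): 64–4096
    by default — large enough that seeded blobs are pairwise distinct,
    small enough for fast suites.
    """

    depth: int = 3
    fanout: int = 3
    blob_size: tuple[int, int] = (64, 4096)
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1 or self.fanout < 1:
            raise ValidationError("depth and fanout must both be >= 1")
        lo, hi = self.blob_size
        if not 1 <= lo <= hi:
            raise ValidationError(f"bad blob size range {self.blob_size}")

    @property
    def n_nodes(self) -> int:
        return sum(self.fanout ** i for i in range(self.depth))


@dataclass
class CorpusNode:
    signature: ContentSignature
    medium: str  # "blob" | "text" | "rdf"
    children: list["CorpusNode"] = field(default_factory=list)


@dataclass
class Corpus:
    """A generated corpus: the tree, the store holding it, and a signed
    citation of the root by which the whole corpus is citable."""

    spec: CorpusSpec
    store: ContentStore
    root: CorpusNode
    root_citation: SignedCitation

    @property
    def nodes(self) -> list[CorpusNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    @property
    def leaves(self) -> list[CorpusNode]:
        return [n for n in self.nodes if not n.children]


def _leaf_metadata(node: CorpusNode, index: int) -> dict:
    short = node.signature.hex[:12]
    return {
        "creators": ("Synthetic Corpus Generator",),
        "date": "2021",
        "title": f"Synthetic item {index} ({short}).",
        "access_events": (
            AccessEvent(
                f"https://corpus.example.org/items/{short}", "2021-12-07"
            ),
        ),
    }


def generate_corpus(spec: CorpusSpec, store: ContentStore) -> Corpus:
    """Generate and store a nested collection tree; return its root citation.

    Leaves are seeded random blobs.  Internal tiers alternate media: even
    tiers are ASCII reference lists of their children's signed citations,
    odd tiers are N-Quads acquisition provenance naming the children as
    ``prov:generated`` objects.  Either way every child's full signature is
    embedded in the parent's bytes, so the root signature transitively
    commits to every byte in the corpus.
    """
    rng = random.Random(spec.seed)
    counter = [0]

    def build(level: int) -> CorpusNode:
        if level == spec.depth - 1:
            size = rng.randint(*spec.blob_size)
            blob = rng.randbytes(size)
            return CorpusNode(store.put(blob), "blob")
        children = [build(level + 1) for _ in range(spec.fanout)]
        if level % 2 == 0:
            entries = []
            for child in children:
                counter[0] += 1
                meta = _leaf_metadata(child, counter[0])
                entries.append(
                    render_signed_citation(
                        SignedCitation(signature=child.signature, **meta)
                    )
                )
            content = package_collection(entries).canonical_bytes
            medium = "text"
        else:
            lines = []
            for child in children:
                activity = f"urn:uuid:{uuid.UUID(int=rng.getrandbits(128), version=4)}"
                lines.append(
                    record_acquisition(
                        AcquisitionEvent(
                            used_location=(
                                "https://corpus.example.org/items/"
                                f"{child.signature.hex[:12]}"
                            ),
                            generated=child.signature,
                            started_at="2021-12-07T00:00:00Z",
                            activity_id=activity,
                        )
                    )
                )
            content = "".join(lines).encode("ascii")
            medium = "rdf"
        return CorpusNode(store.put(content), medium, children)

    root = build(0)
    citation = SignedCitation(
        creators=("Synthetic Corpus Generator",),
        date="2021",
        title=(
            f"A synthetic collection of {spec.n_nodes} items "
            f"(depth {spec.depth}, fanout {spec.fanout})."
        ),
        signature=root.signature,
    )
    return Corpus(spec, store, root, citation)


# ---------------------------------------------------------------------------
# Timeline simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimelineSpec:
    """A simulated web of ``n_locations`` URLs observed over ``epochs``
    rounds; each location independently drifts with probability ``p_drift``
    or rots with probability ``p_rot`` (disjoint outcomes) at one random
    later epoch."""

    n_locations: int = 2000
    p_drift: float = 0.30
    p_rot: float = 0.20
    epochs: int = 4
    seed: int = 0
    blob_size: tuple[int, int] = (64, 4096)

    def __post_init__(self):
        if not (0 <= self.p_drift and 0 <= self.p_rot):
            raise ValidationError("probabilities must be non-negative")
        if self.p_drift + self.p_rot > 1:
            raise ValidationError("p_drift + p_rot must not exceed 1")
        if self.n_locations < 1 or self.epochs < 1:
            raise ValidationError("need at least one location and one epoch")


@dataclass(frozen=True)
class LocationTruth:
    """Injected ground truth for one location."""

    label: str  # "stable" | "drift" | "rot"
    change_epoch: Optional[int]  # epoch at which the change first appears


class SimulatedWeb:
    """In-memory web for tests: per-location content per epoch, plus a
    fetcher serving the final epoch's state (failures raise OSError)."""

    def __init__(self, epochs: int):
        self.epochs = epochs
        self._content: dict[str, list[Optional[bytes]]] = {}

    def add(self, url: str, per_epoch: list[Optional[bytes]]):
        self._content[url] = per_epoch

    def content_at(self, url: str, epoch: int) -> Optional[bytes]:
        return self._content[url][epoch]

    def urls(self) -> list[str]:
        return sorted(self._content)

    def fetcher(self, url: str) -> bytes:
        """Fetch the latest state of a URL; rotten locations raise."""
        latest = self._content[url][-1]
        if latest is None:
            raise OSError(f"simulated link rot: {url} is gone")
        return latest


def simulate_timeline(
    spec: TimelineSpec,
) -> tuple[SimulatedWeb, Registry, dict[str, LocationTruth]]:
    """Run the simulated web and record one observation per location per
    epoch in a fresh registry.

    Epoch 0 serves the true content everywhere.  From its change epoch
    onward, a drifting location serves its content with one seeded byte
    flipped, and a rotten location fails (recorded as FAILED).  Returns the
    web, the registry, and the per-location injected truth.
    """
    rng = random.Random(spec.seed)
    web = SimulatedWeb(spec.epochs)
    registry = Registry()
    truth: dict[str, LocationTruth] = {}
    t0 = datetime(2022, 1, 1, tzinfo=timezone.utc)

    for i in range(spec.n_locations):
        url = f"https://site-{i:05d}.example.org/data"
        original = rng.randbytes(rng.randint(*spec.blob_size))
        u = rng.random()
        if u < spec.p_drift:
            label = "drift"
        elif u < spec.p_drift + spec.p_rot:
            label = "rot"
        else:
            label = "stable"
        change = rng.randrange(1, spec.epochs) if spec.epochs > 1 else None
        if label == "stable" or change is None:
            truth[url] = LocationTruth("stable", None)
            per_epoch: list[Optional[bytes]] = [original] * spec.epochs
        elif label == "drift":
            idx = rng.randrange(len(original))
            altered = bytearray(original)
            altered[idx] ^= rng.randint(1, 255)
            altered = bytes(altered)
            truth[url] = LocationTruth("drift", change)
            per_epoch = [original] * change + [altered] * (spec.epochs - change)
        else:
            truth[url] = LocationTruth("rot", change)
            per_epoch = [original] * change + [None] * (spec.epochs - change)
        web.add(url, per_epoch)

    for epoch in range(spec.epochs):
        when = t0 + timedelta(days=epoch)
        for url in web.urls():
            content = web.content_at(url, epoch)
            if content is None:
                registry.register(url, None, when)
            else:
                registry.register(url, compute_signature(content), when)
    return web, registry, truth


def recovered_rates(registry: Registry) -> dict[str, float]:
    """Fraction of registry locations classified drifted / rotten / stable
    from their whole observation history."""
    summary = registry.summarize()
    n = len(summary) or 1
    drift = sum(1 for s in summary.values() if s is DriftStatus.CONTENT_DRIFT)
    rot = sum(1 for s in summary.values() if s is DriftStatus.LINK_ROT)
    return {
        "drift": drift / n,
        "rot": rot / n,
        "stable": (len(summary) - drift - rot) / n,
        "n": len(summary),
    }
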