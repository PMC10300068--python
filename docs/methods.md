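# Methods

## The model: content signatures and signed citations

A content signature is a pair *(algorithm, digest)* where the digest is a
cryptographic hash of the exact cited bytes.  Its canonical text form is a
content-hash URI, `hash://<algorithm>/<hex digest>`, lowercase hexadecimal,
4 bits per character (64 characters for SHA-256).  The two properties the
whole design rests on are standard for secure hash functions:

- **determinism** — equal bytes always give equal digests, so anyone
  holding the content can recompute and check the signature; and
- **collision resistance** — distinct bytes give distinct digests except
  with negligible probability, so a signature identifies exactly one byte
  stream.

A *signed citation* is a customary citation (creators, date, title,
optional access locations with dates) extended with one full content
signature.  Verification recomputes the digest of retrieved bytes: a
mismatch is *content drift*; an unreachable location is *link rot*.  The
signature itself carries no location, so neither phenomenon can corrupt
the reference — both become detectable, and often repairable, conditions.

Content that embeds other content's signatures (a reference list, or an
RDF document using hash URIs as terms) forms a Merkle-style DAG: the root
signature transitively commits to every byte in the graph.  A true cycle is
impossible — content cannot contain its own hash — but the traversal keeps
a visited set anyway so that even an adversarial resolver cannot make it
loop.

## Identifier dialects and numerical conventions

Three dialects are supported and freely interconvertible, because the
digest bits are invariant under re-encoding:

- `hash://<alg>/<payload>` (canonical), `ni:///<alg>;<payload>`, and the
  human-oriented `nih:<alg>;<hex>[;<check digit>]`.
- Translation never crosses hash algorithms: an md5 digest cannot become a
  sha256 digest without re-hashing content the translator does not have.
- Payload encodings are hex (canonical, lowercase; mixed case accepted on
  input) and base64url (unpadded on output; padded and standard-alphabet
  `+/` input accepted; `+`, `/`, `=` can be percent-encoded on request).
  Parsing is hex-first: an all-hex payload of legal length is read as hex.
- The `ni` algorithm token follows the printed practice `sha256`; the
  RFC 6920 spelling `sha-256` is accepted on input and canonicalized.
- Registered algorithms: `sha256` (default), plus `sha1` and `md5` for
  interoperability with repositories that still index by them — hashing
  with either emits a weak-algorithm warning.  Additional algorithms
  (including tiny test digests) can be registered at run time.

**Truncation.**  Prefixes are whole hex characters.  An *n*-character
prefix spans a keyspace of exactly 16^n (2^64 at n = 16, 2^128 at n = 32);
below 16 characters the library warns — the keyspace drops beneath 2^64
and collisions stop being fanciful.  Base64url encoding of a prefix is
only defined when its bit length (4n) is a multiple of 6; otherwise the
trailing bits of the last character would be unattributable and the string
would not round-trip, so the combination is rejected.  For the same reason
a base64url *input* prefix must have even (unpadded) length.

**Check digits.**  The nih dialect carries a Luhn mod-16 check digit.  The
algorithm's conventions are fixed here so independent implementations
agree: map each hex character to its value 0–15; walking right to left,
double every second value starting with the rightmost; fold doubled values
v ≥ 16 to (v div 16) + (v mod 16); the digit is (16 − sum mod 16) mod 16.
This catches every single-character substitution (verified exhaustively in
the suite), which is the failure mode of hand transcription.

**Collection canonicalization.**  A reference list is hashed as ASCII with
LF line endings, one blank line between entries, and a single trailing LF;
the empty collection is the empty byte stream.  Entry order matters — the
hash of {a,b} differs from the hash of {b,a} — and an opt-in `sort` flag
provides the lexicographic canonical-set form for order-free collections.
Non-ASCII entries are an error unless UTF-8 is explicitly allowed.  One
previously published collection hash could not be re-derived because the
exact whitespace bytes its authors hashed were never recorded; the suite
attempts the documented canonical forms and reports the outcome without
failing — an illustration of precisely why this package pins its byte
discipline down.

## Store, registry, and resolution

The content store files bytes under
`<root>/<alg>/<hex[0:2]>/<hex[2:4]>/<hex>` (two-level fan-out keeps
directories bounded; digests shorter than 4 hex characters fall back to a
flat layout).  Writes are atomic and idempotent.  The invariant with
teeth: **no read path ever returns bytes whose recomputed digest differs
from the request** — tampering surfaces as a corruption error, never as
silently wrong data.  Prefix lookups must be unique; ambiguity is an error
listing the candidates, never a guess.

The registry is an append-only TSV of `(observed_at, location, outcome)`
rows, UTC ISO 8601 timestamps, outcome a hash URI or the literal `FAILED`.
Classification of consecutive observations at one location follows a fixed
truth table: first observation → `initial`; same signature → `unchanged`;
different signature → `content_drift`; success then failure → `link_rot`.
Cells not forced by the definitions were chosen once and frozen by an
exhaustive oracle test: failure → failure stays `link_rot`; failure →
success is `initial` (re-observed, with no prior signature to compare).
A location's whole-history summary is its first change event.

Resolution tries an ordered source list — local store first, then
registry-known locations through an injectable fetcher (most recent first;
the registry does not rank locations, so recency is this package's
documented tie-break) — verifying every candidate and returning the first
match with its provenance, or an error carrying the full attempt log so
drifted copies are distinguishable from unavailability.  URL aliasing maps
a URL to the signature of its **most recent successful** observation and
resolves that; the live URL is deliberately not re-fetched, which is what
pins a workflow to the cited bytes.  Older signatures for the same URL
remain queryable as its version history.  Network fetching is always
opt-in; the bundled HTTP fetcher has a timeout and nothing constructs it
implicitly.

## Provenance and claims

Acquisition provenance is emitted as N-Quads in a minimal PROV dialect —
`prov:used`, `prov:generated`, `prov:startedAtTime` (xsd:dateTime, UTC) —
three quads per acquisition, graph label equal to the activity's
`urn:uuid:…`, no blank nodes, fixed line order.  The output is therefore
byte-stable and itself signable; the suite round-trips it through an
independent N-Quads parser.  Relation claims (`same-as`,
`different-from`, `derived-from`, or any custom IRI) link two hash-URI
terms inside a deterministic claim graph with attribution and timestamp;
they are annotations *about* content and never alter what a signature
identifies.  `different-from` between equal signatures is rejected as a
contradiction.  When building graphs from RDF content, hash-scheme IRIs
are taken from subject/object positions and literals alike via an in-order
textual scan (the serialization contains them verbatim either way), which
keeps traversal order deterministic.

## Synthetic data: what it emulates and what it does not

`generate_corpus` mirrors the structure of real collection manifests:
seeded random blobs as leaves and signed collection descriptions as
internal nodes, alternating ASCII reference lists and N-Quads provenance
per tier.  `depth` counts tiers including the root, so depth 3 / fanout 3
gives 1 + 3 + 9 = 13 nodes — the fixture used for exhaustive
tamper-detection tests.  Blob sizes default to 64–4096 bytes: large enough
that seeded blobs are pairwise distinct, small enough for fast suites.

`simulate_timeline` emulates repeated observation of a set of URLs: each
location independently drifts with probability `p_drift` or rots with
probability `p_rot` (disjoint, via a single uniform draw) at one uniformly
drawn later epoch; drift serves the original content with one seeded byte
flipped — the minimal copy-error perturbation and exactly what a parity
bit could miss but a hash cannot.  The default condition used in the
acceptance checks is 2000 locations, p_drift = 0.30, p_rot = 0.20, over 4
epochs; at n = 2000 the binomial standard error on a recovered rate is
about 1 percentage point, so the ±3-point acceptance band is roughly a
3-sigma check.  One `random.Random(seed)` per call drives everything:
equal specs give byte-identical corpora, timelines, and registry files
across platforms.

What passing these tests does **not** show about real data: blobs are not
real images (no format structure, so nothing is exercised about
format-preserving transformations that change bytes); the simulated web
has no latency, partial reads, or transport corruption; drift is a single
byte rather than re-encoding or re-curation; and observation epochs are
regular.  The historical multi-year crawl statistics that motivated the
drift/rot machinery are not reproduced here — only the methodology is,
with known injected truth in place of the live web.

## Design choices where the design was open

- Hex-first payload interpretation (a 64-hex-character string is read as
  hex even though it is also legal base64), documented rather than
  heuristic.
- `nih` is algorithm-qualified (`nih:sha256;…`) so free-text extraction
  can find it by scheme token; bare RFC-style payloads are out of scope.
- A wrong nih check digit is a parse error, not a warning: the digit
  exists solely to catch transcription errors, so honoring a failed check
  would defeat its purpose.
- Only full signatures are traversed in graphs; prefixes do not identify
  unique bytes to recurse into.
- Drifted content is never expanded during graph verification: its
  embedded references cannot be trusted, so each broken path reports its
  first failing node.

## Known limitations

- Registries are loaded whole into memory; fine for the intended
  lightweight-record scale, wrong for millions of rows.
- Prefix lookup scans the store's directory tree linearly.
- The graph medium classifier treats any content that parses as N-Quads
  with at least one quad as RDF; a pathological plain-text file that is
  also valid N-Quads would be classified as RDF (extraction results are
  unaffected).
- No garbage collection or access control in the store, and no live
  clients for external repositories — the fetcher interface is the
  plug-in point.
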