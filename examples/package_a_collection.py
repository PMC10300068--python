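"""Cite a whole collection with one signature.

Two signed citations are packaged into a canonical ASCII reference list;
the list's own signature then robustly (and recursively) cites both items.
"""

import sigcite as sc

items = {
    "Head frontal view of specimen EX:123.": b"bytes of the head-frontal image",
    "Habitus lateral view of specimen EX:123.": b"bytes of the habitus-lateral image",
}

entries = []
for title, content in items.items():
    citation = sc.SignedCitation(
        creators=("Example Natural History Museum",),
        date="2024",
        title=title,
        signature=sc.compute_signature(content),
    )
    entries.append(sc.render_signed_citation(citation))

collection = sc.package_collection(entries)
print(collection.canonical_bytes.decode("ascii"))
print(f"collection signature: {collection.signature.uri}")
print()

# The collection itself gets a signed citation -- one line that transitively
# commits to every byte of both images.
root = sc.SignedCitation(
    creators=("Some author",), date="2024",
    title="A collection of signed citations for various images.",
    signature=collection.signature,
)
print(sc.render_signed_citation(root))
print()

embedded = sc.extract_signatures(collection.canonical_bytes.decode("ascii"))
print(f"signatures recoverable from the list, in order: {len(embedded)}")
swapped = sc.package_collection(list(reversed(entries)))
print(f"hash of {{a,b}} equals hash of {{b,a}}: {swapped.signature == collection.signature}")
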