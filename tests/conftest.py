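import pytest

import sigcite as sc

# --- Canonical identifier strings used across the suite -------------------

# SHA-256 of the ASCII bytes "abc" (FIPS 180-4 example vector, reproduced by
# the independent oracle in sha256_oracle.py).
ABC_SHA256 = "ba7816bf8f01cfea414140de5dae2223b00361a396177a9cb410ff61f20015ad"
EMPTY_SHA256 = "e3b0c44298fc1c149afbf4c8996fb92427ae41e4649b934ca495991b7852b855"

# The bee-specimen image citations (head-frontal and habitus-lateral views)
# and the interchangeable identifier pair used in the readability discussion.
HEAD_HEX = "edde5b2b45961e356f27b81a3aa51584de4761ad9fa678c4b9fa3230808ea356"
HABITUS_HEX = "8d49bd24f6ba300b4de44fd218b53294f4cc0106cd9631018ef819b38345c75d"
READABILITY_HEX = "29d30b566f924355a383b13cd48c3aa239d42cba0a55f4ccfc2930289b88b43c"
COLLECTION_HEX = "fe21dbf7e3ac1f9f82afa303a927015ada16ff84571e1fe21914c7053f00fb59"
BEES_GRAPH_HEX = "85138e506a29fb73099fb050372d8a379794ab57fe4bfdf141743db0de2b985c"
WING_A_HEX = "79d795bff23567be10d36934facc8befca300e426d0abbd7c273269fe8ec427b"
WING_B_HEX = "86b657f8828b235371322894c65ec62909f62f874c1b1528e49edddb5fc2271a"

HEAD_CITATION = (
    "Museum of Comparative Zoology, Harvard University. 2021. "
    "Head Frontal View of MCZ:ENT:17219 Nomadopsis puellae (Cockerell, 1933) "
    f"hash://sha256/{HEAD_HEX} "
    "Accessed at http://mczbase.mcz.harvard.edu/specimen_images/entomology/"
    "large/MCZ-ENT00017219_Spinoliella_puellae_hef.jpg on 2021-12-07."
)
HABITUS_CITATION = (
    "Museum of Comparative Zoology, Harvard University. 2021. "
    "Habitus Lateral View of MCZ:ENT:17219 Nomadopsis puellae (Cockerell, 1933) "
    f"hash://sha256/{HABITUS_HEX} "
    "Accessed at http://mczbase.mcz.harvard.edu/specimen_images/entomology/"
    "large/MCZ-ENT00017219_Spinoliella_puellae_hal.jpg on 2021-12-07."
)


@pytest.fixture
def store(tmp_path):
    return sc.ContentStore(tmp_path / "store")


@pytest.fixture
def corpus(store):
    """Depth-3 / fanout-3 nested collection: 13 nodes, 9 blob leaves."""
    return sc.generate_corpus(sc.CorpusSpec(depth=3, fanout=3, seed=11), store)


def tamper(store, signature):
    """Flip the first byte of the stored file behind ``signature``."""
    path = store._path(signature)
    raw = bytearray(path.read_bytes())
    raw[0] ^= 0xFF
    path.write_bytes(bytes(raw))
    return path
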