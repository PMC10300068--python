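"""Signature computation, parsing, translation, truncation, verification."""

import io
import random
import warnings

import pytest
from hypothesis import given, settings, strategies as st

import sigcite as sc
from sigcite.errors import (
    ImpossibleTranslationError,
    InvalidLengthError,
    MalformedPayloadError,
    NotASignatureError,
    UnsupportedAlgorithmError,
    UnsupportedCombinationError,
)

from conftest import ABC_SHA256, READABILITY_HEX
from sha256_oracle import sha256_hex


class TestCompute:
    def test_fips_abc_vector(self):
        sig = sc.compute_signature(b"abc")
        assert sig.hex == ABC_SHA256
        assert sig.uri == f"hash://sha256/{ABC_SHA256}"

    def test_deterministic_and_chunking_invariant(self):
        rng = random.Random(1)
        for _ in range(20):
            blob = rng.randbytes(rng.randint(0, 5000))
            whole = sc.compute_signature(blob)
            assert sc.compute_signature(blob) == whole
            for chunk in (1, 7, 4096):
                chunks = [blob[i:i + chunk] for i in range(0, len(blob), chunk)]
                assert sc.compute_signature(chunks) == whole
            assert sc.compute_signature(io.BytesIO(blob)) == whole

    def test_matches_independent_oracle(self):
        rng = random.Random(2)
        for _ in range(25):
            blob = rng.randbytes(rng.randint(0, 2000))
            assert sc.compute_signature(blob).hex == sha256_hex(blob)

    def test_distinct_blobs_distinct_signatures(self):
        rng = random.Random(3)
        sigs = {sc.compute_signature(rng.randbytes(64)).hex for _ in range(100)}
        assert len(sigs) == 100

    def test_unknown_algorithm(self):
        with pytest.raises(UnsupportedAlgorithmError):
            sc.compute_signature(b"abc", "sha3-512")

    def test_weak_algorithms_warn_but_work(self):
        with pytest.warns(sc.signatures.WeakAlgorithmWarning):
            sig = sc.compute_signature(b"abc", "md5")
        assert sig.hex == "900150983cd24fb0d6963f7d28e17f72"  # RFC 1321 suite


class TestParse:
    def test_hash_uri_hex(self):
        p = sc.parse_signature(f"hash://sha256/{READABILITY_HEX}")
        assert p.scheme == "hash-uri" and p.encoding == "hex"
        assert p.is_full and p.signature.hex == READABILITY_HEX

    def test_ni_hex_same_digest_as_hash_uri(self):
        a = sc.parse_signature(f"hash://sha256/{READABILITY_HEX}")
        b = sc.parse_signature(f"ni:///sha256;{READABILITY_HEX}")
        assert a.signature == b.signature
        assert b.scheme == "ni"

    def test_scheme_case_insensitive(self):
        # prose capitalizes the scheme at sentence start
        p = sc.parse_signature(f"Hash://sha256/{READABILITY_HEX}")
        assert p.signature.hex == READABILITY_HEX

    def test_mixed_case_digest_canonicalized(self):
        p = sc.parse_signature(f"hash://sha256/{READABILITY_HEX.upper()}")
        assert p.signature.hex == READABILITY_HEX

    def test_short_payload_is_prefix(self):
        p = sc.parse_signature(f"hash://sha256/{READABILITY_HEX[:16]}")
        assert not p.is_full
        assert p.payload.prefix_hex == READABILITY_HEX[:16]

    def test_base64url_payload(self):
        b64 = sc.format_signature(
            sc.ContentSignature.from_hex("sha256", READABILITY_HEX),
            "hash-uri", "base64url",
        )
        p = sc.parse_signature(b64)
        assert p.encoding == "base64url"
        assert p.signature.hex == READABILITY_HEX

    def test_percent_encoded_payload_decoded(self):
        digest = sc.compute_signature(b"percent").digest
        import base64
        padded = base64.urlsafe_b64encode(digest).decode()  # ends with '='
        uri = "hash://sha256/" + padded.replace("=", "%3D")
        assert sc.parse_signature(uri).signature.digest == digest

    def test_nih_with_check_digit(self):
        digit = sc.compute_check_digit(READABILITY_HEX)
        p = sc.parse_signature(f"nih:sha256;{READABILITY_HEX};{digit}")
        assert p.scheme == "nih" and p.signature.hex == READABILITY_HEX

    def test_nih_wrong_check_digit_rejected(self):
        digit = sc.compute_check_digit(READABILITY_HEX)
        wrong = "0" if digit != "0" else "1"
        with pytest.raises(MalformedPayloadError):
            sc.parse_signature(f"nih:sha256;{READABILITY_HEX};{wrong}")

    @pytest.mark.parametrize(
        "bad, err",
        [
            ("hash://sha256/xyz", MalformedPayloadError),
            (f"hash://sha256/{READABILITY_HEX}ff", MalformedPayloadError),
            ("hash://sha256/", MalformedPayloadError),
            ("doi:10.1000/xyz", NotASignatureError),
            ("https://example.org/a", NotASignatureError),
            ("hash://nosuchalg/aa", UnsupportedAlgorithmError),
        ],
    )
    def test_rejects_malformed(self, bad, err):
        with pytest.raises(err):
            sc.parse_signature(bad)


class TestFormatAndTranslate:
    CANONICAL = [
        f"hash://sha256/{READABILITY_HEX}",
        f"ni:///sha256;{READABILITY_HEX}",
    ]

    @pytest.mark.parametrize("text", CANONICAL)
    def test_format_parse_roundtrip_identity(self, text):
        p = sc.parse_signature(text)
        assert sc.format_signature(p.payload, p.scheme, p.encoding) == text

    def test_translate_hash_to_ni_preserves_hex(self):
        out = sc.translate(f"hash://sha256/{READABILITY_HEX}", "ni", "hex")
        assert out == f"ni:///sha256;{READABILITY_HEX}"

    def test_translate_to_own_dialect_is_canonical_form(self):
        text = f"Hash://sha256/{READABILITY_HEX.upper()}"
        assert sc.translate(text, "hash", "hex") == f"hash://sha256/{READABILITY_HEX}"

    def test_translate_base64url_roundtrip(self):
        import base64
        src = f"hash://sha256/{READABILITY_HEX}"
        via = sc.translate(src, "hash", "base64url")
        expected = base64.urlsafe_b64encode(bytes.fromhex(READABILITY_HEX)).decode().rstrip("=")
        assert via == f"hash://sha256/{expected}"
        assert sc.translate(via, "hash", "hex") == src

    def test_translate_never_crosses_algorithms(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md5_sig = sc.compute_signature(b"a legacy-indexed file", "md5")
        with pytest.raises(ImpossibleTranslationError):
            sc.translate(md5_sig.uri, "hash", "hex", algorithm="sha1")

    def test_ni_base64url_form(self):
        import base64
        sig = sc.ContentSignature.from_hex("sha256", READABILITY_HEX)
        out = sc.format_signature(sig, "ni", "base64url")
        expected = base64.urlsafe_b64encode(sig.digest).decode().rstrip("=")
        assert out == f"ni:///sha256;{expected}"

    def test_percent_encoding_escapes_reserved(self):
        sig = sc.ContentSignature.from_hex("sha256", READABILITY_HEX)
        plain = sc.format_signature(sig, "hash-uri", "base64url", percent_encode=True)
        assert "+" not in plain and "=" not in plain.split("/")[-1]

    def test_prefix_base64url_needs_multiple_of_six_bits(self):
        sig = sc.ContentSignature.from_hex("sha256", READABILITY_HEX)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prefix = sc.truncate_signature(sig, 8)  # 32 bits
        with pytest.raises(UnsupportedCombinationError):
            sc.format_signature(prefix, "hash-uri", "base64url")
        ok = sc.truncate_signature(sig, 48)  # 192 bits
        roundtrip = sc.parse_signature(sc.format_signature(ok, "hash-uri", "base64url"))
        assert roundtrip.payload.hex == ok.prefix_hex


class TestTruncation:
    def test_printed_truncation_forms(self):
        sig = sc.ContentSignature.from_hex("sha256", READABILITY_HEX)
        assert sc.truncate_signature(sig, 32).uri == (
            "hash://sha256/29d30b566f924355a383b13cd48c3aa2"
        )
        assert sc.truncate_signature(sig, 16).uri == (
            "hash://sha256/29d30b566f924355"
        )

    def test_full_length_truncation_matches_as_full(self):
        sig = sc.compute_signature(b"abc")
        prefix = sc.truncate_signature(sig, 64)
        assert prefix.is_full
        assert sc.verify_content(b"abc", prefix).status == "match"

    def test_short_prefix_warns(self):
        sig = sc.compute_signature(b"abc")
        with pytest.warns(sc.signatures.ShortPrefixWarning):
            sc.truncate_signature(sig, 8)

    @pytest.mark.parametrize("n", [0, -1, 65, 1.5])
    def test_out_of_range_lengths(self, n):
        with pytest.raises(InvalidLengthError):
            sc.truncate_signature(sc.compute_signature(b"abc"), n)

    def test_prefix_monotonicity(self):
        sig = sc.ContentSignature.from_hex("sha256", READABILITY_HEX)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for n in range(1, 65):
                assert sc.matches(sc.truncate_signature(sig, n), sig)

    def test_prefix_of_other_digest_does_not_match(self):
        a = sc.compute_signature(b"a")
        b = sc.compute_signature(b"b")
        assert a.hex[0] != b.hex[0]  # frozen: digests share no leading char
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert not sc.matches(sc.truncate_signature(a, 8), b)


class TestKeyspace:
    def test_printed_keyspace_sizes(self):
        assert sc.keyspace_size(16) == 2 ** 64 == 18446744073709551616
        assert abs(sc.keyspace_size(16) / 1.8e19 - 1) < 0.03  # "1.8 x 10^19"
        assert sc.keyspace_size(32) == 2 ** 128
        assert sc.keyspace_size(1) == 16

    def test_exact_power_of_sixteen(self):
        for n in range(1, 65):
            assert sc.keyspace_size(n) == 16 ** n

    def test_invalid_length(self):
        with pytest.raises(InvalidLengthError):
            sc.keyspace_size(0)


class TestCheckDigit:
    def test_zero_payload(self):
        assert sc.compute_check_digit("00") == "0"

    def test_single_f_hand_evaluated(self):
        # 15 doubled = 30 -> 1 + 14 = 15; (16 - 15) mod 16 = 1
        assert sc.compute_check_digit("f") == "1"

    def test_detects_every_single_substitution(self):
        rng = random.Random(4)
        hexdigits = "0123456789abcdef"
        for _ in range(50):
            payload = "".join(rng.choice(hexdigits) for _ in range(rng.randint(4, 64)))
            digit = sc.compute_check_digit(payload)
            assert sc.verify_check_digit(payload, digit)
            for pos in range(len(payload)):
                for sub in hexdigits:
                    if sub == payload[pos]:
                        continue
                    mutated = payload[:pos] + sub + payload[pos + 1:]
                    assert not sc.verify_check_digit(mutated, digit)

    def test_non_hex_rejected(self):
        with pytest.raises(MalformedPayloadError):
            sc.compute_check_digit("xyz")


class TestVerifyContent:
    def test_roundtrip_match(self):
        sig = sc.compute_signature(b"some content")
        assert sc.verify_content(b"some content", sig).status == "match"

    def test_single_bit_flip_detected(self):
        blob = bytearray(random.Random(5).randbytes(256))
        sig = sc.compute_signature(bytes(blob))
        blob[100] ^= 0x01
        outcome = sc.verify_content(bytes(blob), sig)
        assert outcome.status == "mismatch"
        assert outcome.observed != sig

    def test_prefix_match_status(self):
        blob = b"prefix-cited content"
        sig = sc.compute_signature(blob)
        prefix = sc.truncate_signature(sig, 16)
        outcome = sc.verify_content(blob, prefix)
        assert outcome.status == "prefix_match"
        assert outcome.observed == sig


# --- Property tests -------------------------------------------------------

@settings(derandomize=True, max_examples=60)
@given(st.binary(max_size=512))
def test_parse_of_canonical_uri_recovers_signature(blob):
    sig = sc.compute_signature(blob)
    assert sc.parse_signature(sig.uri).signature == sig


@settings(derandomize=True, max_examples=60)
@given(
    st.binary(min_size=0, max_size=128),
    st.sampled_from([("hash", "hex"), ("hash", "base64url"), ("ni", "hex"),
                     ("ni", "base64url"), ("nih", "hex")]),
)
def test_translate_involution_per_dialect(blob, dialect):
    scheme, encoding = dialect
    sig = sc.compute_signature(blob)
    away = sc.translate(sig.uri, scheme, encoding)
    back = sc.translate(away, "hash", "hex")
    assert back == sig.uri
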