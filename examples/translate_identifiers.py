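"""Translate, truncate, and checksum content signatures.

One digest, many skins: the same 256 bits rendered as a content-hash URI,
a named-information (ni) URI, a base64url form, readable truncations, and a
human-oriented nih form with a transcription check digit.
"""

import warnings

import sigcite as sc

uri = "hash://sha256/29d30b566f924355a383b13cd48c3aa239d42cba0a55f4ccfc2930289b88b43c"
print(f"canonical:   {uri}")
print(f"ni (hex):    {sc.translate(uri, 'ni', 'hex')}")
print(f"base64url:   {sc.translate(uri, 'hash', 'base64url')}")
print(f"nih + check: {sc.translate(uri, 'nih', 'hex')}")
print()

sig = sc.parse_signature(uri).signature
print(f"truncated to 32 chars: {sc.truncate_signature(sig, 32).uri}")
print(f"truncated to 16 chars: {sc.truncate_signature(sig, 16).uri}")
print(f"keyspace at 16 chars:  16^16 = {sc.keyspace_size(16):.2e} possible hashes")
with warnings.catch_warnings():  # below 16 chars the library warns
    warnings.simplefilter("ignore")
    short = sc.truncate_signature(sig, 8)
print(f"keyspace at 8 chars:   16^8  = {sc.keyspace_size(8):.2e}  (collisions plausible)")
print()

digit = sc.compute_check_digit(sig.hex)
typo = "a" + sig.hex[1:]  # one mistyped character
print(f"check digit: {digit}")
print(f"typo detected: {not sc.verify_check_digit(typo, digit)}")
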