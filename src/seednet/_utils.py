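"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(base_seed: int, label: str) -> int:
    """Derive a stage-specific RNG seed from a single base seed.

    All randomness in the package flows from one integer; stages draw
    independent streams by hashing the base seed together with a stage
    label. The result is a non-negative int below 2**31.
    """
    digest = hashlib.sha256(f"{base_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
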