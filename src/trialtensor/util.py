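"""Shared small helpers."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from a global seed and a stage name.

    Hash-based substream derivation: adding a stage never perturbs another
    stage's random stream.  The result fits in a signed 32-bit integer.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
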