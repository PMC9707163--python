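"""Stable seed derivation.

All randomness in the package flows from one master seed; per-stage and
per-pair seeds are derived by hashing the master seed together with string
labels, so results are reproducible and independent of execution order.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *parts: str) -> int:
    """Deterministic 31-bit seed from a master seed and string labels.

    Uses SHA-256 so the mapping is stable across platforms and Python
    versions (unlike ``hash``).
    """
    key = f"{int(master)}|" + "|".join(parts)
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
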