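"""Deterministic seed derivation for pipeline stages.

Every stochastic stage derives its own 31-bit seed from a global seed and
a stage name via SHA-256, so stages are independently reproducible and
insensitive to execution order or interpreter hash randomization.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(global_seed: int, *stage: object) -> int:
    """Derive a stable seed < 2**31 from a global seed and stage labels."""
    key = ":".join([str(int(global_seed))] + [str(s) for s in stage])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
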