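"""Stable sub-seed derivation.

Every stochastic stage derives its own seed from the master seed plus a tuple of
string/int tokens (species id, procedure, replicate index, ...) via SHA-256, so
any subset of an experiment can be rerun bit-identically without replaying the
whole random stream.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, *tokens: object) -> int:
    """Derive a deterministic 31-bit seed from a master seed and context tokens."""
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for t in tokens:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31 - 1)
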