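"""Deterministic seed derivation for per-task random streams."""

from __future__ import annotations

import zlib


def stable_pair_seed(master_seed: int, tag: str) -> int:
    """Derive a sub-seed from the master seed and a task tag.

    Stable across sessions and platforms (CRC-based, unlike Python's
    salted ``hash``); result fits in a signed 32-bit integer.
    """
    return zlib.crc32(f"{master_seed}|{tag}".encode()) & 0x7FFFFFFF
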