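"""Deterministic seed derivation: one master seed, named per-stage streams."""

from __future__ import annotations

import zlib

__all__ = ["derive_seed"]

_MOD = 2**31 - 1


def derive_seed(master: int, name: str) -> int:
    """A stable child seed for a named stage of the pipeline.

    Mixing the stage name through CRC32 keeps the streams of different
    stages independent while every stage remains individually
    re-runnable from the master seed alone.
    """
    return (int(master) * 1_000_003 + zlib.crc32(name.encode())) % _MOD
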