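"""Deterministic random-stream derivation.

Every source of randomness in the package is derived from one integer seed
plus a stable string/integer key path, so any frame, individual, or training
run can be regenerated in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK31 = 0x7FFFFFFF


def stable_key(*parts) -> list[int]:
    """Map a mixed key path to 31-bit integers (crc32 for strings; stable across runs)."""
    out: list[int] = []
    for p in parts:
        if isinstance(p, (int, np.integer)):
            out.append(int(p) & _MASK31)
        else:
            out.append(zlib.crc32(str(p).encode("utf-8")) & _MASK31)
    return out


def rng_for(seed: int, *parts) -> np.random.Generator:
    """Counter-based child stream for (seed, *parts)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) & _MASK31, spawn_key=tuple(stable_key(*parts)))
    )


def child_seed(seed: int, *parts) -> int:
    """A derived 31-bit integer seed for APIs that take one."""
    ss = np.random.SeedSequence(entropy=int(seed) & _MASK31, spawn_key=tuple(stable_key(*parts)))
    return int(ss.generate_state(1)[0] & _MASK31)
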