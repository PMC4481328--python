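"""Deterministic seed derivation.

All randomness in the package flows from a single master seed. Child seeds
are derived with a splitmix64-style mixer over an FNV-1a hash of the string
tokens identifying the consumer, so derived seeds are stable across runs,
platforms and Python sessions (``hash()`` is never used).
"""

from __future__ import annotations

_MASK = (1 << 64) - 1


def _fnv1a(data: bytes) -> int:
    h = 0xCBF29CE484222325
    for b in data:
        h ^= b
        h = (h * 0x100000001B3) & _MASK
    return h


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    return z ^ (z >> 31)


def child_seed(master_seed: int, *tokens: object) -> int:
    """Derive a stable 31-bit child seed from a master seed and tokens.

    Tokens may be strings or integers; they are folded into an FNV-1a hash
    and passed through splitmix64. The result fits in a non-negative int32,
    suitable for ``numpy.random.default_rng``.
    """
    if master_seed < 0:
        raise ValueError("master_seed must be non-negative")
    h = _fnv1a(str(int(master_seed)).encode())
    for tok in tokens:
        h = _splitmix64(h ^ _fnv1a(str(tok).encode()))
    return h & 0x7FFFFFFF
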