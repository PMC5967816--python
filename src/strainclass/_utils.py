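"""Small shared helpers: seed derivation and rounding conventions."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "round_half_up"]

_SEED_MOD = 2**31 - 1


def derive_seed(master: int, *tags) -> int:
    """Derive a child seed deterministically from a master seed and tags.

    Every stochastic stage of a run draws its own child seed so that stages
    are independently reproducible and reordering one stage never perturbs
    another. The result is always in [0, 2^31).
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(repr(int(master)).encode())
    for t in tags:
        h.update(b"\x1f")
        h.update(repr(t).encode())
    return int.from_bytes(h.digest(), "little") % _SEED_MOD


def round_half_up(x: float) -> int:
    """Round with ties away from zero (0.5 -> 1), not banker's rounding."""
    return int(np.floor(x + 0.5))
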