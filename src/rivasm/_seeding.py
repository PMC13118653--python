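"""Deterministic seed derivation for stochastic operations.

Every stochastic operation takes an explicit integer seed. Composite
analyses derive per-stage and per-item child seeds by stable hashing of
the parent seed together with string tokens (operation names, sorted
sample-pair ids), so results never depend on evaluation order or on how
work is split across workers.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(seed: int, *tokens) -> int:
    """Derive a child seed (< 2**31) from a parent seed and string tokens."""
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for t in tokens:
        h.update(b"\x00")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def rng_for(seed: int, *tokens) -> np.random.Generator:
    """A numpy Generator keyed to (seed, tokens)."""
    return np.random.default_rng(child_seed(seed, *tokens))
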