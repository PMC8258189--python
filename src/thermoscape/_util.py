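"""Seed derivation and small shared helpers.

All randomness in the package flows from one root seed.  Stage seeds are
derived with :func:`derive_seed`, which feeds the root seed plus a tuple of
string keys (stage name, split index, ...) through ``numpy``'s
``SeedSequence``.  The scheme is documented in every run manifest so that a
run can be reproduced from the manifest alone.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(root_seed: int, *keys: str | int) -> int:
    """Return a deterministic 31-bit child seed for ``(root_seed, *keys)``.

    String keys are hashed with CRC32 so the derivation is stable across
    interpreter runs and platforms.
    """
    entropy = [int(root_seed)]
    for key in keys:
        entropy.append(zlib.crc32(str(key).encode()) if isinstance(key, str) else int(key))
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def rng_for(root_seed: int, *keys: str | int) -> np.random.Generator:
    """A ``numpy`` Generator seeded via :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(root_seed, *keys))
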