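"""Deterministic per-stage seed derivation.

Every stage draws from its own generator seeded from the master seed plus a
tuple of string tokens (stage name, dataset label, replicate index ...), so
adding or removing one dataset never perturbs another dataset's stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master_seed: int, *tokens: object) -> int:
    """A 31-bit seed determined by ``master_seed`` and the token tuple."""
    digest = zlib.crc32("/".join(str(t) for t in tokens).encode())
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, digest])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(master_seed: int, *tokens: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *tokens))
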