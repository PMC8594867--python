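"""Deterministic seed derivation.

Every source of randomness in the package draws its seed from one master
seed hashed together with stage/fold/set tags, so streams in different
stages are decorrelated and a run manifest containing the master seed and
the tag scheme suffices to re-derive every seed used anywhere.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master: int, *tags: object) -> int:
    """A 31-bit seed deterministically derived from master seed and tags."""
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for tag in tags:
        h.update(b"\x00" + str(tag).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def rng_for(master: int, *tags: object) -> np.random.Generator:
    """A numpy Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master, *tags))
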