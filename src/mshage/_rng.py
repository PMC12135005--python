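"""Counter-style sub-seeding.

Every stochastic stage derives its own stream from one master seed plus a
tuple of tags (stage name, variant position, copy index, ...), so results do
not depend on iteration order and any single draw can be replayed in
isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MAX_SEED = 2**31 - 2  # msprime requires seeds in [1, 2^32); we stay below 2^31


def subseed(master: int, *tags) -> int:
    """Derive a stable seed in [1, 2^31 - 1] from ``master`` and ``tags``.

    The mapping is a SHA-256 hash of the rendered key, so it is stable across
    platforms and Python processes (unlike ``hash()``).
    """
    key = f"{int(master)}:" + "/".join(str(t) for t in tags)
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:8], "little") % _MAX_SEED + 1


def rng_for(master: int, *tags) -> np.random.Generator:
    """A numpy Generator seeded by :func:`subseed`."""
    return np.random.default_rng(subseed(master, *tags))
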