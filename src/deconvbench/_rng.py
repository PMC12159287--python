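"""Deterministic child-seed derivation.

All randomness in the package flows from one integer master seed. Each
stage derives its own independent stream by hashing a short string tag into
a ``numpy.random.SeedSequence`` spawn key, so that re-running a single stage
reproduces exactly the stream it saw inside a full pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(master_seed: int, *tags: str | int) -> int:
    """Derive a sub-seed (< 2**31) from a master seed and a tag path."""
    key = tuple(
        t if isinstance(t, int) else zlib.crc32(t.encode("utf-8")) for t in tags
    )
    ss = np.random.SeedSequence(int(master_seed), spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def child_rng(master_seed: int, *tags: str | int) -> np.random.Generator:
    """A ``numpy`` Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *tags))
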