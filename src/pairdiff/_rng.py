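"""Seeded random-stream management.

All stochastic stages draw from named substreams of a single top-level
seed, so any stage can be re-run in isolation and the full pipeline is
reproducible end to end.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _name_key(name: str) -> int:
    digest = hashlib.blake2s(name.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little")


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The same ``(seed, names)`` combination always yields an identical
    stream; distinct names yield statistically independent streams.
    """
    keys = [_name_key(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & (2**63 - 1), *keys]))
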