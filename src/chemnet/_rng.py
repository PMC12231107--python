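"""Deterministic RNG substreams.

Every stochastic routine in the package draws from a substream derived
from a single master seed plus a tuple of string/int keys (stage name,
entity id, ...).  Substreams are independent by construction, so adding
a strain or a null-model sample never reshuffles the draws of existing
entities.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(master_seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator keyed by ``(master_seed, *keys)``.

    The same arguments always yield an identical stream; distinct key
    tuples yield streams that are independent for practical purposes
    (seed material is fed through numpy's SeedSequence entropy pool).
    """
    material = [int(master_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(material))
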