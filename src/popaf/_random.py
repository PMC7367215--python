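"""Named-substream random number generation.

Every stochastic output of the simulator draws from its own substream,
derived from the single global seed plus a tuple of string/int keys. Adding
a new output therefore never perturbs draws of existing ones, and any output
is reproducible in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``.

    The entropy fed to the bit generator is the global seed followed by a
    CRC32 of each key's string form, so distinct key tuples map to distinct,
    stable streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(str(k).encode("utf-8")) for k in keys)
    return np.random.default_rng(entropy)
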