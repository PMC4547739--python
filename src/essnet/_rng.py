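"""Named random substreams.

One global integer seed drives every stochastic stage; each generator pulls a
substream keyed by a stable string name, so adding a new generator never
perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the (seed, name) substream.

    The name is hashed with CRC-32, which is stable across processes and
    Python versions (unlike ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
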