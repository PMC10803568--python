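"""Named random substreams.

Every stochastic stage draws from its own substream derived from the single
run seed plus a stage name, so adding draws to one stage never perturbs
another stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, name)``.

    The stage name is hashed with CRC-32 so the entropy pool is stable
    across interpreter runs (unlike ``hash``).
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
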