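"""Named RNG substreams.

Each generator asks for ``substream(seed, "name")``; the stream is a pure
function of (seed, name), so simulators are independent of each other and
reproducible across platforms.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,))
    return np.random.Generator(np.random.PCG64(ss))
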