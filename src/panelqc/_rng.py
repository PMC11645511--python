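"""Named random substreams fanned out from one global seed.

Each pipeline stage (and each panel within a stage) draws from its own
substream so that toggling one stage never shifts another stage's randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def substream(seed: int, *names: str) -> np.random.Generator:
    """Deterministic generator for ``(seed, names...)``.

    The stream key is a CRC32 of the joined names, so the mapping is stable
    across processes and Python versions (unlike ``hash``).
    """
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *keys]))


def child_seed(seed: int, *names: str) -> int:
    """A derived integer seed (< 2**31) for ``(seed, names...)``."""
    return int(substream(seed, *names).integers(2**31))
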