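"""Named random substreams derived from a single top-level seed.

Every stochastic stage (design, cohort, choices, draws, starts, ...) pulls
an independent deterministic stream via a stable name hash, so one seed
reproduces an entire pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream_seed", "substream"]


def substream_seed(seed: int, name: str) -> int:
    """Deterministic child seed for a named stage; stays below 2**31."""
    return int((int(seed) * 0x9E3779B1 + zlib.crc32(name.encode())) % (2**31 - 1))


def substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(seed, name))
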