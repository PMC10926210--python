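"""Named random substreams.

One global seed drives independent, order-insensitive substreams keyed by
task name (e.g. ``"genotypes:rs6025"``), so adding a SNP or reordering tasks
does not perturb unrelated draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """A Generator derived deterministically from (seed, name)."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), key])))
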