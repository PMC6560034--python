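"""Named random substreams derived from one master seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named stream of ``seed``.

    Every source of randomness in the package draws from a stream derived
    from one master seed and a stage name, so reruns with the same seed are
    bit-identical regardless of stage execution order.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), tag)))


def subseed(seed: int, name: str) -> int:
    """A 31-bit integer seed for libraries that take plain ints."""
    return int(substream(seed, name).integers(0, 2**31 - 1))
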