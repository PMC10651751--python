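"""Shared helpers: seeded substreams and small validation utilities."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "check_positive"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible random stream derived from a root seed.

    Every stage of the pipeline draws from its own substream so that rerunning
    one stage never perturbs another.  The child seed is a CRC32 hash of the
    stage name mixed into a ``SeedSequence`` with the root seed.
    """
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def check_positive(name: str, value) -> None:
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value!r}")
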