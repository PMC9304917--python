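"""Splittable deterministic random streams.

One global integer seed drives the whole pipeline; each sub-task derives its
own independent stream from (seed, task-tag) so stages stay reproducible in
isolation and insensitive to the order other stages consume randomness.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, *tags: str | int) -> np.random.Generator:
    """Generator for a named sub-task of a seeded run."""
    keys = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, str):
            keys.append(zlib.crc32(tag.encode("utf8")))
        else:
            keys.append(int(tag) & 0xFFFFFFFF)
    return np.random.default_rng(keys)
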