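"""Deterministic named random streams derived from one master seed."""

from __future__ import annotations

import zlib

import numpy as np


def named_rng(master_seed: int, *names: str) -> np.random.Generator:
    """A generator keyed by ``(master_seed, names...)``.

    Stream identity depends only on the master seed and the name path, so
    sub-experiments are reproducible independently of execution order.
    """
    keys = [int(master_seed) & 0x7FFFFFFF]
    keys += [zlib.crc32(n.encode()) & 0x7FFFFFFF for n in names]
    return np.random.default_rng(keys)
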