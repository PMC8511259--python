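"""Deterministic per-stage random substreams.

One top-level integer seed; each named operation derives an independent
generator so stages can be re-run in isolation without perturbing others.
"""

from __future__ import annotations

import zlib

import numpy as np

def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for operation `name` derived from the top-level seed."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,)))
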