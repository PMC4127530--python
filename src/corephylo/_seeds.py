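"""Seed-stream management.

All stochastic components draw from :func:`stream`, which derives an
independent child generator from a root seed plus a string label.  Two
modules seeded from the same root therefore never share a stream, and any
single stage can be re-run in isolation with bit-identical output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, label: str) -> np.random.Generator:
    """Return an independent PCG64 generator for ``(seed, label)``.

    The label is hashed (crc32) into the spawn key so that streams are a
    pure function of the pair and stable across sessions.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
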