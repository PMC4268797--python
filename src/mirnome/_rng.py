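"""Deterministic random sub-stream derivation.

One root seed drives the whole pipeline.  Each stage (and each repetition
within a stage) derives its own independent generator from the root seed plus
a stable string/integer label, so adding a stage never perturbs the random
numbers another stage sees.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the sub-stream identified by ``labels``.

    Labels are hashed with CRC-32 (stable across platforms and sessions) and
    fed into a :class:`numpy.random.SeedSequence` together with the root seed.
    """
    keys = [zlib.crc32(str(label).encode("utf-8")) for label in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *keys]))
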