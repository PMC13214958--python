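"""Shared helpers: deterministic seed fan-out."""

from __future__ import annotations

import zlib

import numpy as np


def spawn_seed(seed: int, label: str) -> int:
    """Derive a stage-specific child seed from a run seed.

    Deterministic in ``(seed, label)`` and independent across labels, so
    enabling or disabling one pipeline stage never shifts the randomness
    of another.  The result is always below 2**31.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(label.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))
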