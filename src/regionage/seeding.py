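"""Deterministic named RNG streams.

One master seed governs every stage of the pipeline. Sub-streams are derived
from (seed, *labels) keys so any stage/region can be re-run in isolation and
reproduce exactly what the end-to-end run did.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "stream_seed"]


def _key_ints(labels: tuple) -> list[int]:
    out = []
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            out.append(int(lab) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(lab).encode("utf-8")))
    return out


def stream(seed: int, *labels) -> np.random.Generator:
    """Return a Generator for the sub-stream named by ``labels``.

    Identical (seed, labels) always yields an identical stream; distinct
    labels yield statistically independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + _key_ints(labels)))


def stream_seed(seed: int, *labels) -> int:
    """A 31-bit integer seed derived from a named sub-stream (for libraries
    that take plain int seeds, e.g. scikit-learn)."""
    ss = np.random.SeedSequence([int(seed)] + _key_ints(labels))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
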