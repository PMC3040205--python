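"""Deterministic random-stream derivation.

All randomness in a run flows from one integer seed; each stage derives an
independent substream from (seed, stage name) so stages are individually
reproducible regardless of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def _stage_key(stage: str) -> int:
    # crc32 is stable across platforms and Python versions (unlike hash()).
    return zlib.crc32(stage.encode("utf-8"))


def substream(seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Return a Generator for ``stage`` derived deterministically from ``seed``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _stage_key(stage), *map(int, extra)])
    )


def subseed(seed: int, stage: str, *extra: int) -> int:
    """Derive a plain integer sub-seed (for APIs that take ``seed: int``)."""
    ss = np.random.SeedSequence([int(seed), _stage_key(stage), *map(int, extra)])
    return int(ss.generate_state(1, dtype=np.uint64)[0])
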