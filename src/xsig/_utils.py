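"""Shared helpers: seeded generators, interpolated quantiles, hashing."""

from __future__ import annotations

import hashlib
import zlib
from pathlib import Path

import numpy as np


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Named random generator for a pipeline stage.

    Each stage draws from its own stream, keyed by (seed, crc32(stage)),
    so adding or reordering stages never perturbs another stage's draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(stage.encode())])
    )


def iqr(values: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Inter-quartile range (Q3 - Q1) with linear-interpolation quantiles."""
    q1, q3 = np.percentile(values, [25, 75], axis=axis, method="linear")
    return q3 - q1


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
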