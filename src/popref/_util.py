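"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (Python's built-in round is banker's)."""
    factor = 10.0**ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1.0 if scaled >= 0 else -1.0)
    return rounded / factor


def spawn_rng(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent generator for a named stream from one global seed.

    Identical (seed, stream) pairs always yield identical generators.
    """
    ss = np.random.SeedSequence([seed, *(ord(c) for c in stream)])
    return np.random.default_rng(ss)
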