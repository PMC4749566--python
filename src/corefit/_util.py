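"""Small numeric helpers shared across modules."""
from __future__ import annotations

import math

import numpy as np

#: Guard against float-representation error when f*U or theta*N is an exact
#: integer (e.g. 0.3*10 = 2.9999999999999996 must count as 3).
_REL_EPS = 1e-9


def scaled_floor(fraction: float, total: int) -> int:
    """floor(fraction * total), robust to binary-float representation."""
    return int(math.floor(fraction * total + _REL_EPS))


def scaled_ceil(fraction: float, total: int) -> int:
    """ceil(fraction * total), robust to binary-float representation."""
    v = fraction * total
    r = round(v)
    if abs(v - r) < _REL_EPS:
        return int(r)
    return int(math.ceil(v))


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    return np.random.default_rng(seed)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one master seed.

    Documented derivation: SeedSequence(master).generate_state(n) masked to
    31 bits, so every stage of a pipeline run is traceable to the master seed
    and stages can run in any order.
    """
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]
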