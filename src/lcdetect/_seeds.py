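"""Deterministic seed splitting.

One user-facing integer seed expands into independent child streams, one per
purpose, via :class:`numpy.random.SeedSequence` spawn keys.  Stages can
therefore be rerun independently without perturbing each other's randomness.
"""

from __future__ import annotations

import numpy as np

DEFAULT_SEED = 20220402

#: fixed purpose -> spawn-key assignment; never reorder existing entries.
PURPOSES = {
    "sides": 0,
    "order": 1,
    "responses": 2,
    "random_effects": 3,
    "invalid": 4,
}


def child_rng(seed: int, purpose: str) -> np.random.Generator:
    """Return the child generator of `seed` dedicated to `purpose`."""
    try:
        key = PURPOSES[purpose]
    except KeyError:
        raise ValueError(f"unknown seed purpose {purpose!r}") from None
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
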