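"""Small shared helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["round_half_away", "child_rng"]


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (the tables' arithmetic convention),
    unlike numpy's banker's rounding. Vectorised."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    # nextafter guards against values like 2.675 stored just below the half
    scaled = np.nextafter(np.abs(x) * factor, np.abs(x) * factor + 1.0)
    out = np.sign(x) * np.floor(scaled + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-entity stream: the draws for entity ``key`` do not
    move when other entities are added to the same simulation."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    )
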