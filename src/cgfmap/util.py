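"""Small numeric helpers shared across modules."""
from __future__ import annotations

import zlib

import numpy as np
from scipy.special import expit as _expit

LOGIT_EPS = 1e-6
LOGIT_CLIP = 12.0


def expit(x):
    return _expit(x)


def logit(p, eps: float = LOGIT_EPS):
    """Logit with epsilon-clipping at the [0, 1] boundary."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("prevalence outside [0, 1]")
    p = np.clip(p, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def clip_logit(x, bound: float = LOGIT_CLIP):
    return np.clip(x, -bound, bound)


def _salt_to_int(s) -> int:
    if isinstance(s, (int, np.integer)):
        return int(s) & 0x7FFFFFFF
    return zlib.crc32(str(s).encode()) & 0x7FFFFFFF


def rng_from_seed(seed, *salt) -> np.random.Generator:
    """Independent generator derived from (seed, salt...); deterministic across runs."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *map(_salt_to_int, salt)])
    )
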