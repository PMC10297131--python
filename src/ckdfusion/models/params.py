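"""Seeded parameter initialization."""

from __future__ import annotations

from typing import Tuple, Union

import numpy as np

SCHEMES = ("glorot_uniform", "he_uniform")


def _fans(shape: Tuple[int, ...]) -> Tuple[int, int]:
    # weight matrices are stored (fan_out, fan_in); vectors are biases
    if len(shape) == 1:
        return shape[0], shape[0]
    return shape[1], shape[0]


def init_params(shape: Tuple[int, ...], scheme: str = "glorot_uniform",
                seed: Union[int, np.random.Generator] = 0) -> np.ndarray:
    """Draw an initial parameter array.

    ``glorot_uniform``: U(-a, a) with a = sqrt(6 / (fan_in + fan_out));
    ``he_uniform``: U(-a, a) with a = sqrt(6 / fan_in). Same seed gives
    identical draws.
    """
    if any(s <= 0 for s in shape):
        raise ValueError(f"dimensions must be positive, got {shape}")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fan_in, fan_out = _fans(tuple(shape))
    if scheme == "glorot_uniform":
        a = np.sqrt(6.0 / (fan_in + fan_out))
    else:
        a = np.sqrt(6.0 / fan_in)
    return rng.uniform(-a, a, size=shape)


def zeros(shape: Tuple[int, ...]) -> np.ndarray:
    return np.zeros(shape, dtype=float)
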