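"""Baseline: a single sigmoid unit over the raw features (logistic form).

Equivalent by construction to :class:`TabularModel` with zero hidden
layers; kept as its own family for the four-way comparison protocol.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from ckdfusion.models import autodiff as ad
from ckdfusion.models.base import Model
from ckdfusion.models.gcn import _transpose
from ckdfusion.models.params import init_params, zeros


class BaselineModel(Model):

    family = "baseline"
    full_batch = False

    def __init__(self, in_dim: int, seed: int = 0,
                 init_scheme: str = "glorot_uniform"):
        super().__init__()
        self.in_dim = int(in_dim)
        self.seed = seed
        self.init_scheme = init_scheme
        rng = np.random.default_rng(seed)
        self._register("W", init_params((1, self.in_dim), init_scheme, rng))
        self._register("b", zeros((1,)))

    def forward_t(self, X: np.ndarray) -> Tuple[ad.Tensor, ad.Tensor]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.in_dim:
            raise ValueError(
                f"X shape {X.shape} incompatible with in_dim {self.in_dim}")
        emb = ad.Tensor(X)
        out = ad.sigmoid(ad.add_bias(
            ad.matmul(emb, _transpose(self.params["W"])), self.params["b"]))
        return ad.ravel(out), emb

    def config(self) -> dict:
        return {"in_dim": self.in_dim, "seed": self.seed,
                "init_scheme": self.init_scheme}


def baseline_forward(model: BaselineModel, X: np.ndarray) -> np.ndarray:
    """Per-row probabilities sigmoid(X @ w + b)."""
    return model.forward(X)[0]
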