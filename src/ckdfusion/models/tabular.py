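"""Feed-forward tabular branch.

Hidden layers follow the recurrence ``H(l) = sigma(H(l-1) @ W(l).T + B(l))``
with ``H(0) = X``; the output layer is a single sigmoid unit. The last
hidden activation matrix is exposed as the tabular embedding T for fusion.
With zero hidden layers the model degenerates to a logistic unit.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from ckdfusion.models import autodiff as ad
from ckdfusion.models.base import Model
from ckdfusion.models.gcn import _transpose
from ckdfusion.models.params import init_params, zeros


class TabularModel(Model):

    family = "tabular"
    full_batch = False

    def __init__(self, in_dim: int, hidden_dims: Sequence[int] = (64, 32),
                 activation: str = "relu", seed: int = 0,
                 init_scheme: str = "glorot_uniform"):
        super().__init__()
        self.in_dim = int(in_dim)
        self.hidden_dims = tuple(int(m) for m in hidden_dims)
        self.activation = activation
        self.seed = seed
        self.init_scheme = init_scheme
        rng = np.random.default_rng(seed)
        dims = (self.in_dim,) + self.hidden_dims
        for l, (m_in, m_out) in enumerate(zip(dims[:-1], dims[1:])):
            self._register(f"hidden{l}.W",
                           init_params((m_out, m_in), init_scheme, rng))
            self._register(f"hidden{l}.b", zeros((m_out,)))
        self._register("out.W", init_params((1, dims[-1]), init_scheme, rng))
        self._register("out.b", zeros((1,)))

    @property
    def embedding_dim(self) -> int:
        return self.hidden_dims[-1] if self.hidden_dims else self.in_dim

    def embed_t(self, X: np.ndarray) -> ad.Tensor:
        """Hidden stack only: the q-dimensional embeddings T (= H(L))."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.in_dim:
            raise ValueError(
                f"X shape {X.shape} incompatible with in_dim {self.in_dim}")
        act = ad.ACTIVATIONS[self.activation]
        H = ad.Tensor(X)
        for l in range(len(self.hidden_dims)):
            W, b = self.params[f"hidden{l}.W"], self.params[f"hidden{l}.b"]
            H = act(ad.add_bias(ad.matmul(H, _transpose(W)), b))
        return H

    def forward_t(self, X: np.ndarray) -> Tuple[ad.Tensor, ad.Tensor]:
        emb = self.embed_t(X)
        W, b = self.params["out.W"], self.params["out.b"]
        out = ad.sigmoid(ad.add_bias(ad.matmul(emb, _transpose(W)), b))
        return ad.ravel(out), emb

    def config(self) -> dict:
        return {"in_dim": self.in_dim, "hidden_dims": list(self.hidden_dims),
                "activation": self.activation, "seed": self.seed,
                "init_scheme": self.init_scheme}


def tabular_forward(model: TabularModel, X: np.ndarray,
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """(per-row probabilities, last-hidden-layer embeddings)."""
    return model.forward(X)
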