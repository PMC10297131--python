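"""Late-fusion model: averaging head over graph and tabular embeddings.

The graph branch emits G (n x p), the tabular branch T (n x q); two
dimension-matching transforms map both into a shared p'-dimensional space,
their elementwise average F_avg is taken, and a sigmoid head produces the
final per-patient probability. The whole composite is trained end-to-end
through a single loss.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from ckdfusion.graph import NormalizedAdjacency
from ckdfusion.models import autodiff as ad
from ckdfusion.models.base import Model
from ckdfusion.models.gcn import GCNModel, _transpose
from ckdfusion.models.params import init_params, zeros
from ckdfusion.models.tabular import TabularModel


class FusionModel(Model):

    family = "fusion"
    full_batch = True

    def __init__(self, adjacency: NormalizedAdjacency, in_dim: int,
                 conv_dims: Sequence[int] = (32, 16),
                 tab_hidden_dims: Sequence[int] = (64, 32),
                 p_prime: int = 16, activation: str = "relu",
                 transform_activation: str = "relu", seed: int = 0,
                 init_scheme: str = "glorot_uniform"):
        super().__init__()
        self.p_prime = int(p_prime)
        self.transform_activation = transform_activation
        self.activation = activation
        self.seed = seed
        self.init_scheme = init_scheme
        # branch sub-models contribute their conv/hidden stacks only; their
        # own heads are never used here
        self.gnn = GCNModel(adjacency, in_dim, conv_dims,
                            activation=activation, seed=seed,
                            init_scheme=init_scheme)
        self.tab = TabularModel(in_dim, tab_hidden_dims,
                                activation=activation, seed=seed + 1,
                                init_scheme=init_scheme)
        rng = np.random.default_rng(seed + 2)
        p, q, pp = self.gnn.embedding_dim, self.tab.embedding_dim, self.p_prime
        for name, t in self.gnn.params.items():
            if name.startswith("conv"):
                self.params[f"gnn.{name}"] = t
        for name, t in self.tab.params.items():
            if name.startswith("hidden"):
                self.params[f"tab.{name}"] = t
        self._register("transform_g.W", init_params((pp, p), init_scheme, rng))
        self._register("transform_g.b", zeros((pp,)))
        self._register("transform_t.W", init_params((pp, q), init_scheme, rng))
        self._register("transform_t.b", zeros((pp,)))
        self._register("head.W", init_params((1, pp), init_scheme, rng))
        self._register("head.b", zeros((1,)))

    def forward_t(self, X: np.ndarray) -> Tuple[ad.Tensor, ad.Tensor]:
        X = np.asarray(X, dtype=float)
        act = ad.ACTIVATIONS[self.transform_activation]
        G = self.gnn.embed_t(X)
        T = self.tab.embed_t(X)
        G_t = act(ad.add_bias(ad.matmul(G, _transpose(
            self.params["transform_g.W"])), self.params["transform_g.b"]))
        T_t = act(ad.add_bias(ad.matmul(T, _transpose(
            self.params["transform_t.W"])), self.params["transform_t.b"]))
        F_avg = ad.scale(ad.add(G_t, T_t), 0.5)
        out = ad.sigmoid(ad.add_bias(ad.matmul(F_avg, _transpose(
            self.params["head.W"])), self.params["head.b"]))
        return ad.ravel(out), F_avg

    def config(self) -> dict:
        return {"in_dim": self.gnn.in_dim,
                "conv_dims": list(self.gnn.conv_dims),
                "tab_hidden_dims": list(self.tab.hidden_dims),
                "p_prime": self.p_prime, "activation": self.activation,
                "transform_activation": self.transform_activation,
                "seed": self.seed, "init_scheme": self.init_scheme,
                "adjacency_scheme": self.gnn.adjacency.scheme}


def fusion_forward(model: FusionModel, X: np.ndarray,
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """(per-patient probabilities, fused representation F_avg)."""
    return model.forward(X)
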