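"""Graph-convolutional branch.

Each conv layer computes ``sigma(A_hat @ H @ W.T + b)`` where ``A_hat`` is
the normalized adjacency (self-loops included) — the matrix form of the
per-node neighbourhood sum with 1/c_ij coefficients. A dense head with a
sigmoid output unit turns the final node embeddings into per-node
probabilities; the pre-head embedding matrix is exposed for fusion.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from ckdfusion.graph import NormalizedAdjacency
from ckdfusion.models import autodiff as ad
from ckdfusion.models.base import Model
from ckdfusion.models.params import init_params, zeros


def _transpose(t: ad.Tensor) -> ad.Tensor:
    return ad.Tensor(t.value.T, (t,), lambda g: (g.T,))


def gcn_layer_forward(H: np.ndarray, A: NormalizedAdjacency,
                      W: np.ndarray, b: np.ndarray,
                      activation: str = "relu") -> np.ndarray:
    """Single graph-convolution layer, numpy only.

    ``H`` is (n, m_in), ``W`` is (m_out, m_in), ``b`` is (m_out,).
    """
    H = np.asarray(H, dtype=float)
    if H.shape[0] != A.n_nodes:
        raise ValueError(
            f"H has {H.shape[0]} rows but adjacency has {A.n_nodes} nodes")
    if W.shape[1] != H.shape[1]:
        raise ValueError(
            f"W shape {W.shape} incompatible with H shape {H.shape}")
    pre = A.dot(H) @ W.T + b
    fn = ad.ACTIVATIONS[activation]
    if activation == "identity":
        return pre
    return fn(ad.Tensor(pre)).value


class GCNModel(Model):
    """Stack of graph-conv layers plus a dense prediction head.

    Parameters
    ----------
    adjacency
        Normalized adjacency over all nodes (transductive: the graph spans
        train, validation and test patients alike).
    conv_dims
        Hidden widths of the conv layers; input width is ``in_dim``. The
        last entry is the embedding dimensionality ``p``.
    head_dims
        Widths of dense head layers between the embedding and the scalar
        sigmoid output (empty for a single linear map).
    """

    family = "gnn"
    full_batch = True

    def __init__(self, adjacency: NormalizedAdjacency, in_dim: int,
                 conv_dims: Sequence[int] = (32, 16),
                 head_dims: Sequence[int] = (),
                 activation: str = "relu", seed: int = 0,
                 init_scheme: str = "glorot_uniform"):
        super().__init__()
        if not conv_dims:
            raise ValueError("need at least one conv layer")
        self.adjacency = adjacency
        self.in_dim = int(in_dim)
        self.conv_dims = tuple(int(m) for m in conv_dims)
        self.head_dims = tuple(int(m) for m in head_dims)
        self.activation = activation
        self.seed = seed
        self.init_scheme = init_scheme
        rng = np.random.default_rng(seed)
        dims = (self.in_dim,) + self.conv_dims
        for l, (m_in, m_out) in enumerate(zip(dims[:-1], dims[1:])):
            self._register(f"conv{l}.W",
                           init_params((m_out, m_in), init_scheme, rng))
            self._register(f"conv{l}.b", zeros((m_out,)))
        hdims = (self.conv_dims[-1],) + self.head_dims + (1,)
        for l, (m_in, m_out) in enumerate(zip(hdims[:-1], hdims[1:])):
            self._register(f"head{l}.W",
                           init_params((m_out, m_in), init_scheme, rng))
            self._register(f"head{l}.b", zeros((m_out,)))

    @property
    def embedding_dim(self) -> int:
        return self.conv_dims[-1]

    def embed_t(self, X: np.ndarray) -> ad.Tensor:
        """Conv stack only: the p-dimensional node embeddings G."""
        if X.shape[0] != self.adjacency.n_nodes:
            raise ValueError(
                f"X has {X.shape[0]} rows but adjacency has "
                f"{self.adjacency.n_nodes} nodes")
        if X.shape[1] != self.in_dim:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.in_dim}")
        act = ad.ACTIVATIONS[self.activation]
        H = ad.Tensor(X)
        for l in range(len(self.conv_dims)):
            W, b = self.params[f"conv{l}.W"], self.params[f"conv{l}.b"]
            H = ad.add_bias(ad.matmul(ad.spmm(self.adjacency.matrix, H),
                                      _transpose(W)), b)
            H = act(H)
        return H

    def forward_t(self, X: np.ndarray) -> Tuple[ad.Tensor, ad.Tensor]:
        emb = self.embed_t(np.asarray(X, dtype=float))
        H = emb
        act = ad.ACTIVATIONS[self.activation]
        n_head = len(self.head_dims) + 1
        for l in range(n_head):
            W, b = self.params[f"head{l}.W"], self.params[f"head{l}.b"]
            H = ad.add_bias(ad.matmul(H, _transpose(W)), b)
            H = ad.sigmoid(H) if l == n_head - 1 else act(H)
        return ad.ravel(H), emb

    def config(self) -> dict:
        return {"in_dim": self.in_dim, "conv_dims": list(self.conv_dims),
                "head_dims": list(self.head_dims),
                "activation": self.activation, "seed": self.seed,
                "init_scheme": self.init_scheme,
                "adjacency_scheme": self.adjacency.scheme}


def gcn_forward(model: GCNModel, X: np.ndarray,
                ) -> Tuple[np.ndarray, np.ndarray]:
    """(per-node probabilities, pre-head embeddings)."""
    return model.forward(X)
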