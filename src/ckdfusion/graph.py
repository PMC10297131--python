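"""Weighted k-nearest-neighbour patient-similarity graph and its
normalized adjacency operator.

Each patient is a node; a directed k-NN relation (self excluded) is
computed per row under the chosen distance metric and symmetrized by union
into an undirected edge set. Edge weights default to the inverse distance
``1 / (s + epsilon)``; ``epsilon`` caps the weight of duplicate patients.
Self-loops are not stored on the graph — they are added (with weight 1)
when the adjacency operator is normalized for graph convolution.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

METRICS = ("euclidean", "manhattan", "cosine")


@dataclass
class PatientGraph:
    """Undirected weighted graph over patients.

    ``weights`` maps each undirected edge ``(i, j)`` with ``i < j`` to a
    strictly positive finite weight.
    """

    n_nodes: int
    weights: Dict[Tuple[int, int], float]
    knn_k: int
    metric: str
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        for (i, j), w in self.weights.items():
            if i == j:
                raise ValueError(f"self-edge ({i},{i}) must not be stored")
            if not (i < j):
                raise ValueError(f"edge ({i},{j}) must be stored with i < j")
            if not (0 <= i < self.n_nodes and j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) out of range")
            if not (w > 0 and np.isfinite(w)):
                raise ValueError(f"edge ({i},{j}) weight {w} not positive "
                                 "finite")

    @property
    def edges(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(sorted(self.weights))

    @property
    def n_edges(self) -> int:
        return len(self.weights)


@dataclass
class NormalizedAdjacency:
    """Sparse normalized adjacency with self-loops, ready for convolution.

    ``scheme='sym'`` gives the symmetric normalization
    ``a_ij / sqrt(d_i d_j)``; ``scheme='row'`` gives ``a_ij / d_i`` whose
    rows sum to one.
    """

    n_nodes: int
    matrix: sp.csr_matrix
    scheme: str

    def dot(self, H: np.ndarray) -> np.ndarray:
        return self.matrix @ H


def pairwise_distance(X: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Symmetric n x n distance matrix with a zero diagonal.

    Cosine is handled as cosine *distance* (1 - cosine similarity); a
    zero-norm row under cosine raises naming the row.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("pairwise_distance requires no missing values")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        zero = np.flatnonzero(norms == 0)
        if zero.size:
            raise ValueError(f"zero-norm row(s) {zero.tolist()} under cosine")
    D = cdist(X, X, metric={"manhattan": "cityblock"}.get(metric, metric))
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def knn_neighbors(D: np.ndarray, k: int) -> np.ndarray:
    """Directed k-NN relation: for each row the k nearest other rows,
    nearest first (ties broken by lower index, stable)."""
    n = D.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"need n > k >= 1, got n={n}, k={k}")
    D = D.copy()
    np.fill_diagonal(D, np.inf)
    return np.argsort(D, axis=1, kind="stable")[:, :k]


def build_knn_graph(X: np.ndarray, k: int = 5, metric: str = "euclidean",
                    epsilon: float = 1e-8,
                    weight_mode: str = "inverse_distance") -> PatientGraph:
    """Union-symmetrized k-NN graph with inverse-distance (or unit) weights.

    ``w_ij = 1 / (s(x_i, x_j) + epsilon)`` so duplicate rows get the
    maximal finite weight ``1 / epsilon``.
    """
    if weight_mode not in ("inverse_distance", "unit"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    X = np.asarray(X, dtype=float)
    D = pairwise_distance(X, metric)
    nbrs = knn_neighbors(D, k)
    weights: Dict[Tuple[int, int], float] = {}
    for i in range(X.shape[0]):
        for j in nbrs[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) not in weights:
                w = 1.0 if weight_mode == "unit" else 1.0 / (D[a, b] + epsilon)
                weights[(a, b)] = w
    return PatientGraph(n_nodes=X.shape[0], weights=weights, knn_k=k,
                        metric=metric, epsilon=epsilon)


def normalize_adjacency(g: PatientGraph, scheme: str = "sym",
                        use_weights: bool = True) -> NormalizedAdjacency:
    """Add unit self-loops and normalize.

    ``sym``: D^(-1/2) (A + I) D^(-1/2) with (weighted) degrees including the
    self-loop. ``row``: D^(-1) (A + I), rows summing to one. The self-loop
    weight is 1 regardless of the edge weight mode.
    """
    if scheme not in ("sym", "row"):
        raise ValueError(f"unknown scheme {scheme!r}")
    n = g.n_nodes
    rows, cols, vals = [], [], []
    for (i, j), w in g.weights.items():
        wij = w if use_weights else 1.0
        rows += [i, j]
        cols += [j, i]
        vals += [wij, wij]
    rows += list(range(n))
    cols += list(range(n))
    vals += [1.0] * n
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    if scheme == "sym":
        dinv = 1.0 / np.sqrt(deg)
        M = sp.diags(dinv) @ A @ sp.diags(dinv)
    else:
        M = sp.diags(1.0 / deg) @ A
    return NormalizedAdjacency(n_nodes=n, matrix=M.tocsr(), scheme=scheme)


def save_graph(g: PatientGraph, edges_path: str, header_path: str) -> None:
    """Write the weighted edge list (``i<TAB>j<TAB>w``, i < j, 0-based) and
    a JSON header; :func:`load_graph` restores it bit-exactly."""
    with open(edges_path, "w", encoding="utf-8") as fh:
        for (i, j) in sorted(g.weights):
            fh.write(f"{i}\t{j}\t{float(g.weights[(i, j)])!r}\n")
    with open(header_path, "w", encoding="utf-8") as fh:
        json.dump({"n_nodes": g.n_nodes, "k": g.knn_k, "metric": g.metric,
                   "epsilon": g.epsilon}, fh, indent=2)


def load_graph(edges_path: str, header_path: str) -> PatientGraph:
    with open(header_path, "r", encoding="utf-8") as fh:
        head = json.load(fh)
    weights: Dict[Tuple[int, int], float] = {}
    if os.path.getsize(edges_path) > 0:
        with open(edges_path, "r", encoding="utf-8") as fh:
            for line in fh:
                i_s, j_s, w_s = line.rstrip("\n").split("\t")
                weights[(int(i_s), int(j_s))] = float(w_s)
    return PatientGraph(n_nodes=head["n_nodes"], weights=weights,
                        knn_k=head["k"], metric=head["metric"],
                        epsilon=head["epsilon"])
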