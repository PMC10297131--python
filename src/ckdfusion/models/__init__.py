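"""Forward architectures: GCN, tabular, fusion and baseline."""

from __future__ import annotations

from typing import Optional

from ckdfusion.graph import NormalizedAdjacency
from ckdfusion.models.base import Model
from ckdfusion.models.baseline import BaselineModel, baseline_forward
from ckdfusion.models.fusion import FusionModel, fusion_forward
from ckdfusion.models.gcn import GCNModel, gcn_forward, gcn_layer_forward
from ckdfusion.models.params import init_params
from ckdfusion.models.tabular import TabularModel, tabular_forward

FAMILIES = ("fusion", "gnn", "tabular", "baseline")


def build_model(family: str, in_dim: int,
                adjacency: Optional[NormalizedAdjacency] = None,
                arch: Optional[dict] = None, seed: int = 0) -> Model:
    """Construct a model of the given family from an architecture dict."""
    arch = dict(arch or {})
    arch.pop("seed", None)
    if family == "gnn":
        if adjacency is None:
            raise ValueError("gnn requires an adjacency")
        return GCNModel(adjacency, in_dim, seed=seed, **arch)
    if family == "tabular":
        return TabularModel(in_dim, seed=seed, **arch)
    if family == "fusion":
        if adjacency is None:
            raise ValueError("fusion requires an adjacency")
        return FusionModel(adjacency, in_dim, seed=seed, **arch)
    if family == "baseline":
        return BaselineModel(in_dim, seed=seed, **arch)
    raise ValueError(f"unknown model family {family!r}; "
                     f"choose from {FAMILIES}")


__all__ = [
    "Model", "GCNModel", "TabularModel", "FusionModel", "BaselineModel",
    "build_model", "init_params", "gcn_layer_forward", "gcn_forward",
    "tabular_forward", "fusion_forward", "baseline_forward", "FAMILIES",
]
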