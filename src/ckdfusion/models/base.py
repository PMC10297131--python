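"""Shared model plumbing: parameter registry and checkpointing."""

from __future__ import annotations

import json
from typing import Dict, List, Tuple

import numpy as np

from ckdfusion.models.autodiff import Tensor


class Model:
    """Base class for the forward architectures.

    Subclasses register parameters as :class:`Tensor` leaves in
    ``self.params`` and implement ``forward_t``; optimizers update the leaf
    arrays in place so the graph rebuilt at each step sees fresh values.
    ``full_batch`` marks transductive models that must always see every
    node (graph branch present).
    """

    family: str = "base"
    full_batch: bool = False

    def __init__(self) -> None:
        self.params: Dict[str, Tensor] = {}

    def _register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value)
        self.params[name] = t
        return t

    def param_list(self) -> List[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()

    def forward_t(self, X: np.ndarray) -> Tuple[Tensor, Tensor]:
        raise NotImplementedError

    def forward(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Numpy-facing forward pass: (scores, embeddings)."""
        s, e = self.forward_t(np.asarray(X, dtype=float))
        return s.value.copy(), e.value.copy()

    # -- checkpointing ------------------------------------------------------

    def config(self) -> dict:
        raise NotImplementedError

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: t.value.copy() for k, t in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        missing = set(self.params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in state.items():
            if self.params[k].value.shape != np.asarray(v).shape:
                raise ValueError(f"shape mismatch for {k!r}")
            self.params[k].value[...] = v

    def save_checkpoint(self, json_path: str, arrays_path: str) -> None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump({"family": self.family, "config": self.config()},
                      fh, indent=2, default=str)
        np.savez(arrays_path, **self.state_dict())
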