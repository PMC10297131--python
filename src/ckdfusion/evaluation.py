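"""Training loop, metric protocol, grid search and the four-model
comparison.

Training minimizes mean binary cross-entropy (plus optional L2) with SGD
or Adam; graph-bearing models (gnn, fusion) train full-batch with node
masks over one fixed transductive graph, tabular/baseline models train on
minibatches. Per-epoch loss and accuracy are recorded on the train and
test roles. Grid search exhaustively enumerates the Cartesian product of
candidate values and selects by validation accuracy (or F1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ckdfusion.graph import NormalizedAdjacency
from ckdfusion.models import Model, build_model
from ckdfusion.models import autodiff as ad
from ckdfusion.preprocess import SplitAssignment

CLAMP_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.05
    epochs: int = 200
    batch_size: int = 32
    l2: float = 0.0
    optimizer: str = "adam"
    early_stop_patience: Optional[int] = None
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class Metrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)
    train_accuracy: List[float] = field(default_factory=list)
    test_loss: List[float] = field(default_factory=list)
    test_accuracy: List[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_dict(self) -> dict:
        return asdict(self)


def bce_loss(scores: np.ndarray, labels: np.ndarray, l2: float = 0.0,
             params: Sequence[np.ndarray] = ()) -> float:
    """Mean binary cross-entropy (scores clamped at 1e-12) plus
    ``l2 * sum of squared parameters``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.size == 0:
        raise ValueError("empty supervision set")
    p = np.clip(scores, CLAMP_EPS, 1.0 - CLAMP_EPS)
    loss = float(-(labels * np.log(p) + (1 - labels) * np.log(1 - p)).mean())
    return loss + l2 * sum(float((w ** 2).sum()) for w in params)


def predict_labels(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff score >= threshold (boundary inclusive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    threshold: float = 0.5) -> Metrics:
    """Confusion counts and derived accuracy/precision/recall/F1.

    Ratios with a zero denominator are reported as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length, nonempty")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("inputs must be binary 0/1 vectors")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = tp + tn + fp + fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return Metrics(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=(tp + tn) / n,
                   precision=precision, recall=recall, f1=f1,
                   threshold=threshold)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class _Optimizer:
    def __init__(self, params: List[ad.Tensor], lr: float):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        raise NotImplementedError


class _SGD(_Optimizer):
    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.value -= self.lr * p.grad


class _Adam(_Optimizer):
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1 ** self.t)
            vhat = self.v[i] / (1 - self.beta2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _make_optimizer(name: str, params: List[ad.Tensor], lr: float):
    return {"sgd": _SGD, "adam": _Adam}[name](params, lr)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _loss_tensor(model: Model, scores: ad.Tensor, idx: np.ndarray,
                 y: np.ndarray, l2: float) -> ad.Tensor:
    sel = ad.gather_rows(scores, idx)
    loss = ad.bce_mean(sel, y[idx], eps=CLAMP_EPS)
    if l2 > 0:
        for p in model.param_list():
            loss = ad.add(loss, ad.scale(ad.sumsq(p), l2))
    return loss


def _eval_role(model: Model, X: np.ndarray, y: np.ndarray,
               idx: np.ndarray) -> Tuple[float, float]:
    if model.full_batch:
        scores = model.forward(X)[0][idx]
    else:
        scores = model.forward(X[idx])[0]
    loss = bce_loss(scores, y[idx])
    acc = compute_metrics(y[idx], predict_labels(scores)).accuracy
    return loss, acc


def train(model: Model, X: np.ndarray, y: np.ndarray, config: TrainConfig,
          split: SplitAssignment) -> Tuple[Model, TrainingHistory]:
    """Seeded optimization of the BCE objective on the training role.

    Full-batch models take one gradient step per epoch over the masked
    node set; minibatch models shuffle and sweep the training rows. The
    history records loss/accuracy on the train and test roles each epoch;
    with ``early_stop_patience`` set, training stops after that many
    epochs without validation-loss improvement and the best-epoch
    parameters are restored.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    train_idx = split.indices("train")
    val_idx = split.indices("val")
    test_idx = split.indices("test")
    if train_idx.size == 0:
        raise ValueError("training role is empty")
    rng = np.random.default_rng(config.seed)
    opt = _make_optimizer(config.optimizer, model.param_list(),
                          config.learning_rate)
    history = TrainingHistory()
    best_val, best_state, stale = np.inf, None, 0
    for _epoch in range(config.epochs):
        if model.full_batch:
            model.zero_grad()
            scores, _ = model.forward_t(X)
            loss = _loss_tensor(model, scores, train_idx, y, config.l2)
            if not np.isfinite(loss.value):
                raise RuntimeError(
                    "non-finite training loss; try a lower learning rate")
            ad.backward(loss)
            opt.step()
        else:
            order = rng.permutation(train_idx)
            for start in range(0, len(order), config.batch_size):
                batch = order[start:start + config.batch_size]
                model.zero_grad()
                scores, _ = model.forward_t(X[batch])
                loss = ad.bce_mean(scores, y[batch], eps=CLAMP_EPS)
                if config.l2 > 0:
                    for p in model.param_list():
                        loss = ad.add(loss, ad.scale(ad.sumsq(p), config.l2))
                if not np.isfinite(loss.value):
                    raise RuntimeError(
                        "non-finite training loss; try a lower learning rate")
                ad.backward(loss)
                opt.step()
        tr_loss, tr_acc = _eval_role(model, X, y, train_idx)
        te_loss, te_acc = _eval_role(model, X, y, test_idx)
        history.train_loss.append(tr_loss)
        history.train_accuracy.append(tr_acc)
        history.test_loss.append(te_loss)
        history.test_accuracy.append(te_acc)
        if config.early_stop_patience is not None and val_idx.size:
            val_loss, _ = _eval_role(model, X, y, val_idx)
            if val_loss < best_val - 1e-12:
                best_val, best_state, stale = val_loss, model.state_dict(), 0
            else:
                stale += 1
                if stale > config.early_stop_patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# model evaluation, grid search, comparison
# ---------------------------------------------------------------------------

def evaluate(model: Model, X: np.ndarray, y: np.ndarray,
             idx: np.ndarray, threshold: float = 0.5) -> Metrics:
    """Metrics of a trained model on the rows ``idx``."""
    if model.full_batch:
        scores = model.forward(X)[0][idx]
    else:
        scores = model.forward(X[idx])[0]
    return compute_metrics(y[idx], predict_labels(scores, threshold),
                           threshold)


_TRAIN_FIELDS = set(TrainConfig.__dataclass_fields__)


def _split_point(point: Dict[str, object], base: TrainConfig,
                 ) -> Tuple[dict, TrainConfig]:
    arch = {k: v for k, v in point.items() if k not in _TRAIN_FIELDS}
    overrides = {k: v for k, v in point.items() if k in _TRAIN_FIELDS}
    return arch, replace(base, **overrides)


def grid_search(family: str, X: np.ndarray, y: np.ndarray,
                split: SplitAssignment, grid: Dict[str, Iterable],
                adjacency: Optional[NormalizedAdjacency] = None,
                base_config: Optional[TrainConfig] = None,
                base_arch: Optional[dict] = None,
                selection_metric: str = "accuracy",
                ) -> Tuple[dict, List[dict]]:
    """Exhaustive grid search over the Cartesian product of ``grid``.

    Keys matching :class:`TrainConfig` fields override the training
    configuration; any other key is passed to the model constructor. Each
    point trains one seeded model and is scored on the validation role.
    Ties keep the earlier enumeration point. A training failure scores
    ``-inf`` instead of aborting the search.

    Returns (best point, leaderboard sorted by score descending).
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    if selection_metric not in ("accuracy", "f1"):
        raise ValueError(f"unknown selection metric {selection_metric!r}")
    base_config = base_config or TrainConfig()
    keys = list(grid)
    leaderboard: List[dict] = []
    val_idx = split.indices("val")
    if val_idx.size == 0:
        raise ValueError("validation role is empty")
    for rank, values in enumerate(itertools.product(*(grid[k] for k in keys))):
        point = dict(zip(keys, values))
        arch, cfg = _split_point(point, base_config)
        arch = {**(base_arch or {}), **arch}
        try:
            model = build_model(family, X.shape[1], adjacency, arch,
                                seed=cfg.seed)
            model, _ = train(model, X, y, cfg, split)
            metrics = evaluate(model, X, y, val_idx)
            score = getattr(metrics, selection_metric)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            score, metrics = -np.inf, None
            point = {**point, "error": str(exc)}
        leaderboard.append({"point": point, "score": float(score),
                            "order": rank})
    leaderboard.sort(key=lambda e: (-e["score"], e["order"]))
    best = leaderboard[0]["point"]
    if "error" in best:
        raise RuntimeError("every grid point failed to train")
    return best, leaderboard


def compare_models(X: np.ndarray, y: np.ndarray, split: SplitAssignment,
                   adjacency: NormalizedAdjacency,
                   configs: Optional[Dict[str, Tuple[dict, TrainConfig]]] = None,
                   seed: int = 0) -> Dict[str, dict]:
    """Train fusion, gnn, tabular and baseline under identical splits and
    report per-model test metrics, confusion matrices and histories."""
    configs = configs or {}
    table: Dict[str, dict] = {}
    for family in ("fusion", "gnn", "tabular", "baseline"):
        arch, cfg = configs.get(family, ({}, TrainConfig(seed=seed)))
        model = build_model(family, X.shape[1], adjacency, arch,
                            seed=cfg.seed)
        model, history = train(model, X, y, cfg, split)
        metrics = evaluate(model, X, y, split.indices("test"))
        table[family] = {
            "model": family,
            "metrics": metrics.to_dict(),
            "confusion": [[metrics.tn, metrics.fp],
                          [metrics.fn, metrics.tp]],
            "history": history.to_dict(),
        }
    return table


def repeated_splits(X: np.ndarray, y: np.ndarray,
                    adjacency: NormalizedAdjacency,
                    fractions: Tuple[float, float, float] = (0.7, 0.15, 0.15),
                    n_repeats: int = 5, seed: int = 0,
                    configs: Optional[dict] = None) -> List[Dict[str, dict]]:
    """Seeded repeated-split robustness loop over :func:`compare_models`."""
    from ckdfusion.preprocess import split as make_split
    out = []
    for r in range(n_repeats):
        assignment = make_split(y, fractions, seed=seed + r)
        out.append(compare_models(X, y, assignment, adjacency,
                                  configs=configs, seed=seed + r))
    return out
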