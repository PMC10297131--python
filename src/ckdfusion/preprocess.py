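"""Cleaning chain for CKD tables: complete-case filtering, median/mode
imputation, IQR winsorization, min-max / z-score normalization, from-scratch
SMOTE oversampling, and the stratified train/val/test partition.

The default pipeline order mirrors the source protocol — complete-case
filter, SMOTE up to the target total, then split — while
``leakage_safe=True`` switches to the statistically sound order
(split first, oversample the training role only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from ckdfusion.data_io import BINARY, Dataset, NUMERIC

ROLES = ("train", "val", "test")


@dataclass(frozen=True)
class PreprocessConfig:
    impute_strategy: str = "median_mode"          # or "complete_case"
    outlier_rule: str = "none"                    # or "iqr_winsorize"
    outlier_k: float = 1.5
    normalize: str = "minmax"                     # "minmax" | "zscore" | "none"
    smote_enabled: bool = True
    smote_target_total: int = 2000
    smote_k_neighbors: int = 5
    smote_seed: int = 0
    split_fractions: Tuple[float, float, float] = (0.7, 0.15, 0.15)
    split_seed: int = 0
    leakage_safe: bool = False

    def validate(self) -> None:
        if self.impute_strategy not in ("median_mode", "complete_case"):
            raise ValueError(
                f"unknown impute_strategy {self.impute_strategy!r}")
        if self.outlier_rule not in ("none", "iqr_winsorize"):
            raise ValueError(f"unknown outlier_rule {self.outlier_rule!r}")
        if self.normalize not in ("minmax", "zscore", "none"):
            raise ValueError(f"unknown normalize {self.normalize!r}")
        fr = self.split_fractions
        if len(fr) != 3 or any(f <= 0 for f in fr):
            raise ValueError("split fractions must be three positive numbers")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.smote_k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class SplitAssignment:
    """Per-row role tags forming an exhaustive, disjoint partition."""

    roles: np.ndarray  # array of 'train' | 'val' | 'test'

    def __post_init__(self) -> None:
        self.roles = np.asarray(self.roles, dtype=object)
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.roles)

    def indices(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return np.flatnonzero(self.roles == role)

    def mask(self, role: str) -> np.ndarray:
        return self.roles == role


@dataclass
class NormalizerState:
    """Per-column statistics so held-out splits reuse fitted parameters."""

    method: str
    lo: np.ndarray    # minmax: column minima;  zscore: means
    hi: np.ndarray    # minmax: column maxima;  zscore: stds

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.method == "none":
            return X.copy()
        if self.method == "minmax":
            span = self.hi - self.lo
            out = np.zeros_like(X, dtype=float)
            nz = span != 0
            out[:, nz] = (X[:, nz] - self.lo[nz]) / span[nz]
            return out
        if self.method == "zscore":
            out = np.zeros_like(X, dtype=float)
            nz = self.hi != 0
            out[:, nz] = (X[:, nz] - self.lo[nz]) / self.hi[nz]
            return out
        raise ValueError(f"unknown method {self.method!r}")


def complete_cases(ds: Dataset) -> Dataset:
    """Keep exactly the rows with no missing cell, preserving order."""
    keep = ~ds.mask.any(axis=1)
    if not keep.any():
        raise ValueError(
            "no complete cases remain; use impute_strategy='median_mode'")
    return ds.take(np.flatnonzero(keep))


def impute(ds: Dataset, strategy: str = "median_mode") -> Dataset:
    """Fill masked cells: numeric/ordinal columns with the observed median,
    binary columns with the modal code. Observed cells are untouched."""
    if strategy != "median_mode":
        raise ValueError(f"unknown impute strategy {strategy!r}")
    X = ds.X.copy()
    for j, name in enumerate(ds.schema.names):
        col_mask = ds.mask[:, j]
        if not col_mask.any():
            continue
        observed = X[~col_mask, j]
        if observed.size == 0:
            raise ValueError(f"column {name!r} is fully missing")
        if ds.schema.kinds[name] == BINARY:
            codes, counts = np.unique(observed, return_counts=True)
            fill = codes[np.argmax(counts)]
        else:
            fill = np.median(observed)
        X[col_mask, j] = fill
    return replace(ds, X=X, mask=np.zeros_like(ds.mask))


def winsorize_outliers(ds: Dataset, k: float = 1.5) -> Dataset:
    """Clip numeric columns to [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation (numpy's default, R type 7) over the
    observed cells; categorical (binary and ordinal) columns are untouched.
    """
    X = ds.X.copy()
    for j, name in enumerate(ds.schema.names):
        if ds.schema.kinds[name] != NUMERIC:
            continue
        observed = ~ds.mask[:, j]
        if not observed.any():
            continue
        q1, q3 = np.quantile(X[observed, j], [0.25, 0.75])
        lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
        X[observed, j] = np.clip(X[observed, j], lo, hi)
    return replace(ds, X=X)


def fit_normalizer(X: np.ndarray, method: str = "minmax") -> NormalizerState:
    if method == "none":
        d = X.shape[1]
        return NormalizerState("none", np.zeros(d), np.ones(d))
    if method == "minmax":
        return NormalizerState("minmax", X.min(axis=0), X.max(axis=0))
    if method == "zscore":
        return NormalizerState("zscore", X.mean(axis=0), X.std(axis=0))
    raise ValueError(f"unknown normalize method {method!r}")


def normalize(ds: Dataset, method: str = "minmax",
              split: Optional[SplitAssignment] = None,
              ) -> Tuple[Dataset, NormalizerState]:
    """Normalize every column, fitting statistics on the train role when a
    split is supplied (whole data otherwise). Constant columns map to 0."""
    if ds.mask.any():
        raise ValueError("normalize requires a dataset with no missing cells")
    fit_rows = split.indices("train") if split is not None else slice(None)
    state = fit_normalizer(ds.X[fit_rows], method)
    return replace(ds, X=state.transform(ds.X)), state


def smote(X: np.ndarray, y: np.ndarray, target_total: int,
          k_neighbors: int = 5, seed: int = 0,
          ) -> Tuple[np.ndarray, np.ndarray]:
    """From-scratch SMOTE: bring every class up to ``target_total / 2``.

    Each synthetic point is ``x + u * (x_nbr - x)`` for a uniformly chosen
    seed row ``x`` of the undersized class, one of its ``k`` nearest
    same-class neighbours ``x_nbr`` (Euclidean), and ``u ~ Uniform(0, 1)``.
    Original rows are retained; synthetic rows are appended (class 0 block
    first, then class 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if target_total < n:
        raise ValueError(f"target_total {target_total} < current n {n}")
    if target_total % 2 != 0:
        raise ValueError("target_total must be even (per-class halves)")
    per_class = target_total // 2
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        deficit = per_class - len(idx)
        if deficit < 0:
            raise ValueError(
                f"class {cls} already exceeds target_total/2 "
                f"({len(idx)} > {per_class})")
        if deficit == 0:
            continue
        if len(idx) < 2:
            raise ValueError(
                f"class {cls} needs >= 2 members for interpolation")
        k = min(k_neighbors, len(idx) - 1)
        Xc = X[idx]
        dist = cdist(Xc, Xc)
        np.fill_diagonal(dist, np.inf)
        nbrs = np.argsort(dist, axis=1, kind="stable")[:, :k]
        seeds = rng.integers(0, len(idx), size=deficit)
        picks = rng.integers(0, k, size=deficit)
        u = rng.random(deficit)
        base = Xc[seeds]
        other = Xc[nbrs[seeds, picks]]
        new_X.append(base + u[:, None] * (other - base))
        new_y.append(np.full(deficit, cls, dtype=int))
    return np.vstack(new_X), np.concatenate(new_y)


def smote_dataset(ds: Dataset, target_total: int, k_neighbors: int = 5,
                  seed: int = 0) -> Dataset:
    """Dataset-level SMOTE wrapper (requires no missing cells)."""
    if ds.mask.any():
        raise ValueError("SMOTE requires a dataset with no missing cells")
    Xo, yo = smote(ds.X, ds.y, target_total, k_neighbors, seed)
    return Dataset(X=Xo, mask=np.zeros_like(Xo, dtype=bool), y=yo,
                   schema=ds.schema, provenance=ds.provenance)


def split(y: np.ndarray, fractions: Tuple[float, float, float] = (0.7, 0.15, 0.15),
          seed: int = 0) -> SplitAssignment:
    """Stratified, seeded train/val/test partition.

    Within each class the shuffled indices are cut at
    ``round(cum_fraction * n_class)`` boundaries, so role sizes are exact up
    to rounding and each role's class ratio is within one sample of the
    global ratio.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 10:
        raise ValueError("split requires n >= 10")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    roles = np.empty(n, dtype=object)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        nc = len(idx)
        b1 = int(np.floor(fractions[0] * nc + 0.5))
        b2 = int(np.floor((fractions[0] + fractions[1]) * nc + 0.5))
        roles[idx[:b1]] = "train"
        roles[idx[b1:b2]] = "val"
        roles[idx[b2:]] = "test"
    assignment = SplitAssignment(roles=roles)
    for role in ROLES:
        present = set(y[assignment.mask(role)])
        missing = set(np.unique(y)) - present
        if missing:
            raise ValueError(
                f"class(es) {sorted(missing)} absent from role {role!r} at "
                f"the requested fractions")
    return assignment


def run_preprocess(ds: Dataset, config: PreprocessConfig,
                   ) -> Tuple[Dataset, SplitAssignment, NormalizerState]:
    """Run the full cleaning chain under ``config``.

    Default (paper-faithful) order: complete-case/impute -> winsorize ->
    normalize (whole-data statistics) -> SMOTE -> split. With
    ``leakage_safe=True``: ... -> split -> normalize (train statistics) ->
    SMOTE on the training role only (synthetic rows appended as 'train').
    """
    config.validate()
    if config.impute_strategy == "complete_case":
        ds = complete_cases(ds)
    else:
        ds = impute(ds, "median_mode")
    if config.outlier_rule == "iqr_winsorize":
        ds = winsorize_outliers(ds, config.outlier_k)

    if not config.leakage_safe:
        ds, state = normalize(ds, config.normalize)
        if config.smote_enabled:
            ds = smote_dataset(ds, config.smote_target_total,
                               config.smote_k_neighbors, config.smote_seed)
        assignment = split(ds.y, config.split_fractions, config.split_seed)
        return ds, assignment, state

    assignment = split(ds.y, config.split_fractions, config.split_seed)
    ds, state = normalize(ds, config.normalize, split=assignment)
    if config.smote_enabled:
        train_idx = assignment.indices("train")
        Xt, yt = ds.X[train_idx], ds.y[train_idx]
        # scale the train-only target by the train share of the total
        target = config.smote_target_total
        train_target = int(round(target * len(train_idx) / ds.n))
        train_target += train_target % 2
        train_target = max(train_target, len(train_idx) + len(train_idx) % 2)
        Xo, yo = smote(Xt, yt, train_target, config.smote_k_neighbors,
                       config.smote_seed)
        n_new = len(yo) - len(yt)
        if n_new > 0:
            X_all = np.vstack([ds.X, Xo[len(yt):]])
            y_all = np.concatenate([ds.y, yo[len(yt):]])
            ds = Dataset(X=X_all, mask=np.zeros_like(X_all, dtype=bool),
                         y=y_all, schema=ds.schema, provenance=ds.provenance)
            assignment = SplitAssignment(
                roles=np.concatenate([assignment.roles,
                                      np.full(n_new, "train", dtype=object)]))
    return ds, assignment, state
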