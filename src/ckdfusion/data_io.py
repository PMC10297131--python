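"""Reading, writing and simulation of CKD-style clinical feature tables.

Supports the UCI chronic-kidney-disease file in its original (dirty) ARFF
dialect and as a CSV export, a generic CSV path, and a seeded synthetic
generator whose class-conditional defaults emulate the feature spreads of
the real cohort (e.g. non-CKD hemoglobin concentrated in 12.5-17.5, CKD
hemoglobin dispersed over 5-17.5).

Conventions
-----------
* Missing cells are represented by ``nan`` in ``Dataset.X`` with a parallel
  boolean mask; '?' and empty cells in files denote missing.
* Binary categoricals are coded yes/present/abnormal -> 1,
  no/notpresent/normal -> 0; 'appet' good -> 1, poor -> 0.
* The class label is coded ckd -> 1 (positive), notckd -> 0.
* 'sg', 'al' and 'su' are ordinal and kept on their numeric scale.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

NUMERIC = "numeric"
BINARY = "categorical-binary"
ORDINAL = "categorical-ordinal"

#: canonical feature order of the UCI chronic-kidney-disease table
CKD_FEATURE_NAMES: Tuple[str, ...] = (
    "age", "bp", "sg", "al", "su", "rbc", "pc", "pcc", "ba", "bgr",
    "bu", "sc", "sod", "pot", "hemo", "pcv", "wc", "rc", "htn", "dm",
    "cad", "appet", "pe", "ane",
)

_CKD_KINDS: Dict[str, str] = {
    **{n: NUMERIC for n in ("age", "bp", "bgr", "bu", "sc", "sod", "pot",
                            "hemo", "pcv", "wc", "rc")},
    **{n: ORDINAL for n in ("sg", "al", "su")},
    **{n: BINARY for n in ("rbc", "pc", "pcc", "ba", "htn", "dm", "cad",
                           "appet", "pe", "ane")},
}

_CKD_LEVELS: Dict[str, Dict[str, int]] = {
    "rbc": {"normal": 0, "abnormal": 1},
    "pc": {"normal": 0, "abnormal": 1},
    "pcc": {"notpresent": 0, "present": 1},
    "ba": {"notpresent": 0, "present": 1},
    "htn": {"no": 0, "yes": 1},
    "dm": {"no": 0, "yes": 1},
    "cad": {"no": 0, "yes": 1},
    "appet": {"poor": 0, "good": 1},
    "pe": {"no": 0, "yes": 1},
    "ane": {"no": 0, "yes": 1},
}

#: header aliases seen across UCI distributions of the same table
_NAME_ALIASES = {"wbcc": "wc", "rbcc": "rc"}

CLASS_COLUMN = "class"
_CLASS_LEVELS = {"notckd": 0, "ckd": 1}
_MISSING_TOKENS = {"?", ""}


class SchemaError(ValueError):
    """A column name or declaration does not match the expected schema."""


class ParseError(ValueError):
    """A data cell could not be interpreted under the schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with per-feature kind tags and level codings.

    Parameters
    ----------
    names
        Ordered feature identifiers (the class column is not part of this).
    kinds
        Map from feature name to one of ``numeric``, ``categorical-binary``,
        ``categorical-ordinal``.
    levels
        For each binary categorical feature, the map from level string to
        its integer code.
    """

    names: Tuple[str, ...]
    kinds: Dict[str, str]
    levels: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise SchemaError("feature names must be unique")
        for name in self.names:
            if name not in self.kinds:
                raise SchemaError(f"no kind declared for feature {name!r}")
            if self.kinds[name] not in (NUMERIC, BINARY, ORDINAL):
                raise SchemaError(
                    f"unknown kind {self.kinds[name]!r} for feature {name!r}")
            if self.kinds[name] == BINARY:
                lv = self.levels.get(name)
                if not lv or len(lv) < 2:
                    raise SchemaError(
                        f"binary feature {name!r} needs >= 2 levels")
                if len(set(lv.values())) != len(lv):
                    raise SchemaError(
                        f"level codes for {name!r} must be distinct")

    @property
    def n_features(self) -> int:
        return len(self.names)

    def is_arithmetic(self, name: str) -> bool:
        """True for features on a numeric scale (numeric or ordinal)."""
        return self.kinds[name] in (NUMERIC, ORDINAL)

    def code_for(self, name: str, token: str) -> float:
        """Map a raw string cell to its numeric code."""
        if self.is_arithmetic(name):
            try:
                return float(token)
            except ValueError:
                raise ParseError(
                    f"unparseable numeric value {token!r} in column {name!r}"
                ) from None
        lv = self.levels[name]
        key = token.strip().lower()
        if key not in lv:
            raise ParseError(
                f"unknown level {token!r} for column {name!r}; "
                f"allowed: {sorted(lv)}")
        return float(lv[key])

    def string_for(self, name: str, value: float) -> str:
        """Inverse of :meth:`code_for` for serialization."""
        if self.is_arithmetic(name):
            if float(value).is_integer():
                return str(int(value))
            return repr(float(value))
        inv = {c: s for s, c in self.levels[name].items()}
        code = int(round(value))
        if code not in inv:
            raise ParseError(
                f"code {value!r} has no level string for column {name!r}")
        return inv[code]


def default_schema() -> FeatureSchema:
    """The canonical 24-feature UCI chronic-kidney-disease schema."""
    return FeatureSchema(names=CKD_FEATURE_NAMES, kinds=dict(_CKD_KINDS),
                         levels={k: dict(v) for k, v in _CKD_LEVELS.items()})


def gaussian_schema(n_features: int) -> FeatureSchema:
    """An all-numeric schema ``f00..fNN`` for abstract synthetic data."""
    names = tuple(f"f{i:02d}" for i in range(n_features))
    return FeatureSchema(names=names, kinds={n: NUMERIC for n in names})


@dataclass
class Dataset:
    """A feature matrix with missingness mask, binary labels and schema.

    ``X`` holds ``nan`` wherever ``mask`` is true; masked cells must never
    enter arithmetic. ``y`` is coded 1 = ckd, 0 = notckd.
    """

    X: np.ndarray
    mask: np.ndarray
    y: np.ndarray
    schema: FeatureSchema
    provenance: str = "csv"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape != self.mask.shape:
            raise ValueError(
                f"X shape {self.X.shape} != mask shape {self.mask.shape}")
        if self.X.shape[0] < 1:
            raise ValueError("dataset must contain at least one row")
        if self.X.shape[1] != self.schema.n_features:
            raise SchemaError(
                f"X has {self.X.shape[1]} columns, schema declares "
                f"{self.schema.n_features}")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be coded in {0, 1}")
        # keep the sentinel consistent with the mask
        self.X = self.X.copy()
        self.X[self.mask] = np.nan

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def equals(self, other: "Dataset") -> bool:
        """Field-for-field equality (nan-aware on masked cells)."""
        if self.X.shape != other.X.shape:
            return False
        same_obs = np.array_equal(self.X[~self.mask],
                                  other.X[~other.mask]) if np.array_equal(
            self.mask, other.mask) else False
        return (same_obs
                and np.array_equal(self.y, other.y)
                and self.schema.names == other.schema.names)

    def take(self, rows: np.ndarray) -> "Dataset":
        """Row subset, order preserved."""
        return replace(self, X=self.X[rows], mask=self.mask[rows],
                       y=self.y[rows])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _clean_token(tok: str) -> str:
    return tok.strip().strip("\t ").strip()


def _parse_rows(rows: Sequence[Sequence[str]], header: Sequence[str],
                schema: FeatureSchema, provenance: str) -> Dataset:
    names = [h.strip().lower() for h in header]
    names = [_NAME_ALIASES.get(n, n) for n in names]
    expected = [n.lower() for n in schema.names] + [CLASS_COLUMN]
    for got in names:
        if got not in expected:
            raise SchemaError(f"unknown column name {got!r}")
    if names != expected:
        raise SchemaError(
            "column order must match the schema followed by 'class'")
    d = schema.n_features
    X = np.empty((len(rows), d))
    mask = np.zeros((len(rows), d), dtype=bool)
    y = np.empty(len(rows), dtype=int)
    for i, row in enumerate(rows):
        if len(row) != d + 1:
            raise ParseError(
                f"row {i + 1}: expected {d + 1} fields, got {len(row)}")
        for j, name in enumerate(schema.names):
            tok = _clean_token(row[j])
            if tok in _MISSING_TOKENS:
                mask[i, j] = True
                X[i, j] = np.nan
            else:
                try:
                    X[i, j] = schema.code_for(name, tok)
                except ParseError as exc:
                    raise ParseError(f"row {i + 1}: {exc}") from None
        cls = _clean_token(row[d]).lower()
        if cls not in _CLASS_LEVELS:
            raise ParseError(
                f"row {i + 1}: unknown class label {row[d]!r}; "
                f"allowed: {sorted(_CLASS_LEVELS)}")
        y[i] = _CLASS_LEVELS[cls]
    return Dataset(X=X, mask=mask, y=y, schema=schema, provenance=provenance)


def _read_arff(text: str, schema: FeatureSchema) -> Dataset:
    # Lenient reader: the distributed UCI file carries stray tabs, blank
    # tokens and occasional trailing commas, which strict ARFF parsers reject.
    declared: List[str] = []
    data_rows: List[List[str]] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            rest = line.split(None, 1)[1].strip()
            name = rest.split(None, 1)[0].strip("'\"").lower()
            declared.append(name)
            continue
        if low.startswith("@data"):
            in_data = True
            continue
        if in_data:
            toks = [_clean_token(t) for t in line.split(",")]
            # drop a single empty trailing field from a stray comma
            if len(toks) == len(declared) + 1 and toks[-1] == "":
                toks = toks[:-1]
            data_rows.append(toks)
    if not declared:
        raise SchemaError("no @attribute declarations found")
    return _parse_rows(data_rows, declared, schema, provenance="uci")


def read_ckd_file(path: str, dialect: Optional[str] = None,
                  schema: Optional[FeatureSchema] = None) -> Dataset:
    """Read a CKD table in the UCI ARFF dialect or as CSV.

    Parameters
    ----------
    path
        File to read. When ``dialect`` is omitted it is inferred from the
        extension ('.arff' vs anything else).
    dialect
        'arff' or 'csv'.
    schema
        Feature schema; defaults to the canonical 24-feature UCI schema.

    Returns
    -------
    Dataset
        With '?', empty and tab-polluted cells masked as missing, binary
        categoricals coded, and the class column separated into ``y``.
    """
    schema = schema or default_schema()
    if dialect is None:
        dialect = "arff" if str(path).lower().endswith(".arff") else "csv"
    if dialect not in ("arff", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if dialect == "arff":
        return _read_arff(text, schema)
    reader = csv.reader(io.StringIO(text))
    rows = [r for r in reader if any(_clean_token(t) for t in r)]
    if not rows:
        raise ParseError("empty file")
    header, body = rows[0], rows[1:]
    return _parse_rows(body, header, schema, provenance="csv")


def read_table(path: str) -> Dataset:
    """Generic CSV entry point.

    If the header matches the canonical CKD schema the strict reader is
    used; otherwise a schema is inferred from the header: columns whose
    observed cells all parse as numbers become numeric, anything else
    becomes a binary categorical with levels coded in sorted order.
    """
    with open(path, "r", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if any(_clean_token(t) for t in r)]
    if not rows:
        raise ParseError("empty file")
    header = [_clean_token(h).lower() for h in rows[0]]
    if header == [n.lower() for n in CKD_FEATURE_NAMES] + [CLASS_COLUMN]:
        return read_ckd_file(path, dialect="csv")
    if header[-1] != CLASS_COLUMN:
        raise SchemaError("last column must be named 'class'")
    names = tuple(header[:-1])
    kinds: Dict[str, str] = {}
    levels: Dict[str, Dict[str, int]] = {}
    for j, name in enumerate(names):
        observed = [_clean_token(r[j]) for r in rows[1:]
                    if _clean_token(r[j]) not in _MISSING_TOKENS]
        numeric = True
        for tok in observed:
            try:
                float(tok)
            except ValueError:
                numeric = False
                break
        if numeric:
            kinds[name] = NUMERIC
        else:
            kinds[name] = BINARY
            uniq = sorted({tok.lower() for tok in observed})
            if len(uniq) < 2:
                uniq = uniq + ["__other__"]
            levels[name] = {s: c for c, s in enumerate(uniq)}
    schema = FeatureSchema(names=names, kinds=kinds, levels=levels)
    return _parse_rows(rows[1:], header, schema, provenance="csv")


def write_csv(ds: Dataset, path: str) -> None:
    """Serialize a dataset to CSV: '?' for missing, level strings for
    binary categoricals, class column last ('ckd'/'notckd')."""
    inv_class = {c: s for s, c in _CLASS_LEVELS.items()}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(ds.schema.names) + [CLASS_COLUMN])
        for i in range(ds.n):
            row = []
            for j, name in enumerate(ds.schema.names):
                if ds.mask[i, j]:
                    row.append("?")
                else:
                    row.append(ds.schema.string_for(name, ds.X[i, j]))
            row.append(inv_class[int(ds.y[i])])
            writer.writerow(row)


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncNormal:
    """Truncated normal on [low, high]."""
    mean: float
    sd: float
    low: float
    high: float

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=size, random_state=rng)


# class-conditional numeric defaults (index 0 = notckd, 1 = ckd) calibrated
# to the reported cohort spreads: CKD age concentrated 50-70 vs non-CKD
# 20-80, CKD blood pressure spanning 60-100, non-CKD hemoglobin 12.5-17.5
# vs CKD dispersed 5-17.5, non-CKD red cells 4-7 vs CKD 3-6, etc.
CKD_NUMERIC_DEFAULTS: Dict[str, Tuple[TruncNormal, TruncNormal]] = {
    "age": (TruncNormal(50, 15, 20, 80), TruncNormal(60, 6, 50, 70)),
    "bp": (TruncNormal(72, 8, 60, 85), TruncNormal(80, 12, 60, 100)),
    "sg": (TruncNormal(1.020, 0.004, 1.005, 1.025),
           TruncNormal(1.012, 0.005, 1.005, 1.025)),
    "al": (TruncNormal(0.3, 0.35, 0, 1), TruncNormal(2.5, 1.3, 0, 5)),
    "su": (TruncNormal(0.1, 0.3, 0, 5), TruncNormal(1.0, 1.2, 0, 5)),
    "bgr": (TruncNormal(100, 25, 50, 150), TruncNormal(160, 60, 50, 400)),
    "bu": (TruncNormal(35, 10, 10, 60), TruncNormal(80, 40, 10, 250)),
    "sc": (TruncNormal(0.9, 0.3, 0.4, 1.4), TruncNormal(3.0, 2.0, 0.4, 15)),
    "sod": (TruncNormal(141, 3, 130, 150), TruncNormal(138, 5, 110, 150)),
    "pot": (TruncNormal(4.4, 0.5, 3.0, 6.0), TruncNormal(4.6, 0.8, 2.5, 7.5)),
    "hemo": (TruncNormal(15.0, 1.2, 12.5, 17.5), TruncNormal(11.0, 2.8, 5.0, 17.5)),
    "pcv": (TruncNormal(48, 4, 40, 60), TruncNormal(35, 7, 15, 55)),
    "wc": (TruncNormal(7800, 1800, 3000, 15000),
           TruncNormal(8500, 2800, 2000, 20000)),
    "rc": (TruncNormal(5.4, 0.7, 4.0, 7.0), TruncNormal(4.3, 0.7, 3.0, 6.0)),
}

# class-conditional Bernoulli rates for the binary features (P[code 1])
CKD_BINARY_DEFAULTS: Dict[str, Tuple[float, float]] = {
    "rbc": (0.02, 0.35), "pc": (0.03, 0.40), "pcc": (0.01, 0.25),
    "ba": (0.01, 0.15), "htn": (0.05, 0.60), "dm": (0.03, 0.50),
    "cad": (0.02, 0.20), "appet": (0.98, 0.60), "pe": (0.02, 0.30),
    "ane": (0.02, 0.35),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration for the synthetic cohort generator.

    ``mode='clinical'`` emulates the 24-feature CKD table with the
    class-conditional defaults above (overridable per feature).
    ``mode='gaussian'`` draws ``n_features`` standard-normal features for
    class 0 and shifts every feature by ``class_shift`` for class 1 — a
    knob for separability studies (``class_shift=3`` is near-separable).

    ``mode='dual'`` plants two kinds of signal at once: the first two
    features carry an XOR-style cluster structure (class 1 occupies the
    ++/-- quadrants, class 0 the +-/-+ quadrants) that only neighbourhood
    structure can exploit, and the third feature carries a plain
    ``class_shift`` mean offset that a linear model can use.
    """

    n_per_class: int
    missing_rate: float = 0.0
    seed: int = 0
    mode: str = "clinical"
    n_features: int = 24
    class_shift: float = 1.0
    numeric_overrides: Dict[str, Tuple[TruncNormal, TruncNormal]] = field(
        default_factory=dict)
    binary_overrides: Dict[str, Tuple[float, float]] = field(
        default_factory=dict)

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.mode not in ("clinical", "gaussian", "dual"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "gaussian" and self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.mode == "dual" and self.n_features < 3:
            raise ValueError("dual mode needs n_features >= 3")
        for name, pair in {**CKD_NUMERIC_DEFAULTS,
                           **self.numeric_overrides}.items():
            for tn in pair:
                if tn.low > tn.high:
                    raise ValueError(f"range low > high for {name!r}")
                if tn.sd <= 0:
                    raise ValueError(f"sd must be positive for {name!r}")
        for name, rates in {**CKD_BINARY_DEFAULTS,
                            **self.binary_overrides}.items():
            if not all(0.0 <= r <= 1.0 for r in rates):
                raise ValueError(f"Bernoulli rate out of [0,1] for {name!r}")


def generate_synthetic(spec: SyntheticSpec) -> Dataset:
    """Draw a balanced two-class synthetic dataset per ``spec``.

    Rows are ordered class 0 first, then class 1; each block has exactly
    ``n_per_class`` rows. Equal seeds give bit-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    npc = spec.n_per_class
    n = 2 * npc
    if spec.mode == "gaussian":
        schema = gaussian_schema(spec.n_features)
        d = spec.n_features
        X = rng.standard_normal((n, d))
        X[npc:] += spec.class_shift
    elif spec.mode == "dual":
        schema = gaussian_schema(spec.n_features)
        d = spec.n_features
        X = rng.standard_normal((n, d))
        # XOR cluster structure: sign pattern (s, s) for class 1,
        # (s, -s) for class 0, cluster half-distance 2, noise sd 0.7
        s = rng.choice([-1.0, 1.0], size=n)
        X[:, 0] = 2.0 * s + 0.7 * rng.standard_normal(n)
        sign2 = np.concatenate([-s[:npc], s[npc:]])
        X[:, 1] = 2.0 * sign2 + 0.7 * rng.standard_normal(n)
        X[npc:, 2] += spec.class_shift
    else:
        schema = default_schema()
        numeric = {**CKD_NUMERIC_DEFAULTS, **spec.numeric_overrides}
        binary = {**CKD_BINARY_DEFAULTS, **spec.binary_overrides}
        d = schema.n_features
        X = np.empty((n, d))
        for j, name in enumerate(schema.names):
            if schema.kinds[name] == BINARY:
                r0, r1 = binary[name]
                X[:npc, j] = (rng.random(npc) < r0).astype(float)
                X[npc:, j] = (rng.random(npc) < r1).astype(float)
            else:
                tn0, tn1 = numeric[name]
                X[:npc, j] = tn0.sample(npc, rng)
                X[npc:, j] = tn1.sample(npc, rng)
    y = np.concatenate([np.zeros(npc, dtype=int), np.ones(npc, dtype=int)])
    mask = rng.random((n, d)) < spec.missing_rate
    X = X.astype(float)
    X[mask] = np.nan
    return Dataset(X=X, mask=mask, y=y, schema=schema,
                   provenance="synthetic")
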