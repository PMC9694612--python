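"""Trial-table I/O, design-matrix encoding, response scaling and data splits.

The three categorical factors are encoded into a 10-column design matrix:
one 0/1 year code, three locality indicators and six fertilization indicators
(in declared design order).  Responses are min–max scaled to [0, 1] on the
training partition only; indicator inputs are already bounded and are left as
raw codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .design import DesignSpec, DesignError, FACTOR_COLUMNS, RESPONSE_NAMES

__all__ = [
    "DesignMatrix",
    "SplitIndices",
    "ResponseScaler",
    "encode_design",
    "decode_design",
    "normalize",
    "split_indices",
    "read_trial_csv",
    "write_trial_csv",
    "validate_trial_table",
]

#: Float format used for CSV round-tripping (17 significant digits preserves
#: IEEE doubles exactly).
_FLOAT_FMT = "%.17g"


@dataclass
class DesignMatrix:
    """Encoded inputs: N × (1 + |localities| + |fertilizations|)."""

    X: np.ndarray
    column_names: list[str]
    row_index: np.ndarray


@dataclass
class SplitIndices:
    """Disjoint train / validation / test row indices covering all rows."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)

    def to_dict(self) -> dict:
        return {
            "train": [int(i) for i in self.train],
            "validation": [int(i) for i in self.validation],
            "test": [int(i) for i in self.test],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitIndices":
        return cls(
            train=np.asarray(d["train"], dtype=int),
            validation=np.asarray(d["validation"], dtype=int),
            test=np.asarray(d["test"], dtype=int),
        )


def validate_trial_table(table: pd.DataFrame) -> None:
    """Check the fixed 4-factor + 30-response schema; raise naming offenders."""
    expected = list(FACTOR_COLUMNS) + list(RESPONSE_NAMES)
    missing = [c for c in expected if c not in table.columns]
    extra = [c for c in table.columns if c not in expected]
    if missing or extra:
        raise DesignError(
            f"trial table schema mismatch: missing columns {missing}, "
            f"unexpected columns {extra}"
        )


def encode_design(table: pd.DataFrame, design: DesignSpec) -> DesignMatrix:
    """One-hot encode factor levels into the network's input matrix.

    Column order is deterministic: year code (0 for the first year), locality
    indicators in design order, fertilization indicators in design order.

    Raises
    ------
    DesignError
        If a record carries a level absent from ``design``, naming both.
    """
    n = len(table)
    X = np.zeros((n, design.n_inputs))
    for pos, (idx, row) in enumerate(table.iterrows()):
        year, loc, fert = row["year"], row["locality"], row["fertilization"]
        if year not in design.years:
            raise DesignError(f"record {idx}: unseen year level {year!r}")
        if loc not in design.localities:
            raise DesignError(f"record {idx}: unseen locality level {loc!r}")
        if fert not in design.fertilizations:
            raise DesignError(f"record {idx}: unseen fertilization level {fert!r}")
        X[pos, 0] = design.year_code(year)
        X[pos, 1 + design.localities.index(loc)] = 1.0
        X[pos, 1 + len(design.localities) + design.fertilizations.index(fert)] = 1.0
    return DesignMatrix(
        X=X, column_names=design.input_names(), row_index=table.index.to_numpy()
    )


def encode_levels(
    year: str, locality: str, fertilization: str, design: DesignSpec
) -> np.ndarray:
    """Encode a single factor combination into one input row."""
    frame = pd.DataFrame(
        [{"year": year, "locality": locality, "fertilization": fertilization}]
    )
    return encode_design(frame, design).X[0]


def decode_design(dm: DesignMatrix, design: DesignSpec) -> pd.DataFrame:
    """Invert :func:`encode_design`, recovering factor levels per row."""
    nl = len(design.localities)
    rows = []
    for x in dm.X:
        year = design.years[int(round(x[0]))]
        loc = design.localities[int(np.argmax(x[1 : 1 + nl]))]
        fert = design.fertilizations[int(np.argmax(x[1 + nl :]))]
        rows.append({"year": year, "locality": loc, "fertilization": fert})
    return pd.DataFrame(rows, index=dm.row_index)


class ResponseScaler(BaseEstimator, TransformerMixin):
    """Per-column min–max scaler fitted on the training partition only.

    Maps the fitted minimum to ``feature_range[0]`` and maximum to
    ``feature_range[1]``, affinely in between.  Out-of-range values (e.g.
    test rows beyond the training extremes) are *not* clipped, preserving
    invertibility for error reporting in original units.  Degenerate columns
    (max = min) map to the interval midpoint and are flagged.

    Attributes
    ----------
    data_min_, data_max_ : ndarray
        Per-column extremes observed at fit time.
    degenerate_ : ndarray of bool
        Columns with zero range.
    """

    def __init__(self, feature_range: tuple[float, float] = (0.0, 1.0)):
        self.feature_range = feature_range

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.degenerate_ = self.data_max_ == self.data_min_
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "data_min_"):
            raise NotFittedError(
                "ResponseScaler must be fitted before (inverse) transforming"
            )

    def transform(self, X):
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        lo, hi = self.feature_range
        span = np.where(self.degenerate_, 1.0, self.data_max_ - self.data_min_)
        out = lo + (X - self.data_min_) / span * (hi - lo)
        out[:, self.degenerate_] = (lo + hi) / 2.0
        return out[:, 0] if squeeze else out

    def inverse_transform(self, X):
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        lo, hi = self.feature_range
        span = np.where(self.degenerate_, 1.0, self.data_max_ - self.data_min_)
        out = self.data_min_ + (X - lo) / (hi - lo) * span
        out[:, self.degenerate_] = self.data_min_[self.degenerate_]
        return out[:, 0] if squeeze else out

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "feature_range": list(self.feature_range),
            "data_min": self.data_min_.tolist(),
            "data_max": self.data_max_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseScaler":
        scaler = cls(feature_range=tuple(d["feature_range"]))
        scaler.data_min_ = np.asarray(d["data_min"], dtype=float)
        scaler.data_max_ = np.asarray(d["data_max"], dtype=float)
        scaler.degenerate_ = scaler.data_max_ == scaler.data_min_
        return scaler


def normalize(values: np.ndarray, scaler: ResponseScaler, direction: str) -> np.ndarray:
    """Functional wrapper over :class:`ResponseScaler`.

    ``direction`` is ``"forward"`` (original → scaled) or ``"inverse"``.
    """
    if direction == "forward":
        return scaler.transform(values)
    if direction == "inverse":
        return scaler.inverse_transform(values)
    raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")


def split_indices(
    n: int, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2), seed: int = 0
) -> SplitIndices:
    """Uniformly random disjoint train/validation/test partition of ``range(n)``.

    Partition sizes are the fractions rounded half-up, with any remainder
    assigned to training (36 rows at 60/20/20 give 22/7/7).  The split is
    unstratified; rows are permuted with ``seed``.
    """
    if n < 5:
        raise ValueError(f"need at least 5 rows to split, got {n}")
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    k_val = int(np.floor(n * fractions[1] + 0.5))
    k_test = int(np.floor(n * fractions[2] + 0.5))
    k_train = n - k_val - k_test
    if k_train <= 0:
        raise ValueError("training partition would be empty")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(
        train=np.sort(perm[:k_train]),
        validation=np.sort(perm[k_train : k_train + k_val]),
        test=np.sort(perm[k_train + k_val :]),
    )


def write_trial_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as UTF-8 CSV ('.' decimals, full float precision)."""
    validate_trial_table(table)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    """Read a trial table CSV and validate its schema."""
    table = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    validate_trial_table(table)
    return table


def write_config(data: dict, path: str | Path) -> None:
    """Serialize a nested configuration mapping to YAML."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, allow_unicode=True, sort_keys=False)


def read_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
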