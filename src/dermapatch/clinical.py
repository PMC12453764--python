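"""Clinical-metadata encoding: z-score standardization of continuous
variables and one-hot encoding of categoricals, with persisted fitted state.

Standardization uses the population convention sigma = sqrt(mean((x-mu)^2));
statistics are computed on the training table only and reused, leakage-free,
on validation/test records. One-hot vocabularies are sorted
lexicographically, and the output layout is deterministic: the continuous
block (columns alphabetical), then one one-hot block per categorical column
(columns alphabetical, categories in vocabulary order). Missing continuous
values are imputed with the training median; missing categoricals become an
explicit "missing" category.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_CONTINUOUS = ("age", "symptom_duration")
DEFAULT_CATEGORICAL = ("gender", "history_flag", "skin_type")

MISSING = "missing"


@dataclasses.dataclass
class ClinicalEncoder:
    """Fitted scaler/one-hot state (the persisted ScalerParams)."""

    continuous: dict        # column -> {"mean", "std", "median"}
    categorical: dict       # column -> ordered vocabulary list
    dropped: list           # constant continuous columns removed at fit time

    @property
    def feature_names(self) -> list[str]:
        names = [c for c in sorted(self.continuous)]
        for col in sorted(self.categorical):
            names.extend(f"{col}={v}" for v in self.categorical[col])
        return names

    @property
    def dim(self) -> int:
        return len(self.continuous) + sum(len(v) for v in self.categorical.values())

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "ClinicalEncoder":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.DataFrame(list(table))


def fit_encoder(
    table,
    continuous: tuple[str, ...] = DEFAULT_CONTINUOUS,
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL,
) -> ClinicalEncoder:
    """Fit scaler state on a training table (DataFrame or list of records).

    Continuous columns with fewer than two distinct values carry no
    information under z-scoring (sigma = 0) and are dropped with a warning.
    """
    df = _as_frame(table)
    if len(df) == 0:
        raise ValueError("cannot fit the clinical encoder on an empty table")
    if len(df) < 2:
        raise ValueError("need at least 2 rows to fit the clinical encoder")

    cont, dropped = {}, []
    for col in continuous:
        x = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=np.float64)
        finite = x[np.isfinite(x)]
        if finite.size == 0 or np.unique(finite).size < 2:
            warnings.warn(f"dropping constant continuous column {col!r} (sigma = 0)")
            dropped.append(col)
            continue
        mu = float(finite.mean())
        sigma = float(np.sqrt(np.mean((finite - mu) ** 2)))  # population sigma
        cont[col] = {"mean": mu, "std": sigma, "median": float(np.median(finite))}

    cat = {}
    for col in categorical:
        vals = df[col].astype(object)
        vocab = sorted({MISSING if pd.isna(v) else str(v) for v in vals})
        cat[col] = vocab
    return ClinicalEncoder(continuous=cont, categorical=cat, dropped=dropped)


def transform(record, encoder: ClinicalEncoder) -> np.ndarray:
    """Encode one record (mapping / Series) or a table into C_f vectors.

    Continuous values map to (x - mu)/sigma; categoricals to one-hot in
    vocabulary order. A category absent from the fitted vocabulary raises,
    naming the column and offending value.
    """
    if isinstance(record, pd.DataFrame):
        return np.stack([transform(row, encoder) for _, row in record.iterrows()])

    parts = []
    for col in sorted(encoder.continuous):
        stats = encoder.continuous[col]
        raw = record[col]
        x = float(stats["median"]) if raw is None or (
            isinstance(raw, float) and np.isnan(raw)) else float(raw)
        parts.append((x - stats["mean"]) / stats["std"])
    for col in sorted(encoder.categorical):
        vocab = encoder.categorical[col]
        raw = record[col]
        value = MISSING if raw is None or (isinstance(raw, float) and np.isnan(raw)) \
            else str(raw)
        if value not in vocab:
            raise ValueError(
                f"unseen category {value!r} in column {col!r}; "
                f"fitted vocabulary is {vocab}"
            )
        onehot = np.zeros(len(vocab))
        onehot[vocab.index(value)] = 1.0
        parts.append(onehot)
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=np.float64)) for p in parts])


def inverse_continuous(z: float, column: str, encoder: ClinicalEncoder) -> float:
    """Recover x = z * sigma + mu for a fitted continuous column."""
    stats = encoder.continuous[column]
    return z * stats["std"] + stats["mean"]
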