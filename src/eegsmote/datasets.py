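"""Labeled feature matrices for two-class (seizure / nonseizure) learning.

The convention throughout the package: label 1 is the positive class
(ictal / seizure / minority), label 0 the negative class (nonictal /
nonseizure / majority).  Resamplers consume and produce
:class:`LabeledDataset`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "SyntheticProvenance"]


@dataclass(frozen=True)
class SyntheticProvenance:
    """Record of how one synthetic row was generated.

    Attributes
    ----------
    parent : int
        Row index (into the *input* dataset) of the interpolation parent.
    partner : int
        Row index of the interpolation partner.
    delta : float
        Interpolation coefficient in [0, 1]; the synthetic row is
        ``X[parent] + delta * (X[partner] - X[parent])``.
    """

    parent: int
    partner: int
    delta: float

    def to_dict(self) -> dict:
        return {"parent": int(self.parent), "partner": int(self.partner),
                "delta": float(self.delta)}


@dataclass
class LabeledDataset:
    """A feature matrix with binary labels (1 = seizure/minority)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains NaN or Inf entries")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def minority_indices(self) -> np.ndarray:
        return np.flatnonzero(self.y == 1)

    @property
    def majority_indices(self) -> np.ndarray:
        return np.flatnonzero(self.y == 0)

    @property
    def imbalance_ratio(self) -> float:
        """Minority / majority count ratio (inf when no majority rows)."""
        n_maj = len(self.majority_indices)
        if n_maj == 0:
            return float("inf")
        return len(self.minority_indices) / n_maj

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=int)
        return LabeledDataset(self.X[idx], self.y[idx])

    # -- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {f"feature_{j}": self.X[:, j] for j in range(self.n_features)}
        cols["label"] = self.y
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "LabeledDataset":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path, sep=sep)
        if "label" not in df.columns:
            raise ValueError("expected a 'label' column")
        feat_cols = [c for c in df.columns if c != "label"]
        return cls(df[feat_cols].to_numpy(float), df["label"].to_numpy(int))

    def to_npz(self, path: str | Path) -> None:
        np.savez_compressed(path, X=self.X, y=self.y)

    @classmethod
    def from_npz(cls, path: str | Path) -> "LabeledDataset":
        with np.load(path) as f:
            return cls(f["X"], f["y"])


def write_provenance_jsonl(records: list[SyntheticProvenance],
                           path: str | Path) -> None:
    """One JSON object per synthetic row, in synthesis order."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def read_provenance_jsonl(path: str | Path) -> list[SyntheticProvenance]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(SyntheticProvenance(d["parent"], d["partner"], d["delta"]))
    return out
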