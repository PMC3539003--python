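"""Labelled phenotype tables: the tabular currency of the pipeline.

A :class:`PhenotypeTable` wraps a pandas DataFrame with one row per
individual bee and the fixed column set ``(id, strain, rearing,
weight_mg, ovariole_count)``.  Construction validates the schema; file
round-tripping with row-level error reporting lives in :mod:`beecaste.cli_io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "PhenotypeTable"]

REQUIRED_COLUMNS = ("id", "strain", "rearing", "weight_mg", "ovariole_count")


@dataclass(frozen=True)
class PhenotypeTable:
    """Collection of individual (body weight, ovariole count) phenotypes."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing required column(s): {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        w = pd.to_numeric(df["weight_mg"], errors="coerce")
        y = pd.to_numeric(df["ovariole_count"], errors="coerce")
        if w.isna().any():
            row = int(w.index[w.isna()][0])
            raise ValueError(f"non-numeric weight_mg in row {row}")
        if y.isna().any():
            row = int(y.index[y.isna()][0])
            raise ValueError(f"non-numeric ovariole_count in row {row}")
        if (w <= 0).any():
            row = int(w.index[w <= 0][0])
            raise ValueError(f"weight_mg must be > 0; offending row {row}: {w[row]!r}")
        if (y < 0).any():
            row = int(y.index[y < 0][0])
            raise ValueError(f"ovariole_count must be >= 0; offending row {row}: {y[row]!r}")
        df = df.assign(weight_mg=w.astype(float), ovariole_count=y.astype(float))
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def weights(self) -> np.ndarray:
        return self.data["weight_mg"].to_numpy()

    @property
    def ovarioles(self) -> np.ndarray:
        return self.data["ovariole_count"].to_numpy()

    def subset(self, *, strain: str | None = None, rearing: str | None = None) -> "PhenotypeTable":
        df = self.data
        if strain is not None:
            df = df[df["strain"] == strain]
        if rearing is not None:
            df = df[df["rearing"] == rearing]
        return PhenotypeTable(df.reset_index(drop=True))

    @staticmethod
    def concat(tables: list["PhenotypeTable"]) -> "PhenotypeTable":
        return PhenotypeTable(pd.concat([t.data for t in tables], ignore_index=True))

    def equals(self, other: "PhenotypeTable") -> bool:
        return self.data.equals(other.data)
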