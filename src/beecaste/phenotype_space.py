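"""Morphospace construction: model phenotype sets and cloud-structure statistics.

The developmental map traces out a one-parameter curve in (body weight,
ovariole count) space when the three diet coordinates vary in parallel —
the model's phenotype set.  This module builds such curves, applies the
log10 view used for queen-plus-worker comparisons, and quantifies how
bimodal a phenotype cloud is (the caste-gap statistic), which is how the
discrete-nurse-regime versus larval-switch contrast is made quantitative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .model_core import ModelParams, Phenotype, develop_arrays
from .tables import PhenotypeTable

__all__ = ["PhenotypeCurve", "phenotype_set", "log_transform", "caste_gap_statistic"]


@dataclass(frozen=True)
class PhenotypeCurve:
    """Model phenotype set along a diet coordinate grid."""

    t_grid: np.ndarray
    weight_mg: np.ndarray
    ovariole_count: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t_grid, dtype=float)
        x = np.asarray(self.weight_mg, dtype=float)
        y = np.asarray(self.ovariole_count, dtype=float)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t_grid, weight_mg and ovariole_count must have equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("t_grid must be strictly increasing")
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "weight_mg", x)
        object.__setattr__(self, "ovariole_count", y)

    @property
    def points(self) -> list[Phenotype]:
        return [Phenotype(float(x), float(y)) for x, y in zip(self.weight_mg, self.ovariole_count)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t_grid, "weight_mg": self.weight_mg, "ovariole_count": self.ovariole_count}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def phenotype_set(
    params: ModelParams,
    t_lo: float = 0.1,
    t_hi: float = 0.9,
    n_points: int = 81,
    q2_offset: float = 0.0,
) -> PhenotypeCurve:
    """Phenotype curve for diets varying in parallel, q1 = q2 = q3 = t.

    ``q2_offset`` shifts the L4 coordinate (clipped to [0, 1]) relative to
    the parallel path, the device used to express strain differences in
    the nurse-supplied L4 diet.
    """
    if not (0 <= t_lo < t_hi <= 1):
        raise ValueError(f"need 0 <= t_lo < t_hi <= 1, got ({t_lo!r}, {t_hi!r})")
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points!r}")
    t = np.linspace(t_lo, t_hi, n_points)
    q2 = np.clip(t + q2_offset, 0.0, 1.0)
    x, y = develop_arrays(t, q2, t, params)
    return PhenotypeCurve(t_grid=t, weight_mg=x, ovariole_count=y)


def log_transform(obj):
    """Log10 view of a curve or table; returns ``(transformed, n_excluded)``.

    Rows with nonpositive ovariole counts (possible for simulated workers
    with y = 0) cannot be log-transformed; they are excluded and counted,
    never silently dropped.  Nonpositive weights raise, since weights are
    positive by construction.
    """
    if isinstance(obj, PhenotypeCurve):
        if np.any(obj.weight_mg <= 0) or np.any(obj.ovariole_count <= 0):
            raise ValueError("curve has nonpositive coordinates; cannot log-transform")
        return (
            PhenotypeCurve(obj.t_grid, np.log10(obj.weight_mg), np.log10(obj.ovariole_count)),
            0,
        )
    if isinstance(obj, PhenotypeTable):
        df = obj.data
        keep = df["ovariole_count"] > 0
        n_excluded = int((~keep).sum())
        out = df[keep].reset_index(drop=True).copy()
        out["weight_mg"] = np.log10(out["weight_mg"])
        out["ovariole_count"] = np.log10(out["ovariole_count"])
        # bypass PhenotypeTable validation: log weights may legitimately be <= 0
        return out, n_excluded
    raise TypeError(f"cannot log-transform object of type {type(obj).__name__}")


def _standardized_log_cloud(table: PhenotypeTable) -> tuple[np.ndarray, int]:
    logged, n_excluded = log_transform(table)
    pts = np.column_stack(
        [logged["weight_mg"].to_numpy(), logged["ovariole_count"].to_numpy()]
    )
    sd = pts.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (pts - pts.mean(axis=0)) / sd, n_excluded


def caste_gap_statistic(table: PhenotypeTable, seed: int = 0) -> float:
    """Bimodality of a phenotype cloud: silhouette of a 2-means split.

    Points are log10-transformed and z-scored (weight and ovariole count
    live on incommensurate scales), split by 2-means, and scored by the
    mean silhouette width, truncated to [0, 1].  Higher values mean two
    distinct clouds; a single connected cloud scores low.  Degenerate
    tables (all points identical) score 0 by definition.
    """
    if len(table) < 4:
        raise ValueError(f"need at least 4 points, got {len(table)}")
    pts, _ = _standardized_log_cloud(table)
    if len(pts) < 4:
        raise ValueError("fewer than 4 points remain after excluding zero-ovariole rows")
    if np.allclose(pts, pts[0]):
        return 0.0
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(pts)
    if len(np.unique(labels)) < 2:
        return 0.0
    score = float(silhouette_score(pts, labels))
    return float(np.clip(score, 0.0, 1.0))
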