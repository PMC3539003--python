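"""Model fitting and between-strain comparison.

A phenotype cloud — individuals' (body weight, ovariole count) pairs —
is fitted by the one-parameter phenotype curve the developmental map
traces out as the diet coordinates vary in parallel.  Because each
individual's actual feeding regime is unobserved, its latent diet
coordinate t is profiled out: the loss is the sum over individuals of the
squared orthogonal distance, in standardized log10 phenotype space, from
the individual's point to the nearest point on the model curve.

The public surface follows the statsmodels convention:

* :class:`CasteDevelopmentModel` — data plus a free-parameter
  specification; ``fit()`` runs seeded multi-start bounded minimization.
* :class:`CasteDevelopmentResults` — estimates, per-start diagnostics,
  ``summary()``, plotting, and parametric-bootstrap uncertainty via
  :func:`bootstrap_parameters`.
* :func:`compare_strains` — nested-model test for strain differences in
  the larval JH response to diet or in the nurse-supplied L4 diet, with a
  parametric-bootstrap p-value.

Identifiability: ovariole number depends on JH only through
(h - mu0) / sigma0, so absolute titer position is not identifiable from
phenotype data alone.  By default ``mu0`` and ``sigma0`` are held fixed
(at the base parameter values, mu0 anchored to the midpoint of the JH
range) and only relative response parameters are freed; users anchoring
to measured titers can free them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.stats import qmc

from .model_core import (
    ModelParams,
    _develop_fast,
    params_from_dict,
    params_to_dict,
)
from .synthetic_data import (
    CONTINUUM,
    CohortSpec,
    NoiseModel,
    RegimePreset,
    demo_params,
    simulate_cohort,
)
from .tables import PhenotypeTable

__all__ = [
    "DEFAULT_BOUNDS",
    "WHICH_FREE",
    "FitConfig",
    "CasteDevelopmentModel",
    "CasteDevelopmentResults",
    "StrainComparison",
    "bootstrap_parameters",
    "compare_strains",
]

# Tied keys broadcast over the three JH phases; "regime.q2_offset" shifts the
# L4 coordinate of the latent diet path; "l4.w1" re-splits the L4 carryover
# weights as (w1, 1 - w1).
_TIED_JH_KEYS = ("jh.h_w", "jh.h_q", "jh.q_mid", "jh.s")
_REGIME_KEY = "regime.q2_offset"

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "jh.s": (0.02, 0.6),
    "jh.q_mid": (0.05, 0.95),
    "jh.h_q": (2.0, 3.2),
    "jh.h_w": (0.4, 1.6),
    "rescue.mu0": (1.2, 2.4),
    "rescue.sigma0": (0.05, 1.0),
    "size.u_min": (10.0, 150.0),
    "size.u_max": (150.0, 400.0),
    "size.q2_mid": (0.05, 0.95),
    "size.s_u": (0.03, 0.6),
    "size.v_min": (1.0, 100.0),
    "size.v_max": (100.0, 300.0),
    "size.q3_mid": (0.05, 0.95),
    "size.s_v": (0.03, 0.6),
    "size.a0": (0.5, 1.0),
    "l4.w1": (0.0, 1.0),
    _REGIME_KEY: (-0.5, 0.5),
}

WHICH_FREE: dict[str, tuple[str, ...]] = {
    "jh_response": ("jh.h_q", "jh.s"),
    "l4_diet": (_REGIME_KEY,),
}


def _allowed_free_keys() -> set[str]:
    keys = set(params_to_dict(demo_params()))
    keys.discard("rescue.y0")
    keys.update(_TIED_JH_KEYS)
    keys.add(_REGIME_KEY)
    return keys


@lru_cache(maxsize=64)
def _base_items(params: ModelParams) -> tuple:
    # ModelParams is frozen/hashable; flattening it dominates hot loss loops
    return tuple(params_to_dict(params).items())


def apply_free_params(
    base: ModelParams, names: tuple[str, ...], values
) -> tuple[ModelParams, float]:
    """Overlay free-parameter values on a base parameter set.

    Returns the updated :class:`ModelParams` and the latent-path q2
    offset (0 unless ``regime.q2_offset`` is freed).
    """
    d = dict(_base_items(base))
    q2_offset = 0.0
    for name, value in zip(names, values, strict=True):
        v = float(value)
        if name == _REGIME_KEY:
            q2_offset = v
        elif name in _TIED_JH_KEYS:
            f = name.split(".", 1)[1]
            for phase in ("l3", "l4", "l5"):
                d[f"{phase}.{f}"] = v
        elif name == "l4.w1":
            d["l4.w1"] = v
            d["l4.w2"] = 1.0 - v
        elif name in d:
            d[name] = v
        else:
            raise KeyError(f"unknown free parameter {name!r}")
    return params_from_dict(d), q2_offset


def _base_theta(base: ModelParams, names: tuple[str, ...]) -> np.ndarray:
    d = dict(_base_items(base))
    out = []
    for name in names:
        if name == _REGIME_KEY:
            out.append(0.0)
        elif name in _TIED_JH_KEYS:
            out.append(d["l3." + name.split(".", 1)[1]])
        else:
            out.append(d[name])
    return np.asarray(out, dtype=float)


@dataclass(frozen=True)
class FitConfig:
    """Free-parameter mask, bounds and optimizer settings for a fit."""

    free: tuple[str, ...]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_starts: int = 20
    seed: int = 0
    tol: float = 1e-8
    method: str = "trf"
    loss_kind: str = "orthogonal"
    t_range: tuple[float, float] = (0.0, 1.0)
    n_grid: int = 129
    n_refine: int = 3

    def __post_init__(self):
        free = tuple(self.free)
        if len(free) < 1:
            raise ValueError("at least one free parameter is required")
        allowed = _allowed_free_keys()
        unknown = [f for f in free if f not in allowed]
        if unknown:
            raise ValueError(f"unknown free parameter(s): {unknown}")
        if len(set(free)) != len(free):
            raise ValueError(f"duplicate free parameter(s) in {free!r}")
        bounds = dict(DEFAULT_BOUNDS)
        bounds.update(self.bounds)
        missing = [f for f in free if f not in bounds]
        if missing:
            raise ValueError(f"no bounds for free parameter(s): {missing}")
        for f in free:
            lo, hi = bounds[f]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {f!r} must be finite and ordered, got {(lo, hi)!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.method not in ("trf", "nelder-mead"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.loss_kind != "orthogonal":
            raise ValueError(f"unknown loss kind {self.loss_kind!r}")
        if self.n_grid < 8:
            raise ValueError("n_grid must be >= 8")
        if self.n_refine < 1:
            raise ValueError("n_refine must be >= 1")
        object.__setattr__(self, "free", free)
        object.__setattr__(self, "bounds", {f: tuple(map(float, bounds[f])) for f in free})

    @property
    def bounds_array(self) -> np.ndarray:
        return np.array([self.bounds[f] for f in self.free], dtype=float)


_Y_FLOOR = 1e-12  # guards log10 against CDF underflow at extreme parameters


class CasteDevelopmentModel:
    """Phenotype-cloud model: developmental-map curve with latent diet coordinate.

    Parameters
    ----------
    table:
        Phenotype table (rows with zero ovarioles are excluded from the
        log-space loss; the count is kept as ``n_excluded``).
    config:
        :class:`FitConfig` naming the free parameters.
    base_params:
        Fixed values for everything not freed; defaults to the package's
        demo parameter set.
    scale:
        Optional ``(mean_logx, sd_logx, mean_logy, sd_logy)``
        standardization; defaults to this table's own log-phenotype
        moments.  Supply a pooled scale when losses across tables must be
        commensurate.
    regime_models:
        Mapping from rearing label to a :class:`RegimePreset` for rows
        whose feeding regime distribution is known by design: those rows
        are measured against the expected phenotype at the preset's mean
        regime instead of profiling a latent diet coordinate.  Rows with
        unmapped rearing labels (e.g. the artificial continuum, or field
        data of unknown provenance) use the latent-t parallel path.
    """

    def __init__(
        self,
        table: PhenotypeTable,
        config: FitConfig,
        base_params: ModelParams | None = None,
        scale: tuple[float, float, float, float] | None = None,
        regime_models: dict[str, RegimePreset] | None = None,
    ):
        if len(table) == 0:
            raise ValueError("phenotype table is empty")
        self.table = table
        self.config = config
        self.base_params = base_params if base_params is not None else demo_params()
        keep = table.ovarioles > 0
        self.n_excluded = int((~keep).sum())
        if keep.sum() == 0:
            raise ValueError("no rows with positive ovariole count; cannot fit in log space")
        lx = np.log10(table.weights[keep])
        ly = np.log10(table.ovarioles[keep])
        if scale is None:
            sx = lx.std(ddof=0) or 1.0
            sy = ly.std(ddof=0) or 1.0
            scale = (float(lx.mean()), float(sx), float(ly.mean()), float(sy))
        self.scale = scale
        mx, sx, my, sy = scale
        self._pts = np.column_stack([(lx - mx) / sx, (ly - my) / sy])
        self.regime_models = dict(regime_models) if regime_models else {}
        rearing = table.data.loc[keep, "rearing"].to_numpy()
        self._fixed_groups = [
            (np.flatnonzero(rearing == label), preset)
            for label, preset in self.regime_models.items()
            if np.any(rearing == label)
        ]
        fixed_idx = (
            np.concatenate([idx for idx, _ in self._fixed_groups])
            if self._fixed_groups
            else np.empty(0, dtype=int)
        )
        self._latent_idx = np.setdiff1d(np.arange(len(self._pts)), fixed_idx)
        lo, hi = config.t_range
        self._t_grid = np.linspace(lo, hi, config.n_grid)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: FitConfig, base_params: ModelParams | None = None, **kw
    ) -> "CasteDevelopmentModel":
        return cls(PhenotypeTable(df), config, base_params=base_params, **kw)

    # -- loss ---------------------------------------------------------------

    def _curve_std(self, params: ModelParams, q2_offset: float, t: np.ndarray):
        """Standardized log10 curve coordinates at latent diet values ``t``."""
        x, y = _develop_fast(t, np.clip(t + q2_offset, 0.0, 1.0), t, params)
        mx, sx, my, sy = self.scale
        cx = (np.log10(np.maximum(x, _Y_FLOOR)) - mx) / sx
        cy = (np.log10(np.maximum(y, _Y_FLOOR)) - my) / sy
        return cx, cy

    def _point_std(self, params: ModelParams, q2_offset: float, preset: RegimePreset):
        """Standardized log10 expected phenotype at a preset's mean regime."""
        q1, q2, q3 = preset.means
        q2 = float(np.clip(q2 + preset.q2_shift + q2_offset, 0.0, 1.0))
        x, y = _develop_fast(q1, q2, q3, params)
        mx, sx, my, sy = self.scale
        return (np.log10(max(float(x), _Y_FLOOR)) - mx) / sx, (
            np.log10(max(float(y), _Y_FLOOR)) - my
        ) / sy

    def loss_terms(self, params: ModelParams, q2_offset: float = 0.0) -> np.ndarray:
        """Per-individual squared orthogonal distances in standardized log space.

        Rows covered by a known regime model are measured against the
        expected phenotype at their preset's mean regime.  For the
        remaining rows the latent diet coordinate is profiled out:
        minimized over a dense grid followed by one parabolic refinement
        step (re-evaluating the curve at the refined t), which recovers
        the continuous minimizer to well below the grid spacing for this
        smooth curve.
        """
        best = np.empty(len(self._pts))
        for idx, preset in self._fixed_groups:
            px, py = self._point_std(params, q2_offset, preset)
            best[idx] = (self._pts[idx, 0] - px) ** 2 + (self._pts[idx, 1] - py) ** 2
        li = self._latent_idx
        if len(li) == 0:
            return best
        pts = self._pts[li]
        t = self._t_grid
        lo, hi = t[0], t[-1]
        cx, cy = self._curve_std(params, q2_offset, t)
        d2 = (pts[:, :1] - cx) ** 2 + (pts[:, 1:2] - cy) ** 2
        k = np.argmin(d2, axis=1)
        rows = np.arange(len(k))
        lbest = d2[rows, k]
        t_best = t[k]

        # zoom: shrinking local grids around each point's current minimizer
        half = t[1] - t[0]
        offsets = np.linspace(-1.0, 1.0, 9)
        local = None
        for _ in range(self.config.n_refine):
            t_loc = np.clip(t_best[:, None] + half * offsets, lo, hi)
            rx, ry = self._curve_std(params, q2_offset, t_loc.ravel())
            local = (
                (pts[:, :1] - rx.reshape(t_loc.shape)) ** 2
                + (pts[:, 1:2] - ry.reshape(t_loc.shape)) ** 2
            )
            j = np.argmin(local, axis=1)
            t_best = t_loc[rows, j]
            lbest = np.minimum(lbest, local[rows, j])
            half /= 4.0
        # final parabolic step on the last (uniform where unclipped) grid
        interior = (j > 0) & (j < len(offsets) - 1)
        if np.any(interior):
            dm = local[interior, j[interior] - 1]
            d0 = local[interior, j[interior]]
            dp = local[interior, j[interior] + 1]
            denom = dm - 2.0 * d0 + dp
            shift = np.where(denom > 0, 0.5 * (dm - dp) / np.where(denom > 0, denom, 1.0), 0.0)
            t_ref = np.clip(t_best[interior] + np.clip(shift, -1.0, 1.0) * half, lo, hi)
            rx, ry = self._curve_std(params, q2_offset, t_ref)
            d_ref = (pts[interior, 0] - rx) ** 2 + (pts[interior, 1] - ry) ** 2
            lbest[interior] = np.minimum(lbest[interior], d_ref)
        best[li] = lbest
        return best

    def loss(self, theta) -> float:
        """Total loss at a free-parameter vector ``theta``."""
        params, q2_offset = apply_free_params(self.base_params, self.config.free, theta)
        return float(np.sum(self.loss_terms(params, q2_offset)))

    def _residuals(self, theta) -> np.ndarray:
        params, q2_offset = apply_free_params(self.base_params, self.config.free, theta)
        return np.sqrt(self.loss_terms(params, q2_offset) + 1e-300)

    # -- fitting ------------------------------------------------------------

    def _default_starts(self) -> np.ndarray:
        cfg = self.config
        b = cfg.bounds_array
        starts = [np.clip(_base_theta(self.base_params, cfg.free), b[:, 0], b[:, 1])]
        if cfg.n_starts > 1:
            sampler = qmc.LatinHypercube(d=len(cfg.free), seed=cfg.seed)
            unit = sampler.random(cfg.n_starts - 1)
            starts.extend(qmc.scale(unit, b[:, 0], b[:, 1]))
        return np.asarray(starts)

    def fit(self, starts: np.ndarray | None = None) -> "CasteDevelopmentResults":
        """Multi-start bounded local minimization of the profiled loss.

        Deterministic given the config seed; ties across starts resolve
        to the lowest start index.  If no start converges the result is
        returned with ``converged = False`` — never a silent partial
        answer.
        """
        cfg = self.config
        b = cfg.bounds_array
        if starts is None:
            starts = self._default_starts()
        starts = np.atleast_2d(np.asarray(starts, dtype=float))
        thetas, losses, ok = [], [], []
        for x0 in starts:
            x0 = np.clip(x0, b[:, 0], b[:, 1])
            if cfg.method == "trf":
                res = least_squares(
                    self._residuals, x0, bounds=(b[:, 0], b[:, 1]),
                    xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol,
                )
                theta, success = res.x, res.status > 0
            else:
                res = minimize(
                    self.loss, x0, method="Nelder-Mead", bounds=b,
                    options={"xatol": cfg.tol, "fatol": cfg.tol, "maxiter": 2000},
                )
                theta, success = res.x, bool(res.success)
            thetas.append(theta)
            losses.append(self.loss(theta))
            ok.append(success)
        losses = np.asarray(losses)
        best = int(np.argmin(losses))
        params, q2_offset = apply_free_params(self.base_params, cfg.free, thetas[best])
        return CasteDevelopmentResults(
            model=self,
            theta=np.asarray(thetas[best]),
            params=params,
            q2_offset=q2_offset,
            loss=float(losses[best]),
            start_thetas=np.asarray(thetas),
            start_losses=losses,
            start_converged=np.asarray(ok, dtype=bool),
            converged=bool(any(ok)),
        )


@dataclass
class CasteDevelopmentResults:
    """Fit results: estimates, loss surface diagnostics and reporting."""

    model: CasteDevelopmentModel
    theta: np.ndarray
    params: ModelParams
    q2_offset: float
    loss: float
    start_thetas: np.ndarray
    start_losses: np.ndarray
    start_converged: np.ndarray
    converged: bool

    @property
    def free_names(self) -> tuple[str, ...]:
        return self.model.config.free

    def estimates(self) -> dict[str, float]:
        return dict(zip(self.free_names, map(float, self.theta)))

    @property
    def non_identifiable(self) -> bool:
        """Heuristic flag: flat per-start losses despite scattered optima.

        A parameter the data do not constrain produces many distinct
        minimizers with indistinguishable loss; a well-identified fit has
        either dispersed losses or concentrated minimizers.
        """
        if len(self.start_losses) < 3:
            return False
        flat = np.ptp(self.start_losses) <= 1e-6 * (1.0 + abs(self.loss))
        b = self.model.config.bounds_array
        spread = np.max(np.ptp(self.start_thetas, axis=0) / (b[:, 1] - b[:, 0]))
        return bool(flat and spread > 0.05)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Caste development model fit (orthogonal distance, latent diet profiled)",
            f"  observations: {len(self.model._pts)}"
            f" (excluded zero-ovariole rows: {self.model.n_excluded})",
            f"  free parameters: {len(cfg.free)}; starts: {len(self.start_losses)};"
            f" method: {cfg.method}",
            f"  loss: {self.loss:.6g}   converged: {self.converged}"
            f"   non-identifiable: {self.non_identifiable}",
            f"  {'parameter':<18}{'estimate':>14}{'lower':>12}{'upper':>12}",
        ]
        for name, value in self.estimates().items():
            lo, hi = cfg.bounds[name]
            lines.append(f"  {name:<18}{value:>14.6g}{lo:>12.4g}{hi:>12.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict[str, float | bool]:
        out: dict[str, float | bool] = {f"estimate.{k}": v for k, v in self.estimates().items()}
        out["loss"] = self.loss
        out["converged"] = self.converged
        out["non_identifiable"] = self.non_identifiable
        out["n_obs"] = len(self.model._pts)
        out["n_excluded"] = self.model.n_excluded
        return out

    def phenotype_curve(self, n_points: int = 201):
        """Fitted phenotype set on the model's latent-t range."""
        from .phenotype_space import phenotype_set

        lo, hi = self.model.config.t_range
        lo = max(lo, 1e-9) if lo == 0 else lo
        return phenotype_set(
            self.params, t_lo=max(lo, 0.0), t_hi=hi, n_points=n_points, q2_offset=self.q2_offset
        )

    def plot(self, ax=None):
        """Log-log scatter of the data with the fitted curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tbl = self.model.table
        keep = tbl.ovarioles > 0
        ax.scatter(tbl.weights[keep], tbl.ovarioles[keep], s=8, alpha=0.4, label="individuals")
        curve = self.phenotype_curve()
        ax.plot(curve.weight_mg, curve.ovariole_count, color="C1", lw=2, label="fitted curve")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("body weight (mg)")
        ax.set_ylabel("total ovariole count")
        ax.legend()
        return ax


def bootstrap_parameters(
    result: CasteDevelopmentResults,
    cohort_specs: list[CohortSpec],
    n_boot: int = 199,
    seed: int = 0,
    n_starts: int = 1,
    alpha: float = 0.05,
    method: str = "normal",
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric bootstrap of the free-parameter estimates.

    Replicates are simulated from the fitted parameters under the given
    cohort designs (their ``params`` are replaced by the fit; presets are
    shifted by a fitted q2 offset) and refitted warm-started at the
    estimate.

    The profiled-distance estimator carries a small finite-sample bias
    which the bootstrap reproduces, so the default interval is the
    bias-corrected normal interval: centred at ``2*theta_hat -
    mean(theta*)`` with half-width ``t_{1-alpha/2, B-1} * sd(theta*)``.
    ``method="basic"`` gives the pivotal interval ``[2*theta_hat - q_hi,
    2*theta_hat - q_lo]``; ``method="percentile"`` the raw percentile
    interval (not bias-robust — kept for comparison).

    Returns ``(thetas, ci)`` with ``thetas`` of shape (n_boot, d) and
    ``ci`` of shape (d, 2).
    """
    if method not in ("normal", "basic", "percentile"):
        raise ValueError(f"unknown interval method {method!r}")
    cfg = result.model.config
    rng = np.random.default_rng(seed)
    thetas = np.empty((n_boot, len(cfg.free)))
    lhs_starts = (
        qmc.scale(
            qmc.LatinHypercube(d=len(cfg.free), seed=seed).random(n_starts - 1),
            cfg.bounds_array[:, 0],
            cfg.bounds_array[:, 1],
        )
        if n_starts > 1
        else np.empty((0, len(cfg.free)))
    )
    for b in range(n_boot):
        tables = []
        for spec in cohort_specs:
            child = replace(
                spec,
                params=result.params,
                preset=spec.preset.with_q2_shift(result.q2_offset),
                seed=int(rng.integers(2**31)),
            )
            tables.append(simulate_cohort(child))
        table = PhenotypeTable.concat(tables)
        model = CasteDevelopmentModel(
            table, cfg, base_params=result.model.base_params, scale=result.model.scale,
            regime_models=result.model.regime_models,
        )
        starts = np.vstack([result.theta[None, :], lhs_starts])
        thetas[b] = model.fit(starts=starts).theta
    q_lo = np.quantile(thetas, alpha / 2, axis=0)
    q_hi = np.quantile(thetas, 1 - alpha / 2, axis=0)
    if method == "percentile":
        ci = np.column_stack([q_lo, q_hi])
    elif method == "basic":
        ci = np.column_stack([2 * result.theta - q_hi, 2 * result.theta - q_lo])
    else:
        from scipy.stats import t as t_dist

        center = 2 * result.theta - thetas.mean(axis=0)
        half = t_dist.ppf(1 - alpha / 2, n_boot - 1) * thetas.std(axis=0, ddof=1)
        ci = np.column_stack([center - half, center + half])
    return thetas, ci


# -- strain comparison ------------------------------------------------------


def _fit_joint(
    models: list[CasteDevelopmentModel], cfg: FitConfig, starts: np.ndarray
) -> tuple[np.ndarray, float]:
    """Fit one shared free-parameter vector across several tables."""
    b = cfg.bounds_array

    def residuals(theta):
        return np.concatenate([m._residuals(theta) for m in models])

    def total_loss(theta):
        return float(sum(m.loss(theta) for m in models))

    thetas, losses = [], []
    for x0 in np.atleast_2d(starts):
        x0 = np.clip(x0, b[:, 0], b[:, 1])
        if cfg.method == "trf":
            res = least_squares(
                residuals, x0, bounds=(b[:, 0], b[:, 1]), xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol
            )
        else:
            res = minimize(
                total_loss, x0, method="Nelder-Mead", bounds=b,
                options={"xatol": cfg.tol, "fatol": cfg.tol, "maxiter": 2000},
            )
        thetas.append(res.x)
        losses.append(total_loss(res.x))
    best = int(np.argmin(losses))
    return np.asarray(thetas[best]), float(losses[best])


@dataclass
class StrainComparison:
    """Shared- vs. strain-specific-parameter comparison with bootstrap p-value."""

    which: str
    free: tuple[str, ...]
    theta_null: np.ndarray
    loss_null: float
    fit_a: CasteDevelopmentResults
    fit_b: CasteDevelopmentResults
    statistic: float
    boot_stats: np.ndarray
    p_value: float

    @property
    def loss_alt(self) -> float:
        return self.fit_a.loss + self.fit_b.loss

    def summary(self) -> str:
        lines = [
            f"Strain comparison ({self.which}): shared vs. strain-specific "
            f"{', '.join(self.free)}",
            f"  null loss: {self.loss_null:.6g}   alternative loss: {self.loss_alt:.6g}",
            f"  statistic (loss reduction): {self.statistic:.6g}",
            f"  parametric bootstrap: B = {len(self.boot_stats)}   p = {self.p_value:.4g}",
            "  strain-specific estimates:",
        ]
        for label, fit in (("A", self.fit_a), ("B", self.fit_b)):
            est = ", ".join(f"{k} = {v:.6g}" for k, v in fit.estimates().items())
            lines.append(f"    {label}: {est}")
        return "\n".join(lines)

    def to_dict(self) -> dict[str, float]:
        out = {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_boot": float(len(self.boot_stats)),
            "loss_null": self.loss_null,
            "loss_alt": self.loss_alt,
        }
        for k, v in zip(self.free, self.theta_null):
            out[f"null.{k}"] = float(v)
        for label, fit in (("a", self.fit_a), ("b", self.fit_b)):
            for k, v in fit.estimates().items():
                out[f"{label}.{k}"] = v
        return out


def compare_strains(
    table_a: PhenotypeTable,
    table_b: PhenotypeTable,
    which: str,
    base_params: ModelParams | None = None,
    config: FitConfig | None = None,
    preset_a: RegimePreset = CONTINUUM,
    preset_b: RegimePreset = CONTINUUM,
    noise: NoiseModel | None = None,
    n_boot: int = 199,
    seed: int = 0,
) -> StrainComparison:
    """Test whether two strains share the designated developmental parameters.

    ``which`` selects the contrast: ``"jh_response"`` frees the tied JH
    asymptote and steepness (is the larval JH response to diet
    strain-specific?); ``"l4_diet"`` frees the latent-path q2 offset (is
    the nurse-supplied L4 diet strain-specific?).  The statistic is the
    loss reduction from null (shared) to alternative (strain-specific)
    parameters — a likelihood-ratio analogue — and its null distribution
    comes from a parametric bootstrap: both strains simulated from the
    fitted shared parameters under the given rearing presets, both models
    refitted, with the +1-corrected p-value (never exactly zero).
    """
    if which not in WHICH_FREE:
        raise ValueError(f"which must be one of {sorted(WHICH_FREE)}, got {which!r}")
    if n_boot < 19:
        raise ValueError(f"n_boot must be >= 19, got {n_boot!r}")
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("both phenotype tables must be nonempty")
    free = WHICH_FREE[which]
    base_params = base_params if base_params is not None else demo_params()
    noise = noise if noise is not None else NoiseModel()
    if config is None:
        config = FitConfig(free=free, n_starts=8)
    elif tuple(config.free) != free:
        raise ValueError(
            f"config.free {config.free!r} does not match the nested masks for "
            f"{which!r}: {free!r}"
        )

    pooled = PhenotypeTable.concat([table_a, table_b])
    keep = pooled.ovarioles > 0
    lx = np.log10(pooled.weights[keep])
    ly = np.log10(pooled.ovarioles[keep])
    scale = (float(lx.mean()), float(lx.std(ddof=0) or 1.0),
             float(ly.mean()), float(ly.std(ddof=0) or 1.0))

    def build(table):
        return CasteDevelopmentModel(table, config, base_params=base_params, scale=scale)

    def run(tbl_a, tbl_b, starts_null, full=True):
        ma, mb = build(tbl_a), build(tbl_b)
        theta_null, loss_null = _fit_joint([ma, mb], config, starts_null)
        # starting the strain-specific fits at the shared optimum guarantees
        # the nesting invariant loss_alt <= loss_null
        if full:
            alt_starts = np.vstack([theta_null[None, :], np.atleast_2d(starts_null)])
        else:
            alt_starts = theta_null[None, :]
        fit_a = ma.fit(starts=alt_starts)
        fit_b = mb.fit(starts=alt_starts)
        return ma, mb, theta_null, loss_null, fit_a, fit_b

    starts = CasteDevelopmentModel(pooled, config, base_params=base_params,
                                   scale=scale)._default_starts()
    _, _, theta_null, loss_null, fit_a, fit_b = run(table_a, table_b, starts)
    statistic = loss_null - (fit_a.loss + fit_b.loss)

    null_params, null_offset = apply_free_params(base_params, free, theta_null)
    rng = np.random.default_rng(seed)
    boot_stats = np.empty(n_boot)
    warm = theta_null[None, :]
    for b in range(n_boot):
        sim_a = simulate_cohort(
            CohortSpec(
                n=len(table_a), preset=preset_a.with_q2_shift(null_offset),
                params=null_params, noise=noise, strain="boot_a",
                seed=int(rng.integers(2**31)),
            )
        )
        sim_b = simulate_cohort(
            CohortSpec(
                n=len(table_b), preset=preset_b.with_q2_shift(null_offset),
                params=null_params, noise=noise, strain="boot_b",
                seed=int(rng.integers(2**31)),
            )
        )
        _, _, _, b_loss_null, b_fit_a, b_fit_b = run(sim_a, sim_b, warm, full=False)
        boot_stats[b] = b_loss_null - (b_fit_a.loss + b_fit_b.loss)

    p_value = (1.0 + np.sum(boot_stats >= statistic)) / (1.0 + n_boot)
    return StrainComparison(
        which=which,
        free=free,
        theta_null=theta_null,
        loss_null=loss_null,
        fit_a=fit_a,
        fit_b=fit_b,
        statistic=float(statistic),
        boot_stats=boot_stats,
        p_value=float(p_value),
    )
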