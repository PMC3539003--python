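"""Deterministic developmental map from nurse feeding regimes to adult phenotypes.

The model treats honeybee larval development as three feeding phases — the
pooled first three instars (L1–L3), the fourth instar (L4) and the fifth
instar (L5) — each characterised by a normalized diet coordinate
``q1, q2, q3`` in [0, 1] (sugar content / amount of the food supplied by
nurse workers).  Diet drives the hemolymph juvenile-hormone (JH) titer in
each phase through a logistic dose–response on a log10 pmol/mL scale.  The
JH profile in turn rescues developing ovariole primordia from programmed
cell death: each ovariole carries a normally distributed rescue threshold,
and a phase-specific proportion of ovarioles is available for rescue by
that phase's titer.  Body size follows the critical-weight framework: the
L4 diet sets the critical weight, the L5 diet the post-critical growth
increment, and a proportional reduction maps maximal larval weight to
adult weight at eclosion.

All response functions are the logistic

    f(d) = low + (high - low) / (1 + exp(-(d - mid) / scale)),

with the phase JH titers using a convex-weighted effective diet over the
current and earlier phases.  Functions accept scalars or numpy arrays in
the diet/titer arguments; dataclass constructors validate their invariants
eagerly so that invalid parameter sets fail at construction, not deep in a
fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.special import ndtr

__all__ = [
    "FeedingRegime",
    "JHPhaseParams",
    "RescueParams",
    "SizeParams",
    "ModelParams",
    "JHProfile",
    "Phenotype",
    "logistic_response",
    "jh_titer",
    "jh_l3",
    "jh_l4",
    "jh_l5",
    "rescue_fraction",
    "ovariole_number",
    "critical_weight",
    "growth_increment",
    "adult_weight",
    "develop",
    "develop_arrays",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]

_SUM_TOL = 1e-12


def _as_float_array(value, name: str):
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return arr


def _check_unit_interval(value, name: str):
    arr = _as_float_array(value, name)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        bad = arr[(arr < 0.0) | (arr > 1.0)] if arr.ndim else arr
        raise ValueError(f"{name} must lie in [0, 1], got {np.atleast_1d(bad)[0]!r}")
    return arr


def _scalar_or_array(out: np.ndarray, scalar: bool):
    return float(out) if scalar else out


def logistic_response(d, low: float, high: float, mid: float, scale: float):
    """Logistic response from ``low`` to ``high`` with midpoint and steepness scale.

    Vectorized in ``d``; ``scale`` must be positive.  The output is clipped
    to the closed asymptote interval so that downstream bound invariants
    hold exactly at floating-point extremes.
    """
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale!r}")
    arr = np.asarray(d, dtype=float)
    scalar = arr.ndim == 0
    z = (arr - mid) / scale
    out = low + (high - low) / (1.0 + np.exp(-z))
    out = np.clip(out, min(low, high), max(low, high))
    return _scalar_or_array(out, scalar)


@dataclass(frozen=True)
class FeedingRegime:
    """Normalized diet coordinates (q1, q2, q3) for the L1–L3, L4 and L5 phases."""

    q1: float
    q2: float
    q3: float

    def __post_init__(self):
        for name in ("q1", "q2", "q3"):
            _check_unit_interval(getattr(self, name), name)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.q1, self.q2, self.q3)


@dataclass(frozen=True)
class JHPhaseParams:
    """Logistic JH response of one feeding phase.

    ``h_w`` / ``h_q`` are the log10 JH asymptotes under pure worker / queen
    diet; ``q_mid`` and ``s`` the diet midpoint and steepness scale of the
    response.  ``weights`` are the convex diet weights (earliest phase
    first, current phase last) forming the effective diet fed to the
    logistic; their length equals the phase index (1 for L1–L3, 2 for L4,
    3 for L5).
    """

    h_w: float
    h_q: float
    q_mid: float
    s: float
    weights: tuple[float, ...] = (1.0,)

    def __post_init__(self):
        for name in ("h_w", "h_q", "q_mid", "s"):
            _as_float_array(getattr(self, name), name)
        if self.h_q < self.h_w:
            raise ValueError(f"h_q must be >= h_w, got h_q={self.h_q!r} < h_w={self.h_w!r}")
        if self.s <= 0:
            raise ValueError(f"s must be > 0, got {self.s!r}")
        _check_unit_interval(self.q_mid, "q_mid")
        w = tuple(float(x) for x in self.weights)
        if len(w) < 1:
            raise ValueError("weights must be non-empty")
        if any(x < 0 for x in w):
            raise ValueError(f"weights must be nonnegative, got {w!r}")
        if abs(sum(w) - 1.0) > _SUM_TOL:
            raise ValueError(f"weights must sum to 1, got sum {sum(w)!r}")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class RescueParams:
    """Ovariole rescue-threshold distribution and per-phase availability.

    An ovariole escapes programmed cell death iff the log JH titer of its
    phase exceeds its threshold, thresholds being normal(mu0, sigma0).
    ``r1 + r2 + r3 = 1`` partitions the ``y0`` primordia over the three
    phases.  ``y0`` counts developing ovarioles before PCD onset, summed
    over both ovaries.
    """

    mu0: float
    sigma0: float
    r1: float
    r2: float
    r3: float
    y0: int = 160

    def __post_init__(self):
        _as_float_array(self.mu0, "mu0")
        if not (self.sigma0 > 0):
            raise ValueError(f"sigma0 must be > 0, got {self.sigma0!r}")
        for name in ("r1", "r2", "r3"):
            _check_unit_interval(getattr(self, name), name)
        total = self.r1 + self.r2 + self.r3
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"r1 + r2 + r3 must equal 1 exactly, got {total!r}")
        if int(self.y0) != self.y0 or self.y0 < 1:
            raise ValueError(f"y0 must be a positive integer, got {self.y0!r}")
        object.__setattr__(self, "y0", int(self.y0))

    @property
    def r(self) -> tuple[float, float, float]:
        return (self.r1, self.r2, self.r3)


@dataclass(frozen=True)
class SizeParams:
    """Critical-weight and growth-increment responses plus eclosion scaling.

    ``u_min``..``u_max`` (mg) bound the critical weight as a logistic in
    q2; ``v_min``..``v_max`` (mg) bound the post-critical increment as a
    logistic in q3; ``a0`` in (0, 1] is the proportional reduction from
    maximal larval weight ``u + v`` to adult weight at eclosion.  Flat
    (degenerate) responses with equal bounds are legal.
    """

    u_min: float
    u_max: float
    q2_mid: float
    s_u: float
    v_min: float
    v_max: float
    q3_mid: float
    s_v: float
    a0: float

    def __post_init__(self):
        if not (0 <= self.u_min <= self.u_max):
            raise ValueError(f"need 0 <= u_min <= u_max, got ({self.u_min!r}, {self.u_max!r})")
        if not (0 <= self.v_min <= self.v_max):
            raise ValueError(f"need 0 <= v_min <= v_max, got ({self.v_min!r}, {self.v_max!r})")
        for name in ("s_u", "s_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("q2_mid", "q3_mid"):
            _check_unit_interval(getattr(self, name), name)
        if not (0 < self.a0 <= 1):
            raise ValueError(f"a0 must be in (0, 1], got {self.a0!r}")


@dataclass(frozen=True)
class ModelParams:
    """Aggregate parameter set of the developmental map."""

    jh_l3: JHPhaseParams
    jh_l4: JHPhaseParams
    jh_l5: JHPhaseParams
    rescue: RescueParams
    size: SizeParams

    def __post_init__(self):
        for phase, n in (("jh_l3", 1), ("jh_l4", 2), ("jh_l5", 3)):
            if len(getattr(self, phase).weights) != n:
                raise ValueError(
                    f"{phase} expects {n} diet weight(s), got {getattr(self, phase).weights!r}"
                )


@dataclass(frozen=True)
class JHProfile:
    """Log10 JH titers in the three feeding phases."""

    h1: float
    h2: float
    h3: float


@dataclass(frozen=True)
class Phenotype:
    """Adult phenotype: body weight ``x`` (mg) and total ovariole count ``y``.

    ``y`` is real-valued for model expectations and integer for simulated
    individuals.
    """

    x: float
    y: float

    def __post_init__(self):
        _as_float_array(self.x, "x")
        _as_float_array(self.y, "y")
        if not self.x > 0:
            raise ValueError(f"body weight x must be > 0, got {self.x!r}")
        if self.y < 0:
            raise ValueError(f"ovariole count y must be >= 0, got {self.y!r}")


# --- JH titers -------------------------------------------------------------


def jh_titer(diets: Iterable, p: JHPhaseParams):
    """Phase JH titer: logistic response of the convex-weighted effective diet."""
    qs = [
        _check_unit_interval(q, f"q{i + 1}") for i, q in enumerate(diets)
    ]
    if len(qs) != len(p.weights):
        raise ValueError(
            f"expected {len(p.weights)} diet coordinate(s), got {len(qs)}"
        )
    d = sum(w * q for w, q in zip(p.weights, qs))
    return logistic_response(d, p.h_w, p.h_q, p.q_mid, p.s)


def jh_l3(q1, p: JHPhaseParams):
    """Log10 JH titer in L1–L3 as a function of the early-instar diet q1."""
    return jh_titer((q1,), p)


def jh_l4(q1, q2, p: JHPhaseParams):
    """Log10 JH titer in L4, responding to the L1–L3 and L4 diets."""
    return jh_titer((q1, q2), p)


def jh_l5(q1, q2, q3, p: JHPhaseParams):
    """Log10 JH titer in L5, responding to all three phase diets."""
    return jh_titer((q1, q2, q3), p)


# --- ovariole rescue -------------------------------------------------------


def rescue_fraction(h, rescue: RescueParams):
    """Probability that an ovariole's rescue threshold lies below titer ``h``.

    Thresholds are normal(mu0, sigma0), so this is the standard-normal CDF
    of ``(h - mu0) / sigma0``.
    """
    arr = _as_float_array(h, "h")
    scalar = arr.ndim == 0
    out = ndtr((arr - rescue.mu0) / rescue.sigma0)
    return _scalar_or_array(np.asarray(out), scalar)


def _ovariole_number_arrays(h1, h2, h3, rescue: RescueParams):
    return rescue.y0 * (
        rescue.r1 * rescue_fraction(h1, rescue)
        + rescue.r2 * rescue_fraction(h2, rescue)
        + rescue.r3 * rescue_fraction(h3, rescue)
    )


def ovariole_number(profile: JHProfile, rescue: RescueParams):
    """Expected adult ovariole count given a JH profile.

    y0 * [r1 F((h1-mu0)/s0) + r2 F((h2-mu0)/s0) + r3 F((h3-mu0)/s0)] with F
    the standard normal CDF; strictly inside (0, y0) for finite titers.
    """
    return float(_ovariole_number_arrays(profile.h1, profile.h2, profile.h3, rescue))


# --- size determination ----------------------------------------------------


def critical_weight(q2, size: SizeParams):
    """Larval critical weight (mg) as a logistic response to the L4 diet q2."""
    _check_unit_interval(q2, "q2")
    return logistic_response(q2, size.u_min, size.u_max, size.q2_mid, size.s_u)


def growth_increment(q3, size: SizeParams):
    """Post-critical growth increment (mg) as a logistic response to the L5 diet q3."""
    _check_unit_interval(q3, "q3")
    return logistic_response(q3, size.v_min, size.v_max, size.q3_mid, size.s_v)


def adult_weight(u, v, size: SizeParams):
    """Adult eclosion weight: a0 * (u + v), the scaled maximal larval weight."""
    u_arr = _as_float_array(u, "u")
    v_arr = _as_float_array(v, "v")
    if np.any(u_arr < 0):
        raise ValueError(f"critical weight u must be >= 0, got {u!r}")
    if np.any(v_arr < 0):
        raise ValueError(f"growth increment v must be >= 0, got {v!r}")
    scalar = u_arr.ndim == 0 and v_arr.ndim == 0
    return _scalar_or_array(size.a0 * (u_arr + v_arr), scalar)


# --- composition -----------------------------------------------------------


def _develop_fast(q1, q2, q3, params: ModelParams):
    """Validation-free developmental map for hot loops.

    Callers must guarantee the diet arrays are already inside [0, 1]; the
    public :func:`develop_arrays` is the checked equivalent.
    """
    jh3, jh4, jh5 = params.jh_l3, params.jh_l4, params.jh_l5
    h1 = logistic_response(jh3.weights[0] * q1, jh3.h_w, jh3.h_q, jh3.q_mid, jh3.s)
    h2 = logistic_response(
        jh4.weights[0] * q1 + jh4.weights[1] * q2, jh4.h_w, jh4.h_q, jh4.q_mid, jh4.s
    )
    h3 = logistic_response(
        jh5.weights[0] * q1 + jh5.weights[1] * q2 + jh5.weights[2] * q3,
        jh5.h_w, jh5.h_q, jh5.q_mid, jh5.s,
    )
    rescue = params.rescue
    y = rescue.y0 * (
        rescue.r1 * ndtr((np.asarray(h1) - rescue.mu0) / rescue.sigma0)
        + rescue.r2 * ndtr((np.asarray(h2) - rescue.mu0) / rescue.sigma0)
        + rescue.r3 * ndtr((np.asarray(h3) - rescue.mu0) / rescue.sigma0)
    )
    size = params.size
    u = logistic_response(q2, size.u_min, size.u_max, size.q2_mid, size.s_u)
    v = logistic_response(q3, size.v_min, size.v_max, size.q3_mid, size.s_v)
    return size.a0 * (np.asarray(u) + np.asarray(v)), y


def develop_arrays(q1, q2, q3, params: ModelParams):
    """Vectorized developmental map: arrays of diets -> (weight, ovariole) arrays.

    This is the workhorse used by the morphospace and fitting code; the
    scalar :func:`develop` wraps it with Phenotype packaging.
    """
    h1 = jh_l3(q1, params.jh_l3)
    h2 = jh_l4(q1, q2, params.jh_l4)
    h3 = jh_l5(q1, q2, q3, params.jh_l5)
    y = _ovariole_number_arrays(h1, h2, h3, params.rescue)
    u = critical_weight(q2, params.size)
    v = growth_increment(q3, params.size)
    x = adult_weight(u, v, params.size)
    return x, y


def develop(regime: FeedingRegime, params: ModelParams) -> Phenotype:
    """Expected adult phenotype for a feeding regime.

    Weight is determined by q2 (critical weight) and q3 (growth increment);
    ovariole number by the full JH profile driven by q1, q2, q3.  Both
    components are nondecreasing in every diet coordinate.
    """
    x, y = develop_arrays(regime.q1, regime.q2, regime.q3, params)
    return Phenotype(float(x), float(y))


def jh_profile(regime: FeedingRegime, params: ModelParams) -> JHProfile:
    """JH titers of the three phases for a feeding regime."""
    return JHProfile(
        h1=float(jh_l3(regime.q1, params.jh_l3)),
        h2=float(jh_l4(regime.q1, regime.q2, params.jh_l4)),
        h3=float(jh_l5(regime.q1, regime.q2, regime.q3, params.jh_l5)),
    )


# --- serialization ---------------------------------------------------------

_PHASES = ("l3", "l4", "l5")
_PHASE_FIELDS = ("h_w", "h_q", "q_mid", "s")
_RESCUE_FIELDS = ("mu0", "sigma0", "r1", "r2", "r3", "y0")
_SIZE_FIELDS = ("u_min", "u_max", "q2_mid", "s_u", "v_min", "v_max", "q3_mid", "s_v", "a0")


def params_to_dict(params: ModelParams) -> dict[str, float]:
    """Flatten a ModelParams to phase-prefixed keys (e.g. ``l3.h_w``)."""
    out: dict[str, float] = {}
    for phase, jh in zip(_PHASES, (params.jh_l3, params.jh_l4, params.jh_l5)):
        for f in _PHASE_FIELDS:
            out[f"{phase}.{f}"] = float(getattr(jh, f))
        for i, w in enumerate(jh.weights, start=1):
            out[f"{phase}.w{i}"] = float(w)
    for f in _RESCUE_FIELDS:
        out[f"rescue.{f}"] = float(getattr(params.rescue, f))
    for f in _SIZE_FIELDS:
        out[f"size.{f}"] = float(getattr(params.size, f))
    return out


def params_from_dict(d: Mapping[str, float]) -> ModelParams:
    """Inverse of :func:`params_to_dict`; raises on missing or unknown keys."""
    d = dict(d)

    def pop(key: str) -> float:
        try:
            return float(d.pop(key))
        except KeyError:
            raise KeyError(f"missing parameter key {key!r}") from None

    phases = []
    for i, phase in enumerate(_PHASES, start=1):
        kw = {f: pop(f"{phase}.{f}") for f in _PHASE_FIELDS}
        kw["weights"] = tuple(pop(f"{phase}.w{j}") for j in range(1, i + 1))
        phases.append(JHPhaseParams(**kw))
    rescue_kw = {f: pop(f"rescue.{f}") for f in _RESCUE_FIELDS}
    rescue_kw["y0"] = int(rescue_kw["y0"])
    rescue = RescueParams(**rescue_kw)
    size = SizeParams(**{f: pop(f"size.{f}") for f in _SIZE_FIELDS})
    if d:
        raise KeyError(f"unknown parameter key(s): {sorted(d)!r}")
    return ModelParams(jh_l3=phases[0], jh_l4=phases[1], jh_l5=phases[2], rescue=rescue, size=size)


def save_params(params: ModelParams, path) -> None:
    """Write parameters as flat ``key = value`` lines; full-precision round trip."""
    lines = [f"{k} = {v!r}\n" for k, v in params_to_dict(params).items()]
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(lines)


def load_params(path) -> ModelParams:
    """Read a flat ``key = value`` parameter file written by :func:`save_params`."""
    d: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            try:
                d[key.strip()] = float(value)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value {value.strip()!r}") from None
    return params_from_dict(d)
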