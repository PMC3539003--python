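"""Synthetic cohorts with the statistical structure the analysis assumes.

Emulates hive and laboratory rearing data: feeding regimes drawn from
named presets (discrete queen and worker hive regimes, or an artificial
continuum where the three diet coordinates vary in parallel), phenotypes
produced by the developmental map with per-ovariole stochastic rescue and
multiplicative lognormal weight noise, and two-strain designs expressing
strain-specific JH responses and nurse-supplied L4 diets.

The queen hive regime reflects unrestricted, sugar-rich feeding on all
phases; the worker regime low early-instar sugar, restricted L4 feeding
and a partially restored L5 diet.  Default model parameters are an
illustrative fixture spanning a worker-like to queen-like morphospace;
they are not literature estimates.

Randomness: each cohort owns one seed; individuals use spawned
substreams, so an individual's draw is independent of cohort size and
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model_core import (
    FeedingRegime,
    JHPhaseParams,
    ModelParams,
    Phenotype,
    RescueParams,
    SizeParams,
    develop_arrays,
    jh_l3,
    jh_l4,
    jh_l5,
    rescue_fraction,
)
from .tables import PhenotypeTable

__all__ = [
    "RegimePreset",
    "NoiseModel",
    "CohortSpec",
    "QUEEN_HIVE",
    "WORKER_HIVE",
    "CONTINUUM",
    "PRESETS",
    "get_preset",
    "demo_params",
    "sample_regime",
    "simulate_individual",
    "simulate_cohort",
    "make_two_strain",
]


@dataclass(frozen=True)
class RegimePreset:
    """Distribution of feeding regimes imposed by nurses.

    ``kind="normal"``: independent per-component normals (means, spreads)
    clipped to [0, 1].  ``kind="parallel_uniform"``: a single latent t
    uniform on ``t_range`` applied to all three components (the
    artificial-continuum rearing design), with ``means``/``spreads``
    unused except that q2 honours ``q2_shift``.
    """

    name: str
    means: tuple[float, float, float]
    spreads: tuple[float, float, float]
    kind: str = "normal"
    t_range: tuple[float, float] = (0.1, 0.9)
    q2_shift: float = 0.0

    def __post_init__(self):
        if self.kind not in ("normal", "parallel_uniform"):
            raise ValueError(f"unknown preset kind {self.kind!r}")
        for m in self.means:
            if not (0 <= m <= 1):
                raise ValueError(f"preset means must lie in [0, 1], got {self.means!r}")
        if any(s < 0 for s in self.spreads):
            raise ValueError(f"preset spreads must be >= 0, got {self.spreads!r}")
        lo, hi = self.t_range
        if not (0 <= lo < hi <= 1):
            raise ValueError(f"t_range must satisfy 0 <= lo < hi <= 1, got {self.t_range!r}")

    def with_q2_shift(self, delta: float) -> "RegimePreset":
        """Shift the L4 diet component by ``delta`` (applied before clipping)."""
        return replace(self, q2_shift=self.q2_shift + float(delta))


QUEEN_HIVE = RegimePreset("queen_hive", means=(0.85, 0.90, 0.90), spreads=(0.05, 0.05, 0.05))
WORKER_HIVE = RegimePreset("worker_hive", means=(0.20, 0.30, 0.50), spreads=(0.05, 0.05, 0.05))
CONTINUUM = RegimePreset(
    "continuum", means=(0.5, 0.5, 0.5), spreads=(0.0, 0.0, 0.0), kind="parallel_uniform"
)

PRESETS = {p.name: p for p in (QUEEN_HIVE, WORKER_HIVE, CONTINUUM)}


def get_preset(name: str) -> RegimePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown regime preset {name!r}; choose from {sorted(PRESETS)}") from None


@dataclass(frozen=True)
class NoiseModel:
    """Measurement / developmental noise applied on top of the expected phenotype.

    Weight gets a multiplicative lognormal factor with mean 1 and
    coefficient of variation ``cv_weight``; ovariole counts are either the
    per-ovariole stochastic rescue (``binomial_per_ovariole``) or the
    deterministic expectation (``expected_value``).
    """

    cv_weight: float = 0.08
    ovariole_mode: str = "binomial_per_ovariole"

    def __post_init__(self):
        if self.cv_weight < 0:
            raise ValueError(f"cv_weight must be >= 0, got {self.cv_weight!r}")
        if self.ovariole_mode not in ("binomial_per_ovariole", "expected_value"):
            raise ValueError(f"unknown ovariole mode {self.ovariole_mode!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate one labelled cohort reproducibly."""

    n: int
    preset: RegimePreset
    params: ModelParams
    noise: NoiseModel
    strain: str = "wild"
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"cohort size n must be >= 1, got {self.n!r}")


def demo_params() -> ModelParams:
    """Illustrative default parameter set (fixture values, not fitted estimates).

    Chosen so the morphospace spans worker-like (about 100–150 mg, a
    handful of ovarioles) to queen-like (about 300 mg, close to y0
    ovarioles) phenotypes: JH from 1.0 to 2.6 log10 pmol/mL per phase with
    equal diet carryover weights, rescue thresholds normal(1.8, 0.3) — the
    midpoint of the JH range — availability split (0.25, 0.5, 0.25) over
    the three phases, y0 = 160 primordia, critical weight 60–260 mg,
    growth increment 20–160 mg and eclosion scaling a0 = 0.8.
    """
    jh = dict(h_w=1.0, h_q=2.6, q_mid=0.5, s=0.12)
    return ModelParams(
        jh_l3=JHPhaseParams(**jh, weights=(1.0,)),
        jh_l4=JHPhaseParams(**jh, weights=(0.5, 0.5)),
        jh_l5=JHPhaseParams(**jh, weights=(1 / 3, 1 / 3, 1 / 3)),
        rescue=RescueParams(mu0=1.8, sigma0=0.3, r1=0.25, r2=0.5, r3=0.25, y0=160),
        size=SizeParams(
            u_min=60.0, u_max=260.0, q2_mid=0.5, s_u=0.15,
            v_min=20.0, v_max=160.0, q3_mid=0.5, s_v=0.15, a0=0.8,
        ),
    )


def _sample_regime_values(preset: RegimePreset, rng: np.random.Generator) -> np.ndarray:
    if preset.kind == "parallel_uniform":
        lo, hi = preset.t_range
        t = rng.uniform(lo, hi)
        q = np.array([t, t + preset.q2_shift, t])
    else:
        q = rng.normal(loc=preset.means, scale=preset.spreads)
        q[1] += preset.q2_shift
    return np.clip(q, 0.0, 1.0)


def sample_regime(preset: RegimePreset, rng: np.random.Generator) -> FeedingRegime:
    """Draw one feeding regime from a preset, clipped to the unit cube."""
    q = _sample_regime_values(preset, rng)
    return FeedingRegime(q1=float(q[0]), q2=float(q[1]), q3=float(q[2]))


def _phase_rescue_probs(regime: FeedingRegime, params: ModelParams) -> np.ndarray:
    h = np.array(
        [
            jh_l3(regime.q1, params.jh_l3),
            jh_l4(regime.q1, regime.q2, params.jh_l4),
            jh_l5(regime.q1, regime.q2, regime.q3, params.jh_l5),
        ]
    )
    return rescue_fraction(h, params.rescue)


def _realize(
    x_exp: float,
    y_exp: float,
    probs: np.ndarray,
    params: ModelParams,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw one individual's realized phenotype from its expectations.

    Weight gets a mean-one lognormal factor.  Each of the y0 primordia is
    independently assigned a rescue phase with probabilities (r1, r2, r3)
    and survives iff that phase's titer exceeds its normal(mu0, sigma0)
    threshold; since primordia are independent, the survivor count is
    exactly Binomial(y0, r1 p1 + r2 p2 + r3 p3) and is drawn as such.
    """
    if noise.cv_weight > 0:
        sigma2 = np.log1p(noise.cv_weight**2)
        x = x_exp * rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2))
    else:
        x = x_exp
    if noise.ovariole_mode == "expected_value":
        y = y_exp
    else:
        rescue = params.rescue
        p_mix = float(np.dot(rescue.r, probs))
        y = float(rng.binomial(rescue.y0, p_mix))
    return float(x), float(y)


def simulate_individual(
    regime: FeedingRegime,
    params: ModelParams,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> Phenotype:
    """One realized individual: noisy weight and stochastically rescued ovarioles."""
    x_exp, y_exp = develop_arrays(regime.q1, regime.q2, regime.q3, params)
    probs = _phase_rescue_probs(regime, params)
    x, y = _realize(float(x_exp), float(y_exp), probs, params, noise, rng)
    return Phenotype(x=x, y=y)


def _individual_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(ss) for ss in np.random.SeedSequence(seed).spawn(n)]


def simulate_cohort(spec: CohortSpec) -> PhenotypeTable:
    """Simulate ``spec.n`` independent labelled individuals.

    Individual i draws its regime and phenotype from substream i of the
    cohort seed, so results do not depend on cohort size or row order;
    the deterministic developmental map is evaluated vectorized across
    the cohort.
    """
    rngs = _individual_rngs(spec.seed, spec.n)
    regimes = np.empty((spec.n, 3))
    for i, rng in enumerate(rngs):
        regimes[i] = _sample_regime_values(spec.preset, rng)
    params = spec.params
    q1, q2, q3 = regimes.T
    x_exp, y_exp = develop_arrays(q1, q2, q3, params)
    from .model_core import jh_l3 as _l3, jh_l4 as _l4, jh_l5 as _l5

    h = np.column_stack(
        [_l3(q1, params.jh_l3), _l4(q1, q2, params.jh_l4), _l5(q1, q2, q3, params.jh_l5)]
    )
    probs = rescue_fraction(h, params.rescue)
    x = np.empty(spec.n)
    y = np.empty(spec.n)
    for i, rng in enumerate(rngs):
        x[i], y[i] = _realize(float(x_exp[i]), float(y_exp[i]), probs[i], params, spec.noise, rng)
    df = pd.DataFrame(
        {
            "id": [f"{spec.strain}-{spec.preset.name}-{i:05d}" for i in range(spec.n)],
            "strain": spec.strain,
            "rearing": spec.preset.name,
            "weight_mg": x,
            "ovariole_count": y,
        }
    )
    return PhenotypeTable(df)


def make_two_strain(
    spec_high: CohortSpec, spec_low: CohortSpec
) -> tuple[PhenotypeTable, PhenotypeTable]:
    """Simulate a two-strain design (e.g. high vs. low pollen hoarding).

    The two specs may differ in larval parameters (strain-specific JH
    response), in nurse presets (strain-specific L4 diet, including
    cross-fostering designs where one strain's larvae meet the other
    strain's nurse regime), in labels and in seeds.
    """
    return simulate_cohort(spec_high), simulate_cohort(spec_low)
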