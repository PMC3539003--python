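import numpy as np
import pytest

from beecaste import (
    CohortSpec,
    JHPhaseParams,
    ModelParams,
    NoiseModel,
    RescueParams,
    SizeParams,
    demo_params,
)


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return demo_params()


@pytest.fixture(scope="session")
def noise() -> NoiseModel:
    return NoiseModel()


def random_model_params(rng: np.random.Generator) -> ModelParams:
    """Draw a random valid parameter set for property sweeps."""
    def phase(n_weights: int) -> JHPhaseParams:
        h_w = rng.uniform(0.5, 1.5)
        w = rng.dirichlet(np.ones(n_weights))
        w = w / w.sum()
        # exact renormalisation to satisfy the sum-to-one constraint
        w[-1] = 1.0 - float(np.sum(w[:-1]))
        return JHPhaseParams(
            h_w=h_w,
            h_q=h_w + rng.uniform(0.5, 2.0),
            q_mid=rng.uniform(0.2, 0.8),
            s=rng.uniform(0.05, 0.3),
            weights=tuple(w),
        )

    r = rng.dirichlet(np.ones(3))
    r = r / r.sum()
    r[2] = 1.0 - float(r[0] + r[1])
    u_min = rng.uniform(20, 80)
    v_min = rng.uniform(5, 50)
    return ModelParams(
        jh_l3=phase(1),
        jh_l4=phase(2),
        jh_l5=phase(3),
        rescue=RescueParams(
            mu0=rng.uniform(1.4, 2.2),
            sigma0=rng.uniform(0.15, 0.6),
            r1=float(r[0]),
            r2=float(r[1]),
            r3=float(r[2]),
            y0=int(rng.integers(100, 220)),
        ),
        size=SizeParams(
            u_min=u_min,
            u_max=u_min + rng.uniform(100, 250),
            q2_mid=rng.uniform(0.3, 0.7),
            s_u=rng.uniform(0.08, 0.3),
            v_min=v_min,
            v_max=v_min + rng.uniform(60, 180),
            q3_mid=rng.uniform(0.3, 0.7),
            s_v=rng.uniform(0.08, 0.3),
            a0=rng.uniform(0.6, 1.0),
        ),
    )


def monte_carlo_ovarioles(
    h: tuple[float, float, float],
    rescue: RescueParams,
    n_draws: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Independent per-ovariole oracle for the expected rescued fraction.

    Simulates ``n_draws`` ovarioles: phase label ~ categorical(r1, r2, r3),
    threshold ~ normal(mu0, sigma0), rescue iff the phase titer exceeds
    the threshold.  Returns the implied mean ovariole count and its Monte
    Carlo standard error, both on the y0 scale.
    """
    phases = rng.choice(3, size=n_draws, p=list(rescue.r))
    thresholds = rng.normal(rescue.mu0, rescue.sigma0, size=n_draws)
    rescued = np.asarray(h)[phases] > thresholds
    frac = rescued.mean()
    se = np.sqrt(frac * (1 - frac) / n_draws)
    return rescue.y0 * frac, rescue.y0 * se


@pytest.fixture
def small_cohort(params, noise):
    return CohortSpec(n=50, preset=__import__("beecaste").WORKER_HIVE, params=params,
                      noise=noise, strain="w", seed=5)
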