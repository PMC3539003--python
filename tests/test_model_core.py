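import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from beecaste import (
    FeedingRegime,
    JHPhaseParams,
    JHProfile,
    ModelParams,
    Phenotype,
    RescueParams,
    SizeParams,
    adult_weight,
    critical_weight,
    develop,
    develop_arrays,
    growth_increment,
    jh_l3,
    jh_l4,
    jh_l5,
    load_params,
    ovariole_number,
    params_from_dict,
    params_to_dict,
    rescue_fraction,
    save_params,
)
from conftest import monte_carlo_ovarioles, random_model_params

LN9 = math.log(9.0)


class TestJHResponse:
    @pytest.mark.parametrize(
        "p, q1, expected",
        [
            # sigmoid midpoint symmetry
            (JHPhaseParams(1.0, 3.0, q_mid=0.4, s=0.1), 0.4, 2.0),
            # degenerate flat response
            (JHPhaseParams(2.0, 2.0, q_mid=0.5, s=0.1), 0.0, 2.0),
            (JHPhaseParams(2.0, 2.0, q_mid=0.5, s=0.1), 1.0, 2.0),
            # hand-evaluated logistic: 1/(1+e^{-ln 9}) = 0.9
            (JHPhaseParams(1.0, 3.0, q_mid=0.5, s=0.1), 0.5 + 0.1 * LN9, 2.8),
        ],
    )
    def test_l3_examples(self, p, q1, expected):
        assert jh_l3(q1, p) == pytest.approx(expected, abs=1e-12)

    def test_l4_weighted_mean_midpoint(self):
        p = JHPhaseParams(1.0, 3.0, q_mid=0.5, s=0.1, weights=(0.5, 0.5))
        assert jh_l4(0.25, 0.75, p) == pytest.approx(2.0, abs=1e-12)

    def test_l4_zero_carryover_ignores_q1(self):
        p = JHPhaseParams(1.0, 3.0, q_mid=0.5, s=0.1, weights=(0.0, 1.0))
        assert jh_l4(0.0, 0.3, p) == jh_l4(1.0, 0.3, p)

    def test_l4_fig2c_curve_ordering(self):
        # the q1 = 0.75 response lies at or above the q1 = 0.25 response
        p = JHPhaseParams(1.0, 3.0, q_mid=0.5, s=0.1, weights=(0.5, 0.5))
        q2 = np.linspace(0, 1, 21)
        assert np.all(jh_l4(0.75, q2, p) >= jh_l4(0.25, q2, p))

    def test_l5_equal_weights_matches_l3_at_mean(self):
        w = (1 / 3, 1 / 3, 1 - 2 / 3)
        p5 = JHPhaseParams(1.0, 3.0, q_mid=0.5, s=0.1, weights=w)
        p3 = JHPhaseParams(1.0, 3.0, q_mid=0.5, s=0.1)
        assert jh_l5(0.2, 0.5, 0.8, p5) == pytest.approx(jh_l3(0.5, p3), abs=1e-12)

    def test_out_of_range_diet_raises(self):
        p = JHPhaseParams(1.0, 3.0, q_mid=0.5, s=0.1)
        with pytest.raises(ValueError, match="1.5"):
            jh_l3(1.5, p)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        q=st.floats(0.0, 1.0),
        dq=st.floats(0.0, 0.5),
    )
    def test_bounds_and_monotonicity(self, seed, q, dq):
        rng = np.random.default_rng(seed)
        p = JHPhaseParams(
            h_w=rng.uniform(0, 2),
            h_q=rng.uniform(2, 4),
            q_mid=rng.uniform(0, 1),
            s=rng.uniform(0.02, 0.5),
        )
        lo, hi = jh_l3(q, p), jh_l3(min(q + dq, 1.0), p)
        assert p.h_w <= lo <= hi <= p.h_q

    def test_invalid_phase_params(self):
        with pytest.raises(ValueError):
            JHPhaseParams(3.0, 1.0, q_mid=0.5, s=0.1)  # h_q < h_w
        with pytest.raises(ValueError):
            JHPhaseParams(1.0, 3.0, q_mid=0.5, s=0.0)
        with pytest.raises(ValueError):
            JHPhaseParams(1.0, 3.0, q_mid=0.5, s=0.1, weights=(0.5, 0.4))


class TestRescue:
    rescue = RescueParams(mu0=2.0, sigma0=0.5, r1=0.2, r2=0.5, r3=0.3, y0=160)

    def test_half_at_mean_threshold(self):
        assert rescue_fraction(2.0, self.rescue) == pytest.approx(0.5, abs=1e-15)

    def test_matches_numerically_integrated_normal_density(self):
        # oracle: integrate the standard normal density directly
        for z in (-2.0, -0.5, 0.0, 1.959964, 3.0):
            h = self.rescue.mu0 + z * self.rescue.sigma0
            expected, _ = quad(lambda u: math.exp(-u * u / 2) / math.sqrt(2 * math.pi), -10, z)
            assert rescue_fraction(h, self.rescue) == pytest.approx(expected, abs=1e-9)

    def test_upper_tail_limit(self):
        assert rescue_fraction(1e6, self.rescue) == pytest.approx(1.0, abs=1e-12)

    def test_sigma0_must_be_positive(self):
        with pytest.raises(ValueError, match="sigma0"):
            RescueParams(mu0=2.0, sigma0=0.0, r1=0.2, r2=0.5, r3=0.3)

    def test_rescue_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="equal 1"):
            RescueParams(mu0=2.0, sigma0=0.5, r1=0.2, r2=0.5, r3=0.3 + 1e-9)

    def test_ovariole_number_midpoint(self):
        y = ovariole_number(JHProfile(2.0, 2.0, 2.0), self.rescue)
        assert y == pytest.approx(80.0, abs=1e-12)

    def test_single_phase_saturation(self):
        # all ovarioles available in L4 only and a huge L4 titer: all rescued
        rescue = RescueParams(mu0=2.0, sigma0=0.5, r1=0.0, r2=1.0, r3=0.0, y0=160)
        y = ovariole_number(JHProfile(0.0, 50.0, 0.0), rescue)
        assert y == pytest.approx(160.0, abs=1e-9)

    def test_monte_carlo_oracle_fixed_case(self):
        rng = np.random.default_rng(2024)
        h = (1.5, 2.5, 2.0)
        analytic = ovariole_number(JHProfile(*h), self.rescue)
        assert analytic == pytest.approx(96.384, abs=0.01)
        mc, se = monte_carlo_ovarioles(h, self.rescue, 10**6, rng)
        assert abs(analytic - mc) <= 3 * se

    def test_monte_carlo_oracle_random_sweep(self):
        rng = np.random.default_rng(11)
        for _ in range(4):
            p = random_model_params(rng)
            h = tuple(rng.uniform(p.rescue.mu0 - 1, p.rescue.mu0 + 1, size=3))
            analytic = ovariole_number(JHProfile(*h), p.rescue)
            mc, se = monte_carlo_ovarioles(h, p.rescue, 200_000, rng)
            assert abs(analytic - mc) <= 3 * se

    def test_step_function_limit(self):
        rescue = RescueParams(mu0=2.0, sigma0=1e-6, r1=0.2, r2=0.5, r3=0.3)
        for h, step in ((1.9, 0.0), (2.1, 1.0)):
            assert rescue_fraction(h, rescue) == pytest.approx(step, abs=1e-12)


class TestSize:
    size = SizeParams(
        u_min=40, u_max=200, q2_mid=0.5, s_u=0.1,
        v_min=10, v_max=150, q3_mid=0.5, s_v=0.1, a0=0.8,
    )

    @pytest.mark.parametrize(
        "func, q, expected",
        [
            (critical_weight, 0.5, 120.0),          # midpoint
            (critical_weight, 0.5 + 0.1 * LN9, 184.0),  # hand-evaluated
            (growth_increment, 0.5, 80.0),
            (growth_increment, 0.5 - 0.1 * LN9, 24.0),
        ],
    )
    def test_logistic_examples(self, func, q, expected):
        assert func(q, self.size) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_flat_responses(self):
        flat = SizeParams(100, 100, 0.5, 0.1, 30, 30, 0.5, 0.1, 1.0)
        for q in (0.0, 0.3, 1.0):
            assert critical_weight(q, flat) == 100.0
            assert growth_increment(q, flat) == 30.0

    @pytest.mark.parametrize(
        "a0, u, v, expected",
        [(1.0, 100, 50, 150.0), (0.8, 150, 100, 200.0), (0.8, 120, 0, 96.0)],
    )
    def test_adult_weight(self, a0, u, v, expected):
        size = SizeParams(40, 200, 0.5, 0.1, 10, 150, 0.5, 0.1, a0)
        assert adult_weight(u, v, size) == pytest.approx(expected)

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError, match="u"):
            adult_weight(-1.0, 10.0, self.size)
        with pytest.raises(ValueError, match="q2"):
            critical_weight(1.2, self.size)


class TestDevelop:
    def test_midpoint_composition(self, params):
        # demo parameters: all midpoints at 0.5 and mu0 equal to the JH midpoint
        ph = develop(FeedingRegime(0.5, 0.5, 0.5), params)
        size = params.size
        assert ph.x == pytest.approx(
            size.a0 * ((size.u_min + size.u_max) / 2 + (size.v_min + size.v_max) / 2)
        )
        assert ph.y == pytest.approx(params.rescue.y0 / 2)

    def test_queen_corner_saturation(self, params):
        ph = develop(FeedingRegime(1.0, 1.0, 1.0), params)
        size = params.size
        assert ph.x == pytest.approx(size.a0 * (size.u_max + size.v_max), rel=0.05)
        assert ph.y == pytest.approx(params.rescue.y0, rel=0.02)

    def test_weight_ignores_q1(self, params):
        x0, _ = develop_arrays(0.0, 0.5, 0.5, params)
        x1, _ = develop_arrays(1.0, 0.5, 0.5, params)
        assert float(x0) == float(x1)

    def test_componentwise_monotone_on_grid(self, params):
        g = np.linspace(0, 1, 9)
        q1, q2, q3 = np.meshgrid(g, g, g, indexing="ij")
        x, y = develop_arrays(q1.ravel(), q2.ravel(), q3.ravel(), params)
        for arr in (x.reshape(9, 9, 9), y.reshape(9, 9, 9)):
            for axis in range(3):
                assert np.all(np.diff(arr, axis=axis) >= -1e-9)

    def test_flat_jh_response_gives_constant_ovarioles(self, params):
        d = params_to_dict(params)
        for phase in ("l3", "l4", "l5"):
            d[f"{phase}.h_w"] = d[f"{phase}.h_q"] = 2.0
        flat = params_from_dict(d)
        _, y = develop_arrays(np.array([0.0, 0.3, 1.0]), np.array([0.1, 0.5, 0.9]),
                              np.array([0.9, 0.2, 0.4]), flat)
        assert np.allclose(y, y[0])

    def test_bounds_invariant(self, params):
        t = np.linspace(0, 1, 50)
        x, y = develop_arrays(t, t, t, params)
        assert np.all(x > 0)
        assert np.all((y > 0) & (y < params.rescue.y0))

    def test_phenotype_validation(self):
        with pytest.raises(ValueError):
            Phenotype(x=0.0, y=10)
        with pytest.raises(ValueError):
            Phenotype(x=100.0, y=-1)


class TestSerialization:
    def test_dict_roundtrip_exact(self, params):
        assert params_from_dict(params_to_dict(params)) == params

    def test_file_roundtrip_full_precision(self, tmp_path):
        rng = np.random.default_rng(7)
        p = random_model_params(rng)
        path = tmp_path / "params.txt"
        save_params(p, path)
        assert load_params(path) == p

    def test_missing_and_unknown_keys(self, params):
        d = params_to_dict(params)
        d.pop("rescue.mu0")
        with pytest.raises(KeyError, match="rescue.mu0"):
            params_from_dict(d)
        d2 = params_to_dict(params)
        d2["bogus.key"] = 1.0
        with pytest.raises(KeyError, match="bogus.key"):
            params_from_dict(d2)

    def test_malformed_file_reports_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("l3.h_w = 1.0\nl3.h_q == oops\n")
        with pytest.raises(ValueError, match=":2"):
            load_params(path)


def test_model_params_checks_weight_arity():
    phase1 = JHPhaseParams(1.0, 3.0, 0.5, 0.1)
    rescue = RescueParams(2.0, 0.5, 0.2, 0.5, 0.3)
    size = SizeParams(40, 200, 0.5, 0.1, 10, 150, 0.5, 0.1, 0.8)
    with pytest.raises(ValueError, match="jh_l4"):
        ModelParams(jh_l3=phase1, jh_l4=phase1, jh_l5=phase1, rescue=rescue, size=size)
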