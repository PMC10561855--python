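"""Soil physics, ten-pool decomposition, conservation and decay oracles."""

import math

import numpy as np
import pytest

from forestnep.core import SoilParams, SoilState
from forestnep.soil import (
    annual_rs,
    decomposition_step,
    litter_partition,
    potential_evapotranspiration,
    soil_temperature_step,
    temp_effect,
    water_balance_step,
    water_effect,
)

from _oracles import decomposition_oracle


def make_soil(pools, W_s=6.0, W_f=10.0, T_s=15.0, L_s=0.22):
    return SoilState(W_s=W_s, W_f=W_f, T_s=T_s, N_s=1e-3, N_pool=1.0,
                     C_u=np.asarray(pools, dtype=float), L_s=L_s)


class TestSoilTemperature:
    def test_constant_input_fixed_point(self):
        t = 0.0
        for _ in range(5 * 15):
            t = soil_temperature_step(t, 10.0, tau=15.0)
        assert t == pytest.approx(10.0, rel=0.01)

    def test_zero_time_constant_tracks_air(self):
        assert soil_temperature_step(3.0, 21.5, tau=0.0) == 21.5

    def test_step_response_matches_first_order_closed_form(self):
        tau = 15.0
        t = 0.0
        for n in range(1, 61):
            t = soil_temperature_step(t, 10.0, tau=tau)
            assert t == pytest.approx(10.0 * (1 - math.exp(-n / tau)), abs=1e-6)


class TestWaterBalance:
    def test_no_flux_no_change(self):
        assert water_balance_step(5.0, 10.0, 0.0, 0.0) == 5.0

    def test_deluge_saturates_at_field_capacity(self):
        assert water_balance_step(5.0, 10.0, 500.0, 0.0) == 10.0

    def test_rain_offsets_demand(self):
        # 5 cm + 10 mm rain - (2 * 5/10) cm demand = 5 cm
        assert water_balance_step(5.0, 10.0, 10.0, 2.0) == pytest.approx(5.0)

    def test_rejects_negative_rain(self):
        with pytest.raises(ValueError):
            water_balance_step(5.0, 10.0, -1.0, 0.0)

    def test_pet_positive_above_freezing_and_daylength_scaled(self):
        assert potential_evapotranspiration(-5.0, 12.0) == 0.0
        assert potential_evapotranspiration(20.0, 12.0) > potential_evapotranspiration(20.0, 6.0) > 0


class TestDecompositionMultipliers:
    def test_temp_effect_unity_at_40(self):
        assert temp_effect(40.0) == pytest.approx(1.0, abs=1e-15)

    def test_temp_effect_at_20(self):
        expected = math.exp(3.36 * (20.0 - 40.0) / (20.0 + 31.79))
        assert temp_effect(20.0) == pytest.approx(expected, rel=1e-12)
        assert temp_effect(20.0) == pytest.approx(0.2732, abs=5e-4)

    def test_temp_effect_strictly_increasing(self):
        temps = np.linspace(-20.0, 45.0, 80)
        vals = [temp_effect(t) for t in temps]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_temp_effect_pole_rejected(self):
        with pytest.raises(ValueError):
            temp_effect(-31.79)

    def test_water_effect_optimum_at_point_six_of_capacity(self):
        assert water_effect(6.0, 10.0) == pytest.approx(1.0, abs=1e-15)

    def test_water_effect_dry_soil_zero(self):
        assert water_effect(0.0, 10.0) == 0.0

    def test_water_effect_saturated(self):
        # 1 - (1/0.6 - 1)^2 = 1 - (2/3)^2 = 5/9
        assert water_effect(10.0, 10.0) == pytest.approx(5.0 / 9.0, rel=1e-12)


class TestDecompositionStep:
    def test_empty_soil_respires_nothing(self):
        soil = make_soil(np.zeros(10))
        pools, rs, n = decomposition_step(soil, SoilParams(), 1.0, 1.0)
        assert rs == 0.0 and n == 0.0 and np.all(pools == 0.0)

    def test_single_active_pool_fully_respired(self):
        """Active SOM with P=1 and no transfers loses S_8 = 0.042 of itself."""
        params = SoilParams(P_u=np.ones(10), transfer_matrix=np.zeros((10, 10)))
        pools = np.zeros(10)
        pools[7] = 1.0
        soil = make_soil(pools)
        new, rs, _ = decomposition_step(soil, params, 1.0, 1.0)
        assert rs == pytest.approx(0.042, rel=1e-12)
        assert new[7] == pytest.approx(1.0 - 0.042, rel=1e-12)

    def test_mass_conservation_per_step(self, rng):
        params = SoilParams()
        for _ in range(50):
            soil = make_soil(rng.uniform(0.0, 5.0, size=10))
            before = soil.C_u.sum()
            new, rs, _ = decomposition_step(soil, params, rng.uniform(0, 2),
                                            rng.uniform(0, 1))
            assert before - new.sum() - rs == pytest.approx(0.0, abs=1e-12 * max(before, 1))

    def test_matches_scalar_oracle_on_random_draws(self, rng):
        """1,000 random states within 1e-9 relative of the loop oracle."""
        params = SoilParams()
        T = params.transfer_matrix
        for _ in range(1000):
            C = rng.uniform(0.0, 10.0, size=10)
            G_t, G_w = rng.uniform(0, 2), rng.uniform(0, 1)
            L_s = rng.uniform(0.0, 0.5)
            soil = make_soil(C, L_s=L_s)
            new, rs, mn = decomposition_step(soil, params, G_t, G_w)
            o_new, o_rs, o_mn = decomposition_oracle(
                C.tolist(), params.S_u.tolist(), params.P_u.tolist(),
                T.tolist(), G_t, G_w, params.b, L_s, {1, 3},
                params.CN_u.tolist(),
            )
            np.testing.assert_allclose(new, o_new, rtol=1e-9, atol=1e-15)
            assert rs == pytest.approx(o_rs, rel=1e-9, abs=1e-15)
            assert mn == pytest.approx(o_mn, rel=1e-9, abs=1e-18)

    def test_one_pool_decay_matches_exponential_closed_form(self):
        """Daily stepping tracks C0 e^(-rt) within 1% over ten half-lives."""
        params = SoilParams(P_u=np.ones(10), transfer_matrix=np.zeros((10, 10)))
        r = params.S_u[8]          # slow pool, 0.001 d^-1
        n_days = int(10 * math.log(2) / r)
        pools = np.zeros(10)
        pools[8] = 1.0
        soil = make_soil(pools)
        for _ in range(n_days):
            soil.C_u, _, _ = decomposition_step(soil, params, 1.0, 1.0)
        assert soil.C_u[8] == pytest.approx(math.exp(-r * n_days), rel=0.01)

    def test_converges_to_analytic_steady_state(self):
        """Constant inputs drive each pool to inflow/(S_u G_t G_w shield_u)."""
        params = SoilParams()
        G_t, G_w = 0.5, 0.8
        inputs = litter_partition(leaf=0.002, fineroot=0.001, branch=0.0005,
                                  stem=0.0003, coarseroot=0.0002)
        # analytic fixed point: outflow x solves x = inputs + T^T x
        x = np.linalg.solve(np.eye(10) - params.transfer_matrix.T, inputs)
        shield = np.ones(10)
        shield[[1, 3]] = math.exp(-params.b * 0.22)
        expected = x / (params.S_u * G_t * G_w * shield)
        soil = make_soil(expected.copy())
        # fixed point: one step plus inputs leaves the state unchanged
        new, _, _ = decomposition_step(soil, params, G_t, G_w)
        np.testing.assert_allclose(new + inputs, expected, rtol=1e-10)
        # and the dynamics approach it monotonically from below (fast pools)
        fast = SoilParams(S_u=np.full(10, 0.02), P_u=params.P_u,
                          transfer_matrix=params.transfer_matrix)
        xf = np.linalg.solve(np.eye(10) - fast.transfer_matrix.T, inputs)
        shield_f = np.ones(10)
        shield_f[[1, 3]] = math.exp(-fast.b * 0.22)
        target = xf / (fast.S_u * G_t * G_w * shield_f)
        soil = make_soil(0.1 * target)
        prev_dist = np.inf
        for day in range(4000):
            soil.C_u, _, _ = decomposition_step(soil, fast, G_t, G_w)
            soil.C_u = soil.C_u + inputs
        np.testing.assert_allclose(soil.C_u, target, rtol=1e-3)


class TestAnnualRs:
    def test_zero_year(self):
        assert annual_rs([0.0] * 365) == 0.0

    def test_constant_rate(self):
        assert annual_rs([0.001] * 365) == pytest.approx(0.365, rel=1e-12)

    def test_rejects_partial_year(self):
        with pytest.raises(ValueError):
            annual_rs([0.001] * 100)


class TestLitterPartition:
    def test_zero_in_zero_out(self):
        assert np.all(litter_partition() == 0.0)

    def test_leaf_split_by_metabolic_fraction(self):
        adds = litter_partition(leaf=1.0, metabolic_frac=0.6)
        assert adds[0] == pytest.approx(0.6)
        assert adds[1] == pytest.approx(0.4)

    def test_woody_routing(self):
        adds = litter_partition(branch=0.3, stem=0.5, coarseroot=0.2)
        assert adds[4] == 0.3 and adds[5] == 0.5 and adds[6] == 0.2

    def test_total_conserved(self, rng):
        for _ in range(20):
            masses = rng.uniform(0, 2, size=6)
            adds = litter_partition(*masses, metabolic_frac=rng.uniform(0, 1))
            assert adds.sum() == pytest.approx(masses.sum(), rel=1e-12)
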