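"""Orchestration: determinism, mass balance, aggregation, evaluation."""

import copy
import datetime

import numpy as np
import pandas as pd
import pytest

from forestnep.core import ForestType
from forestnep.forcing import archetype_for, synth_grid, synth_weather
from forestnep.simulation import (
    aggregate_regional,
    contributions,
    evaluate_monthly,
    round_half_up,
    run,
    run_cell_year,
    spinup,
)

from conftest import make_day


def small_grid(seed=7, n_cells=2, n_trees=12):
    mix = {ForestType.ECF: 0.5, ForestType.EBF: 0.5}
    return synth_grid(n_cells, mix, seed, n_trees=n_trees)


def grid_forcing(cells, years, seed=99):
    streams = np.random.SeedSequence(seed).spawn(len(cells))
    return {c.id: synth_weather(archetype_for(c.forest_type), years, ss)
            for c, ss in zip(cells, streams)}


class TestRun:
    def test_identical_cells_identical_outputs(self):
        cells_a = small_grid()
        cells_b = small_grid()
        forcing = grid_forcing(cells_a, 1)
        res_a = run(cells_a, forcing)
        res_b = run(cells_b, forcing)
        for cid in forcing:
            ra, rb = res_a[cid][0].record, res_b[cid][0].record
            assert (ra.GPP, ra.NPP, ra.R_s, ra.NEP) == (rb.GPP, rb.NPP, rb.R_s, rb.NEP)

    def test_dark_world_is_a_pure_source(self):
        [cell] = synth_grid(1, {ForestType.EBF: 1.0}, 5, n_trees=8)
        start = datetime.date(2001, 1, 1)
        dark = [make_day(date=start + datetime.timedelta(days=i), D=0.0, PAR_noon=0.0)
                for i in range(365)]
        res = run([cell], {cell.id: dark})
        rec = res[cell.id][0].record
        assert rec.GPP == 0.0
        assert rec.NEP == pytest.approx(rec.NPP - rec.R_s)
        assert rec.NEP < 0.0 and rec.R_s > 0.0

    def test_cumulative_nep_closes_the_carbon_books(self):
        cells = small_grid(n_cells=2)
        forcing = grid_forcing(cells, 2)
        before = {c.id: c.ecosystem_carbon for c in cells}
        res = run(cells, forcing)
        for c in cells:
            cum_nep = sum(r.record.NEP for r in res[c.id])
            delta = c.ecosystem_carbon - before[c.id]
            assert cum_nep == pytest.approx(delta, rel=1e-6, abs=1e-9)

    def test_missing_forcing_is_fatal(self):
        cells = small_grid()
        with pytest.raises(KeyError):
            run(cells, {})

    def test_partial_year_is_fatal(self):
        cells = small_grid()
        forcing = {cid: days[:100] for cid, days in grid_forcing(cells, 1).items()}
        with pytest.raises(ValueError):
            run(cells, forcing)


class TestSpinup:
    def test_equilibrated_cell_converges_immediately(self, constant_year):
        [cell] = synth_grid(1, {ForestType.EBF: 1.0}, 5, n_trees=8)
        spinup(cell, constant_year, tol=1e-4, max_cycles=300)
        assert cell.spinup_converged
        # a second spin-up from the equilibrated state is a no-op
        _, cycles = spinup(cell, constant_year, tol=1e-4, max_cycles=50)
        assert cycles == 1

    def test_tighter_tolerance_never_needs_fewer_cycles(self, constant_year):
        cycles = {}
        for tol in (1e-2, 1e-3):
            [cell] = synth_grid(1, {ForestType.EBF: 1.0}, 5, n_trees=8)
            _, cycles[tol] = spinup(cell, constant_year, tol=tol, max_cycles=300)
        assert cycles[1e-3] >= cycles[1e-2]

    def test_deciduous_stand_survives_cold_climate_spinup(self):
        """A deciduous-conifer stand keeps a viable canopy through the
        seasonal cycle: spring flush rebuilds leaves after the autumn
        shed, so the spun-up stand photosynthesizes and converges."""
        [cell] = synth_grid(1, {ForestType.DCF: 1.0}, 21, n_trees=10)
        year = synth_weather(archetype_for(ForestType.DCF), 1, 22)
        spinup(cell, year, tol=1e-4, max_cycles=150)
        assert cell.spinup_converged
        assert cell.lai > 0.5
        res = run([cell], {cell.id: synth_weather(
            archetype_for(ForestType.DCF), 1, 23)})
        assert res[cell.id][0].record.GPP > 0.1

    def test_rejects_partial_forcing_year(self, constant_year):
        [cell] = synth_grid(1, {ForestType.ECF: 1.0}, 5, n_trees=8)
        with pytest.raises(ValueError):
            spinup(cell, constant_year[:300])


class TestAggregation:
    def test_unit_arithmetic_single_cell(self):
        [cell] = synth_grid(1, {ForestType.ECF: 1.0}, 5, n_trees=8)
        cell.coverage = 1.0
        # 100 gC m^-2 a^-1 over 10 km x 10 km = 1e10 g = 0.01 Tg
        summary = aggregate_regional({cell.id: 100.0}, [cell])
        assert summary.per_type_nep[ForestType.ECF] == pytest.approx(0.01, rel=1e-12)
        assert summary.national_total == pytest.approx(1e-5, rel=1e-12)

    def test_zero_coverage_contributes_nothing(self):
        [cell] = synth_grid(1, {ForestType.RF: 1.0}, 5, n_trees=8)
        cell.coverage = 0.0
        summary = aggregate_regional({cell.id: 500.0}, [cell])
        assert summary.per_type_nep[ForestType.RF] == 0.0

    def test_grouped_sums_equal_per_cell_accumulation(self, rng):
        mix = {t: 1.0 / 8.0 for t in ForestType}
        cells = synth_grid(8, mix, 6, n_trees=8)
        nep = {c.id: float(rng.uniform(-100, 400)) for c in cells}
        summary = aggregate_regional(nep, cells)
        brute = {t: 0.0 for t in ForestType}
        for c in cells:
            brute[c.forest_type] += nep[c.id] * c.area * c.coverage * 1e-12
        for t in ForestType:
            assert summary.per_type_nep[t] == pytest.approx(brute[t], rel=1e-12)


class TestContributions:
    def test_single_nonzero_type_takes_all(self):
        totals = {t: 0.0 for t in ForestType}
        totals[ForestType.DBF] = 12.3
        pct = contributions(totals)
        assert pct[ForestType.DBF] == pytest.approx(100.0)

    def test_percentages_always_sum_to_hundred(self, rng):
        for _ in range(20):
            totals = {t: float(rng.uniform(-50, 100)) for t in ForestType}
            if abs(sum(totals.values())) < 1e-6:
                continue
            assert sum(contributions(totals).values()) == pytest.approx(100.0, abs=1e-9)

    def test_invariant_under_uniform_rescaling(self):
        totals = {t: float(i - 2) for i, t in enumerate(ForestType)}
        a = contributions(totals)
        b = contributions({t: 3.7 * v for t, v in totals.items()})
        for t in ForestType:
            assert a[t] == pytest.approx(b[t], rel=1e-12)

    def test_zero_net_total_raises(self):
        totals = {t: 0.0 for t in ForestType}
        with pytest.raises(ZeroDivisionError):
            contributions(totals)

    def test_reporting_rounds_half_up(self):
        assert round_half_up(34.445) == 34.45
        assert round_half_up(2.225) == 2.23
        assert round_half_up(-4.765) == -4.77


class TestEvaluateMonthly:
    @staticmethod
    def _daily(year=2003, level=0.002, seasonal=0.003):
        idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        doy = idx.dayofyear.to_numpy()
        vals = level + seasonal * np.sin(2 * np.pi * (doy - 90) / 365.0)
        return pd.Series(vals, index=idx)

    def test_perfect_agreement(self):
        sim = self._daily()
        obs_nee = -sim.resample("MS").sum()       # NEE sign convention
        m = evaluate_monthly(sim, obs_nee)
        assert m["bias"] == pytest.approx(0.0, abs=1e-15)
        assert m["rmse"] == pytest.approx(0.0, abs=1e-15)
        assert m["pearson_r"] == pytest.approx(1.0)
        assert m["n_months"] == 12

    def test_constant_offset_shifts_bias_only(self):
        sim = self._daily()
        obs_nep = sim.resample("MS").sum() - 0.05
        m = evaluate_monthly(sim, -obs_nep)
        assert m["bias"] == pytest.approx(0.05, rel=1e-9)
        assert m["pearson_r"] == pytest.approx(1.0)

    def test_matches_hand_computation(self, rng):
        sim = self._daily()
        monthly = sim.resample("MS").sum()
        noise = rng.normal(0, 0.01, size=12)
        obs_nep = monthly + noise
        m = evaluate_monthly(sim, -obs_nep)
        diff = monthly.to_numpy() - obs_nep.to_numpy()
        assert m["bias"] == pytest.approx(diff.mean(), rel=1e-9)
        assert m["rmse"] == pytest.approx(np.sqrt((diff**2).mean()), rel=1e-9)
        sx, sy = monthly.to_numpy(), obs_nep.to_numpy()
        r_hand = (((sx - sx.mean()) * (sy - sy.mean())).sum()
                  / np.sqrt(((sx - sx.mean())**2).sum() * ((sy - sy.mean())**2).sum()))
        assert m["pearson_r"] == pytest.approx(r_hand, rel=1e-9)

    def test_insufficient_overlap_is_fatal(self):
        sim = self._daily()
        obs = sim.resample("MS").sum().iloc[:2]
        with pytest.raises(ValueError):
            evaluate_monthly(sim, -obs)
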