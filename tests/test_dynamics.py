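"""Foraging-arena consumption, calibration and the integrator."""

import numpy as np
import pytest

from shelfweb.balance import BalanceError
from shelfweb.dynamics import (
    apply_effort,
    calibrate,
    consumption_matrix,
    consumption_rate,
    derivative_at_baseline,
    simulate,
)
from shelfweb.scenarios import ForcingSet, PiecewiseLinear, build_scenario
from shelfweb.synth import new_alien_k_overrides

import pandas as pd


def constant_forcing(model, start=2010.0, horizon=60.0, effort=1.0, sst=26.0):
    years = np.arange(start, start + horizon + 1)
    return ForcingSet(
        start_year=start,
        horizon=horizon,
        effort={
            f.name: PiecewiseLinear([start, start + horizon], [effort, effort])
            for f in model.fleets
        },
        sst=pd.Series(sst, index=years),
    )


class TestConsumptionRate:
    def test_direct_evaluation(self):
        # numerator a*v*B*P = 2, denominator v + v + a*P = 5
        assert consumption_rate(a=1, v=2, prey_biomass=1, predator_abundance=1) == pytest.approx(
            0.4, abs=1e-15
        )

    def test_zero_annihilators(self):
        assert consumption_rate(1, 2, 0.0, 1.0) == 0.0
        assert consumption_rate(1, 2, 1.0, 0.0) == 0.0
        assert consumption_rate(1, 2, 1.0, 1.0, f=0.0) == 0.0

    def test_linear_in_environmental_multiplier(self):
        q1 = consumption_rate(1, 2, 1, 1, f=0.3)
        q2 = consumption_rate(1, 2, 1, 1, f=0.6)
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    def test_strictly_increasing_in_biomass_and_abundance(self):
        base = consumption_rate(1.5, 3.0, 1.0, 1.0)
        assert consumption_rate(1.5, 3.0, 2.0, 1.0) > base
        assert consumption_rate(1.5, 3.0, 1.0, 2.0) > base

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            consumption_rate(1, 2, -1.0, 1.0)

    def test_donor_control_bound(self):
        # consumption never exceeds the vulnerable-pool exchange limit v*B*Ti
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, v, b, p = rng.uniform(0.01, 50, size=4)
            q = consumption_rate(a, v, b, p)
            assert q < v * b + 1e-12


class TestCalibration:
    def test_baseline_flows_reproduced(self, calibrated):
        model, params, dyn = calibrated
        q = consumption_matrix(params, dyn.b0, np.ones(model.n))
        link = params.link
        assert np.max(np.abs(q[link] - params.q0[link]) / params.q0[link]) < 1e-10

    def test_mass_action_limit_at_huge_k(self, synthetic_web):
        model, _, _ = synthetic_web
        params, dyn = calibrate(model, k_overrides=None)
        big, _ = calibrate(model, k_overrides={g.name: 1e6 for g in model.groups
                                               if g.category == "consumer"})
        i, j = map(int, np.argwhere(big.link)[0])
        b0_i, b0_j, q0 = dyn.b0[i], dyn.b0[j], big.q0[i, j]
        # flow behaves as mass action: Q ~= Q0 * (B/B0) * (P/P0)
        for sb, sp in [(2.0, 1.0), (1.0, 3.0), (0.5, 0.5)]:
            q = consumption_rate(big.a[i, j], big.v[i, j], sb * b0_i, sp * b0_j)
            assert q == pytest.approx(q0 * sb * sp, rel=1e-4)
        # and the search rate approaches twice the mass-action coefficient,
        # the factor the baseline denominator (2v) absorbs
        assert big.a[i, j] == pytest.approx(2 * q0 / (b0_i * b0_j), rel=1e-5)

    def test_new_alien_override_carries_k(self, synthetic_web):
        model, _, _ = synthetic_web
        params, _ = calibrate(model, k_overrides=new_alien_k_overrides(model))
        for j, g in enumerate(model.groups):
            expected = 10.0 if "new_alien" in g.role_tags else 2.0
            col = params.k[params.link[:, j], j]
            assert np.allclose(col, expected)

    def test_k_at_most_one_rejected(self, synthetic_web):
        model, _, _ = synthetic_web
        pred = next(g.name for g in model.groups if g.category == "consumer")
        with pytest.raises(BalanceError, match="vulnerable pool"):
            calibrate(model, k_overrides={pred: 1.0})

    def test_equilibrium_derivative_is_zero(self, calibrated):
        model, params, dyn = calibrated
        assert np.max(np.abs(derivative_at_baseline(model, params, dyn))) < 1e-9


class TestSimulate:
    def test_baseline_equilibrium_drift(self, calibrated):
        model, params, dyn = calibrated
        res = simulate(model, params, dyn, constant_forcing(model), years=10)
        drift = np.abs(res.biomass[:, -1] - res.biomass[:, 0]) / res.biomass[:, 0]
        assert drift.max() < 0.01

    def test_mass_sanity_production_term(self, calibrated):
        # predation inflow times net growth efficiency is the production term
        model, params, dyn = calibrated
        rng = np.random.default_rng(3)
        for _ in range(5):
            b = dyn.b0 * rng.uniform(0.5, 2.0, size=model.n)
            q = consumption_matrix(params, b, np.ones(model.n))
            intake = q.sum(axis=0) + dyn.qb0 * dyn.import_fraction * b
            for j in np.where(model.consumers())[0]:
                assert dyn.net_growth_efficiency[j] * intake[j] == pytest.approx(
                    (dyn.pb0[j] / dyn.qb0[j]) * intake[j]
                )

    def test_biomass_forcing_bypasses_dynamics(self, calibrated, baseline_forcings):
        model, params, dyn = calibrated
        forced_group = model.names[model.n - 1]
        forcing = constant_forcing(model, horizon=5)
        target = 2.0 * dyn.b0[model.index(forced_group)]
        forcing.biomass_forcing[forced_group] = pd.Series(
            target, index=np.arange(2010.0, 2016.0)
        )
        res = simulate(model, params, dyn, forcing, years=5)
        assert np.allclose(res.biomass[model.index(forced_group), :], target)

    def test_zero_effort_releases_exploited_groups(self, calibrated):
        model, params, dyn = calibrated
        res = simulate(model, params, dyn, constant_forcing(model, effort=0.0), years=3)
        assert res.catch.sum() == 0.0
        exploited = dyn.catchability.sum(axis=1) > 0
        # released fishing mortality raises the exploited community as a
        # whole and the most heavily fished group in particular (individual
        # prey of recovering predators may still dip)
        assert res.biomass[exploited, 1].sum() > dyn.b0[exploited].sum()
        hardest = int(np.argmax(dyn.catchability.sum(axis=1)))
        assert res.biomass[hardest, 1] > dyn.b0[hardest]

    def test_halving_dt_changes_little(self, calibrated, baseline_forcings):
        model, params, dyn = calibrated
        forcing = build_scenario(7, baseline_forcings, horizon=10)
        coarse = simulate(model, params, dyn, forcing, years=10, dt=1 / 12)
        fine = simulate(model, params, dyn, forcing, years=10, dt=1 / 24)
        rel = np.abs(fine.biomass - coarse.biomass) / np.maximum(fine.biomass, 1e-12)
        assert rel.max() < 1e-3

    def test_annual_outputs_have_expected_shape(self, calibrated):
        model, params, dyn = calibrated
        res = simulate(model, params, dyn, constant_forcing(model), years=4)
        assert res.biomass.shape == (model.n, 5)
        assert res.catch.shape == (model.n, len(model.fleets), 4)
        assert len(res.flows) == 5
        assert np.all(np.diff(res.years) > 0)
        assert np.all(res.catch >= 0)


class TestApplyEffort:
    def test_constant_policy(self, calibrated):
        model, _, _ = calibrated
        forcing = constant_forcing(model)
        fleet = model.fleets[0].name
        assert apply_effort(forcing, fleet, 2030.5) == 1.0

    def test_linear_ramp_midpoint(self):
        forcing = ForcingSet(
            start_year=2010,
            horizon=10,
            effort={"trawl": PiecewiseLinear([2010, 2013, 2020], [1.0, 0.5, 0.5])},
            sst=pd.Series(26.0, index=np.arange(2010, 2021)),
        )
        assert apply_effort(forcing, "trawl", 2011.5) == pytest.approx(0.75)

    def test_step_is_right_continuous(self):
        forcing = ForcingSet(
            start_year=2010,
            horizon=10,
            effort={"t": PiecewiseLinear([2010, 2015, 2015, 2020], [1.0, 1.0, 0.4, 0.4])},
            sst=pd.Series(26.0, index=np.arange(2010, 2021)),
        )
        assert apply_effort(forcing, "t", 2015.0) == 0.4
        assert apply_effort(forcing, "t", 2014.999) == pytest.approx(1.0, abs=1e-2)

    def test_outside_horizon_is_an_error(self, calibrated):
        model, _, _ = calibrated
        forcing = constant_forcing(model, horizon=10)
        with pytest.raises(ValueError, match="outside"):
            apply_effort(forcing, model.fleets[0].name, 2090.0)
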