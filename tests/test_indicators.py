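"""Indicator suite: biomass aggregates, Kempton's Q, catch and flow metrics."""

import numpy as np
import pytest

from shelfweb.balance import compute_trophic_levels
from shelfweb.dynamics import simulate
from shelfweb.indicators import (
    FlowSnapshot,
    baseline_flow_snapshot,
    biomass_indicators,
    catch_indicators,
    flow_indicators,
    indicator_series,
    kemptons_q,
    mean_tl_community,
)

from conftest import make_model
from test_dynamics import constant_forcing


class TestBiomassIndicators:
    def test_detritus_excluded_from_total(self):
        m = make_model(
            [
                ("algae", "producer", 10.0, 10.0, 0.0, 0.0),
                ("detritus", "detritus", 5.0, 0.0, 0.0, 0.0),
            ],
            {},
        )
        totalb, forf, invb, predb = biomass_indicators(
            m.array("biomass"), m, np.array([1.0, 1.0])
        )
        assert totalb == 10.0
        assert forf == invb == predb == 0.0

    def test_tag_filtered_sums(self):
        m = make_model(
            [
                ("algae", "producer", 10.0, 10.0, 0.0, 0.0),
                ("detritus", "detritus", 5.0, 0.0, 0.0, 0.0),
                ("sardine", "consumer", 2.0, 1.5, 8.0, 0.2, {"forage"}),
                ("crab", "consumer", 0.5, 2.0, 9.0, 0.3, {"benthic_invertebrate"}),
            ],
            {"sardine": {"algae": 1.0}, "crab": {"detritus": 1.0}},
        )
        tls = np.array([1.0, 1.0, 2.0, 2.0])
        _, forf, invb, predb = biomass_indicators(m.array("biomass"), m, tls)
        assert forf == 2.0
        assert invb == 0.5
        assert predb == 0.0  # no TL >= 4 group

    def test_synthetic_predatory_biomass_counts_high_tl(self, synthetic_web):
        model, _, _ = synthetic_web
        tls = compute_trophic_levels(model)
        b = model.array("biomass")
        totalb, _, _, predb = biomass_indicators(b, model, tls)
        assert predb == pytest.approx(b[(tls >= 4) & model.living()].sum())
        assert 0 < predb < totalb


class TestKemptonsQ:
    def test_hand_evaluated_quartiles(self):
        # 4 groups at TL>=3, ranked biomasses 1,2,4,8: quartile ranks 1 and 3
        b = np.array([1.0, 2.0, 4.0, 8.0])
        tls = np.full(4, 3.5)
        expected = 0.5 * 4 / np.log10(4.0 / 1.0)
        assert kemptons_q(b, tls) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance(self):
        b = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        tls = np.full(5, 4.0)
        assert kemptons_q(10 * b, tls) == pytest.approx(kemptons_q(b, tls), rel=1e-12)

    def test_low_tl_groups_ignored(self):
        b = np.array([1.0, 2.0, 4.0, 8.0])
        tls = np.full(4, 3.5)
        b2 = np.append(b, 100.0)
        tls2 = np.append(tls, 2.0)
        assert kemptons_q(b2, tls2) == kemptons_q(b, tls)

    def test_degenerate_cases_return_missing(self):
        assert np.isnan(kemptons_q(np.array([1.0, 2, 4]), np.full(3, 4.0)))
        assert np.isnan(kemptons_q(np.full(5, 2.0), np.full(5, 4.0)))


class TestCatchIndicators:
    @pytest.mark.parametrize(
        "catch, tls, expected_tl",
        [
            ([1.0], [3.0], 3.0),  # single group
            ([1.0, 1.0], [2.0, 4.0], 3.0),  # symmetric mix
            ([1.0, 0.5], [2.5, 4.0], 3.0),  # (2.5 + 2.0) / 1.5
        ],
    )
    def test_weighted_mean_tl(self, catch, tls, expected_tl):
        total, mtlc = catch_indicators(np.array(catch), np.array(tls))
        assert total == pytest.approx(sum(catch))
        assert mtlc == pytest.approx(expected_tl)

    def test_zero_catch_undefined_tl(self):
        total, mtlc = catch_indicators(np.zeros(3), np.ones(3))
        assert total == 0.0
        assert np.isnan(mtlc)


class TestMeanTlCommunity:
    def test_direct_arithmetic(self):
        m = make_model(
            [
                ("algae", "producer", 10.0, 10.0, 0.0, 0.0),
                ("detritus", "detritus", 99.0, 0.0, 0.0, 0.0),
                ("herb", "consumer", 2.0, 2.0, 10.0, 0.2),
                ("carn", "consumer", 0.5, 1.0, 4.0, 0.2),
            ],
            {"herb": {"algae": 1.0}, "carn": {"herb": 1.0}},
        )
        tls = np.array([1.0, 1.0, 2.0, 3.0])
        out = mean_tl_community(m.array("biomass"), m, tls)
        assert out == pytest.approx(15.5 / 12.5)

    def test_shifting_biomass_upward_raises_it(self):
        m = make_model(
            [
                ("algae", "producer", 10.0, 10.0, 0.0, 0.0),
                ("detritus", "detritus", 5.0, 0.0, 0.0, 0.0),
                ("herb", "consumer", 2.0, 2.0, 10.0, 0.2),
                ("carn", "consumer", 0.5, 1.0, 4.0, 0.2),
            ],
            {"herb": {"algae": 1.0}, "carn": {"herb": 1.0}},
        )
        tls = np.array([1.0, 1.0, 2.0, 3.0])
        lo = mean_tl_community(np.array([10, 5, 2, 0.5]), m, tls)
        hi = mean_tl_community(np.array([10, 5, 2, 2.0]), m, tls)
        assert hi > lo


def loop_snapshot(recycle=3.0):
    """3-compartment web with one detritus loop: producer -> consumer ->
    detritus -> consumer."""
    q = np.zeros((3, 3))
    q[0, 1] = 10.0  # producer eaten by consumer
    q[2, 1] = recycle  # detritivory closes the loop
    flows_to_det = np.array([0.0, 4.0, 0.0])
    respiration = np.array([0.0, 6.0, 0.0])
    exports = np.array([2.0, 3.0, 1.0])
    imports = np.array([12.0, 0.0, 0.0])  # producer gross production
    return FlowSnapshot(
        q=q,
        respiration=respiration,
        flows_to_detritus=flows_to_det,
        exports=exports,
        imports=imports,
        detritus=np.array([False, False, True]),
    )


class TestFlowIndicators:
    def test_acyclic_chain_has_no_cycling(self):
        q = np.zeros((3, 3))
        q[0, 1] = 8.0
        q[1, 2] = 3.0
        snap = FlowSnapshot(
            q=q,
            respiration=np.array([0.0, 3.0, 1.0]),
            flows_to_detritus=np.zeros(3),
            exports=np.array([2.0, 2.0, 2.0]),
            imports=np.array([10.0, 0.0, 0.0]),
            detritus=np.zeros(3, dtype=bool),
        )
        tst, fci, pl = flow_indicators(snap)
        assert fci == pytest.approx(0.0, abs=1e-12)
        assert tst == pytest.approx(q.sum() + 6.0 + 4.0)

    def test_loop_matches_geometric_series_oracle(self):
        snap = loop_snapshot()
        tst, fci, _ = flow_indicators(snap)
        # independent oracle: cycled flow from summing powers of G
        f = snap.internal_flows()
        throughput = f.sum(axis=0) + snap.imports
        g = f / throughput[None, :]
        series = np.eye(3)
        power = np.eye(3)
        for _ in range(2000):
            power = power @ g
            series += power
            if np.abs(power).max() < 1e-14:
                break
        diag = np.diag(series)
        cycled = float((throughput * (diag - 1) / diag).sum())
        assert fci == pytest.approx(100 * cycled / tst, abs=1e-10)
        assert fci > 0

    def test_fci_invariant_to_uniform_rescaling(self):
        snap1 = loop_snapshot()
        snap2 = FlowSnapshot(
            q=2 * snap1.q,
            respiration=2 * snap1.respiration,
            flows_to_detritus=2 * snap1.flows_to_detritus,
            exports=2 * snap1.exports,
            imports=2 * snap1.imports,
            detritus=snap1.detritus,
        )
        assert flow_indicators(snap2)[1] == pytest.approx(flow_indicators(snap1)[1])

    def test_fci_increases_with_recycling_flow(self):
        assert flow_indicators(loop_snapshot(4.0))[1] > flow_indicators(loop_snapshot(2.0))[1]

    def test_pl_definitional_limit(self):
        # no respiration, exports equal to all throughput -> every unit of
        # inflow passes exactly one compartment
        snap = FlowSnapshot(
            q=np.zeros((2, 2)),
            respiration=np.zeros(2),
            flows_to_detritus=np.zeros(2),
            exports=np.array([5.0, 3.0]),
            imports=np.array([5.0, 3.0]),
            detritus=np.zeros(2, dtype=bool),
        )
        tst, fci, pl = flow_indicators(snap)
        assert pl == pytest.approx(1.0)

    def test_negative_respiration_rejected(self):
        with pytest.raises(ValueError, match="respiration"):
            FlowSnapshot(
                q=np.zeros((2, 2)),
                respiration=np.array([-1.0, 0.0]),
                flows_to_detritus=np.zeros(2),
                exports=np.zeros(2),
                imports=np.zeros(2),
            )


class TestSeriesOverRun:
    def test_full_indicator_table(self, calibrated):
        model, params, dyn = calibrated
        res = simulate(model, params, dyn, constant_forcing(model), years=6)
        table = indicator_series(res, model, dyn)
        assert len(table) == 6
        expected_cols = {"TotalB", "ForF", "InvB", "PredB", "Kempton", "TotalC",
                         "mTLc", "mTLco", "TST", "FCI", "PL"}
        assert set(table.columns) == expected_cols
        assert table.drop(columns=["Kempton"]).notna().all().all()
        assert (table["FCI"] >= 0).all() and (table["FCI"] < 100).all()
        assert (table["TST"] > 0).all()
        assert (table["PL"] >= 1).all()

    def test_baseline_snapshot_consistent_with_dynamic_state(self, calibrated):
        # indicator flows at the unforced equilibrium match the balance-based
        # accounting of the static snapshot
        model, params, dyn = calibrated
        static = baseline_flow_snapshot(model)
        res = simulate(model, params, dyn, constant_forcing(model), years=1)
        table = indicator_series(res, model, dyn)
        tst_static, fci_static, pl_static = flow_indicators(static)
        assert table["TST"].iloc[0] == pytest.approx(tst_static, rel=1e-2)
        assert table["FCI"].iloc[0] == pytest.approx(fci_static, rel=1e-2)
        assert table["PL"].iloc[0] == pytest.approx(pl_static, rel=1e-2)
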