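"""Mass-balance solve, trophic levels and catch aggregation."""

import numpy as np
import pytest

from shelfweb.balance import (
    BalanceError,
    Fleet,
    UnbalancedModelError,
    compute_trophic_levels,
    solve_mass_balance,
    total_catch_by_group,
)

from conftest import make_model


def two_group_web(consumer_qb=5.0):
    return make_model(
        [
            ("producer", "producer", 10.0, 10.0, 0.0, 0.0),
            ("detritus", "detritus", 5.0, 0.0, 0.0, 0.0),
            ("grazer", "consumer", 1.0, 1.0, consumer_qb, 0.2),
        ],
        {"grazer": {"producer": 1.0}},
    )


class TestSolveMassBalance:
    def test_hand_computed_producer_ee(self):
        # predation demand 1 * 5 over production 10 * 10
        m = solve_mass_balance(two_group_web())
        assert m.groups[0].ee == pytest.approx(0.05, abs=1e-12)

    def test_isolated_producer_has_zero_ee(self):
        m = make_model(
            [
                ("producer", "producer", 10.0, 10.0, 0.0, 0.0),
                ("detritus", "detritus", 5.0, 0.0, 0.0, 0.0),
            ],
            {},
        )
        assert solve_mass_balance(m).groups[0].ee == 0.0

    def test_synthetic_web_residuals_and_ee(self, synthetic_web):
        model, _, _ = synthetic_web
        b = model.array("biomass")
        pb = model.array("pb")
        qb = model.array("qb")
        ee = model.array("ee")
        y = total_catch_by_group(model)
        living = model.living()
        residual = b * pb * ee - model.diet.dc @ (b * qb) - y
        for i in np.where(living)[0]:
            assert abs(residual[i]) < 1e-9 * max(1.0, b[i] * pb[i])
            assert 0.0 <= ee[i] <= 1.0

    def test_estimate_biomass_instead_of_ee(self):
        # fix the producer's EE and recover the biomass that balances it
        m = two_group_web()
        m.groups[0].ee = 0.05
        m.groups[0].biomass = None
        solved = solve_mass_balance(m, estimate={"producer": "B", "grazer": "EE"})
        assert solved.groups[0].biomass == pytest.approx(10.0, rel=1e-12)

    def test_overconsumption_is_rejected_with_group_names(self):
        m = two_group_web(consumer_qb=200.0)  # demand 200 > production 100
        with pytest.raises(UnbalancedModelError, match="producer"):
            solve_mass_balance(m)

    def test_ee_monotone_in_prey_biomass(self):
        # more prey biomass at fixed predation -> lower EE
        ees = []
        for b_prod in (5.0, 10.0, 20.0):
            m = make_model(
                [
                    ("producer", "producer", b_prod, 10.0, 0.0, 0.0),
                    ("detritus", "detritus", 5.0, 0.0, 0.0, 0.0),
                    ("grazer", "consumer", 1.0, 1.0, 5.0, 0.2),
                ],
                {"grazer": {"producer": 1.0}},
            )
            ees.append(solve_mass_balance(m).groups[0].ee)
        assert ees[0] > ees[1] > ees[2]

    def test_detritus_inflow_covers_detritivory(self, synthetic_web):
        from shelfweb.balance import detritus_budget

        model, _, _ = synthetic_web
        budget = detritus_budget(model)
        assert budget["inflow"] >= budget["detritivory"]
        assert budget["export"] >= 0

    def test_balance_closure_identity(self, synthetic_web):
        # production = predation + catch + net export + (1 - EE) * production
        model, _, _ = synthetic_web
        b = model.array("biomass")
        pb = model.array("pb")
        qb = model.array("qb")
        ee = model.array("ee")
        y = total_catch_by_group(model)
        predation = model.diet.dc @ (b * qb)
        for i in np.where(model.living())[0]:
            production = b[i] * pb[i]
            rhs = predation[i] + y[i] + (1 - ee[i]) * production
            assert rhs == pytest.approx(production, rel=1e-9)


class TestTrophicLevels:
    def test_pure_chain_is_integer_levels(self, chain_model):
        tl = compute_trophic_levels(chain_model)
        assert tl == pytest.approx([1.0, 1.0, 2.0, 3.0], abs=1e-12)

    def test_mixed_diet_midpoint(self):
        m = make_model(
            [
                ("algae", "producer", 50.0, 10.0, 0.0, 0.0),
                ("detritus", "detritus", 5.0, 0.0, 0.0, 0.0),
                ("herb", "consumer", 5.0, 2.0, 10.0, 0.2),
                ("carn", "consumer", 1.0, 1.0, 4.0, 0.2),
                ("top", "consumer", 0.2, 0.5, 2.0, 0.2),
            ],
            {
                "herb": {"algae": 1.0},
                "carn": {"herb": 1.0},
                "top": {"herb": 0.5, "carn": 0.5},
            },
        )
        tl = compute_trophic_levels(m)
        assert tl[m.index("top")] == pytest.approx(3.5, abs=1e-12)

    def test_mutual_feeding_matches_iterative_fixed_point(self):
        m = make_model(
            [
                ("algae", "producer", 100.0, 20.0, 0.0, 0.0),
                ("detritus", "detritus", 5.0, 0.0, 0.0, 0.0),
                ("a", "consumer", 5.0, 2.0, 10.0, 0.2),
                ("b", "consumer", 4.0, 2.0, 10.0, 0.2),
            ],
            {
                "a": {"algae": 0.6, "b": 0.4},
                "b": {"algae": 0.7, "a": 0.3},
            },
        )
        tl = compute_trophic_levels(m)
        # brute-force oracle: iterate the recursion to a 1e-12 fixed point
        dc = m.diet.dc
        guess = np.ones(m.n)
        for _ in range(10_000):
            new = np.ones(m.n)
            for j in range(m.n):
                if m.groups[j].category == "consumer":
                    new[j] = 1 + dc[:, j] @ guess
            if np.max(np.abs(new - guess)) < 1e-13:
                break
            guess = new
        assert tl == pytest.approx(guess, abs=1e-10)

    def test_all_import_diet_is_an_error(self):
        m = make_model(
            [
                ("algae", "producer", 10.0, 10.0, 0.0, 0.0),
                ("detritus", "detritus", 5.0, 0.0, 0.0, 0.0),
                ("drifter", "consumer", 1.0, 1.0, 5.0, 0.2),
            ],
            {},
            imports={"drifter": 1.0},
        )
        with pytest.raises(BalanceError, match="import"):
            compute_trophic_levels(m)

    def test_solution_satisfies_recursion(self, synthetic_web):
        model, _, _ = synthetic_web
        tl = compute_trophic_levels(model)
        dc = model.diet.dc
        imp = model.diet.import_fraction
        for j, g in enumerate(model.groups):
            if g.category == "consumer":
                expected = 1 + (dc[:, j] / (1 - imp[j])) @ tl
                assert abs(tl[j] - expected) < 1e-12
            else:
                assert tl[j] == pytest.approx(1.0)


class TestTotalCatch:
    def test_single_fleet(self):
        m = two_group_web()
        m.fleets.append(Fleet("trawl", {"grazer": 1.0}))
        y = total_catch_by_group(m)
        assert y[m.index("grazer")] == 1.0

    def test_two_fleets_add(self):
        m = two_group_web()
        m.fleets += [Fleet("trawl", {"grazer": 0.3}), Fleet("lines", {"grazer": 0.2})]
        assert total_catch_by_group(m)[m.index("grazer")] == pytest.approx(0.5)

    def test_double_summation_consistency(self, synthetic_web):
        model, _, _ = synthetic_web
        per_group = total_catch_by_group(model).sum()
        per_fleet = sum(f.total_catch() for f in model.fleets)
        assert per_group == pytest.approx(per_fleet, rel=1e-12)

    def test_zero_catch_fleet_rejected(self):
        with pytest.raises(BalanceError, match="zero total catch"):
            Fleet("ghost", {}, {})
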