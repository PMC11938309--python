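import numpy as np
import pandas as pd
import pytest

import survcea as sc
from survcea.psm_econ import EconError, pd_state_cost_per_cycle
from survcea.published import base_case_totals


@pytest.fixture()
def params():
    return sc.EconParams()


def exp_curves(params, lam_pfs, lam_os):
    grid = sc.cycle_grid_years(params)
    return np.exp(-lam_pfs * grid), np.exp(-lam_os * grid), grid


class TestEconParams:
    def test_defaults_validate_clean(self, params):
        assert params.validate() == []

    def test_bad_mix_and_negative_cost_reported(self, params):
        d = params.to_dict()
        d["pd_treatment_mix"]["tcm"] = 0.25  # sums to 0.9
        d["unit_costs"]["sintilimab"]["price"] = -1.0
        problems = sc.EconParams.from_dict(d).validate()
        assert any("pd_treatment_mix" in p for p in problems)
        assert any("sintilimab" in p for p in problems)

    def test_yaml_round_trip_and_cny_mode(self, tmp_path, params):
        path = tmp_path / "econ.yaml"
        params.to_yaml(path)
        back = sc.EconParams.from_yaml(path)
        assert back == params
        cny = sc.EconParams.from_yaml(path, currency="cny")
        assert cny.unit_costs["sintilimab"]["price"] == pytest.approx(
            153.74 * 0.14235
        )


class TestBuildTrace:
    def test_full_survival_keeps_everyone_progression_free(self, params):
        grid = sc.cycle_grid_years(params)
        ones = np.ones_like(grid)
        trace = sc.build_trace(ones, ones, params)
        assert np.allclose(trace["p_pd"], 0.0)
        assert np.allclose(trace["p_death"], 0.0)
        assert trace.attrs["clamp_count"] == 0

    def test_memberships_sum_to_one(self, params):
        S_pfs, S_os, _ = exp_curves(params, 0.5, 0.2)
        trace = sc.build_trace(S_pfs, S_os, params)
        total = trace["p_pfs"] + trace["p_pd"] + trace["p_death"]
        assert np.max(np.abs(total - 1.0)) < 1e-12

    def test_clamp_preserves_conservation_and_counts(self, params):
        """A cycle where S_pfs > S_os gets PD = 0, a clamp count, and rows
        that still sum to one."""
        grid = sc.cycle_grid_years(params)
        S_os = np.exp(-0.4 * grid)
        S_pfs = S_os.copy()
        S_pfs[5] = S_os[5] + 0.03  # inconsistent input at one boundary
        trace = sc.build_trace(S_pfs, S_os, params)
        assert trace.attrs["clamp_count"] == 1
        assert trace["p_pd"].iloc[4] == 0.0 and trace["p_pd"].iloc[5] == 0.0
        total = trace["p_pfs"] + trace["p_pd"] + trace["p_death"]
        assert np.max(np.abs(total - 1.0)) < 1e-12

    def test_wrong_grid_length_rejected(self, params):
        with pytest.raises(EconError, match="cycle grid"):
            sc.build_trace(np.ones(10), np.ones(10), params)


class TestDrugCosts:
    def test_flat_dose_one_vial(self, params):
        strat = sc.StrategyDef("s", (("sintilimab", "flat_mg", 200.0, 21),))
        assert sc.drug_cost_per_cycle(strat, params) == pytest.approx(153.74)

    def test_partial_vial_rounds_up(self, params):
        strat = sc.StrategyDef("s", (("sintilimab", "flat_mg", 250.0, 21),))
        assert sc.drug_cost_per_cycle(strat, params) == pytest.approx(2 * 153.74)

    def test_weight_based_q2w_schedule(self, params):
        """serplulimab 3 mg/kg q2w: 195 mg -> 2 x 100 mg vials -> 1590.90 per
        administration x 1.5 administrations per 21-day cycle."""
        strat = sc.StrategyDef("s", (("serplulimab", "mg_per_kg", 3.0, 14),))
        assert sc.drug_cost_per_cycle(strat, params) == pytest.approx(
            2 * 795.45 * 1.5
        )

    def test_unknown_drug_rejected(self, params):
        strat = sc.StrategyDef("s", (("novel_agent", "flat_mg", 100.0, 21),))
        with pytest.raises(EconError, match="unknown drug"):
            sc.drug_cost_per_cycle(strat, params)

    def test_default_strategies_cover_all_published_arms(self):
        names = {s.name for s in sc.default_strategies()}
        assert names == {
            "chemotherapy", "toripalimab", "camrelizumab", "pembrolizumab",
            "serplulimab", "sintilimab", "tislelizumab",
        }


class TestAccrue:
    def test_perfect_survival_full_utility_gives_horizon(self):
        p = sc.EconParams(
            annual_discount=0.0, utilities={"pfs": 1.0, "pd": 1.0},
            ae_incidence={},
        )
        grid = sc.cycle_grid_years(p)
        trace = sc.build_trace(np.ones_like(grid), np.ones_like(grid), p)
        out = sc.accrue(trace, sc.default_strategies()[0], p)
        assert out["qaly"] == pytest.approx(5.0, abs=1e-10)
        assert out["ly"] == pytest.approx(5.0, abs=1e-10)

    def test_cost_matches_continuous_closed_form(self):
        """Constant hazards, no discounting: accrued cost agrees with the
        continuous-time integral within 0.5% (half-cycle correction)."""
        p = sc.EconParams(annual_discount=0.0, ae_incidence={})
        lam_pfs, lam_os = 0.5, 0.2
        S_pfs, S_os, grid = exp_curves(p, lam_pfs, lam_os)
        trace = sc.build_trace(S_pfs, S_os, p)
        strat = sc.default_strategies()[0]
        out = sc.accrue(trace, strat, p)
        cycle_years = p.cycle_days / 365.25
        pfs_cost = sc.drug_cost_per_cycle(strat, p) + sum(
            p.per_cycle_costs[c]
            for c in ("administration", "laboratory_radiology", "supportive_care",
                      "hospitalization", "routine_follow_up")
        )
        pd_cost = pd_state_cost_per_cycle(p)
        T = p.horizon_years
        int_pfs = (1 - np.exp(-lam_pfs * T)) / lam_pfs
        int_os = (1 - np.exp(-lam_os * T)) / lam_os
        expected = (
            pfs_cost * int_pfs + pd_cost * (int_os - int_pfs)
        ) / cycle_years
        assert out["cost"] == pytest.approx(expected, rel=0.005)

    def test_zero_ae_incidence_is_a_no_op(self, params):
        S_pfs, S_os, _ = exp_curves(params, 0.5, 0.2)
        trace = sc.build_trace(S_pfs, S_os, params)
        strat = sc.default_strategies()[1]
        with_ae = sc.accrue(trace, strat, params)
        p0 = sc.EconParams.from_dict(
            {**params.to_dict(), "ae_incidence": {strat.name: {}}}
        )
        without = sc.accrue(trace, strat, p0)
        base = sc.accrue(
            trace, strat,
            sc.EconParams.from_dict({**params.to_dict(), "ae_incidence": {}}),
        )
        assert without["cost"] == pytest.approx(base["cost"])
        assert without["qaly"] == pytest.approx(base["qaly"])
        assert with_ae["cost"] > without["cost"]  # AE burden is real

    def test_missing_cost_category_is_loud(self, params):
        d = params.to_dict()
        del d["per_cycle_costs"]["supportive_care"]
        p = sc.EconParams.from_dict(d)
        S_pfs, S_os, _ = exp_curves(p, 0.5, 0.2)
        trace = sc.build_trace(S_pfs, S_os, p)
        with pytest.raises(EconError):
            sc.accrue(trace, sc.default_strategies()[0], p)

    def test_discount_zero_identity(self, params):
        """With a 0% discount rate the discounted totals equal plain sums."""
        p = sc.EconParams.from_dict({**params.to_dict(), "annual_discount": 0.0})
        S_pfs, S_os, _ = exp_curves(p, 0.5, 0.2)
        trace = sc.build_trace(S_pfs, S_os, p)
        assert np.allclose(trace["discount"], 1.0, atol=1e-12)
        out = sc.accrue(trace, sc.default_strategies()[0], p)
        u = p.utilities
        manual_qaly = float(
            ((u["pfs"] * trace["p_pfs"] + u["pd"] * trace["p_pd"])
             * trace["dt_years"]).sum()
        )
        ae = sum(
            prob * p.ae_disutilities[ae]
            for ae, prob in p.ae_incidence["chemotherapy"].items()
        )
        assert out["qaly"] == pytest.approx(manual_qaly + ae, abs=1e-10)

    def test_higher_pfs_utility_never_lowers_qalys(self, params):
        S_pfs, S_os, _ = exp_curves(params, 0.5, 0.2)
        trace = sc.build_trace(S_pfs, S_os, params)
        strat = sc.default_strategies()[0]
        lo = sc.accrue(trace, strat, params)
        d = params.to_dict()
        d["utilities"]["pfs"] = 0.9
        hi = sc.accrue(trace, strat, sc.EconParams.from_dict(d))
        assert hi["qaly"] >= lo["qaly"]


class TestICERTable:
    def test_published_totals_reassemble(self, params):
        """Feeding the published base-case totals through the ICER assembly
        reproduces the incremental costs by subtraction and finds exactly
        three strategies below the WTP threshold."""
        tab = sc.icer_table(base_case_totals(), "chemotherapy", params)
        assert tab.loc["toripalimab", "inc_cost"] == pytest.approx(19718.18)
        assert tab.loc["sintilimab", "inc_cost"] == pytest.approx(12008.15)
        assert tab.loc["toripalimab", "inc_qaly"] == pytest.approx(0.61)
        assert tab.attrs["n_below_wtp"] == 3
        assert tab.loc["sintilimab", "rank"] == 1
        assert tab.loc["toripalimab", "rank"] == 2
        assert tab.loc["tislelizumab", "rank"] == 3

    def test_identical_strategy_flagged_not_divided(self, params):
        res = pd.DataFrame(
            {"strategy": ["ref", "twin"], "cost": [100.0, 100.0],
             "qaly": [1.0, 1.0]}
        )
        tab = sc.icer_table(res, "ref", params)
        assert np.isnan(tab.loc["twin", "icer"])
        assert tab.loc["twin", "flag"] == "equivalent"
        assert np.isnan(tab.loc["twin", "rank"])

    def test_dominated_strategy_excluded_from_ranking(self, params):
        res = pd.DataFrame(
            {"strategy": ["ref", "worse", "better"],
             "cost": [100.0, 200.0, 150.0],
             "qaly": [1.0, 0.9, 1.2]}
        )
        tab = sc.icer_table(res, "ref", params)
        assert tab.loc["worse", "flag"] == "dominated"
        assert np.isnan(tab.loc["worse", "icer"])
        assert tab.loc["better", "rank"] == 1

    def test_currency_equivariance(self, params):
        """Scaling every cost by k scales every ICER by exactly k."""
        res = base_case_totals()
        tab1 = sc.icer_table(res, "chemotherapy", params)
        k = 7.0243
        res_k = res.assign(cost=res["cost"] * k)
        tab2 = sc.icer_table(res_k, "chemotherapy", params)
        r1 = tab1["icer"].dropna()
        r2 = tab2["icer"].dropna()
        assert np.allclose(r2.to_numpy(), k * r1.to_numpy(), rtol=1e-12)

    def test_missing_reference_rejected(self, params):
        res = pd.DataFrame({"strategy": ["a"], "cost": [1.0], "qaly": [1.0]})
        with pytest.raises(EconError):
            sc.icer_table(res, "chemotherapy", params)
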