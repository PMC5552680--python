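import copy

import numpy as np
import pytest
from scipy.optimize import linprog

from chardir.atp import (
    FluxFitError,
    ModelError,
    UptakeProfile,
    atp_breakdown,
    fit_fluxes,
    load_model,
    model_from_dict,
    read_sbml,
    save_model,
    substrate_atp_yield,
    total_atp,
    write_sbml,
)
from chardir.synthetic import (
    GLUCOSE_FERMENTATION_ATP,
    ILE_ATP_YIELD,
    LEU_ATP_YIELD,
    VAL_ATP_YIELD,
    simulate_uptake_profiles,
    toy_core_model,
    toy_core_model_dict,
)


def pfba_oracle(model, profile):
    """Independent pFBA formulation: free v plus t >= |v|, interior-point solve."""
    from chardir.atp import _apply_measurements

    lb, ub, _ = _apply_measurements(model, profile)
    nr = model.n_reactions
    nm = model.S.shape[0]
    # variables [v, t]; minimize sum t s.t. Sv=0, t >= v, t >= -v
    c = np.concatenate([np.zeros(nr), np.ones(nr)])
    A_eq = np.hstack([model.S, np.zeros((nm, nr))])
    A_ub = np.vstack([
        np.hstack([np.eye(nr), -np.eye(nr)]),     # v - t <= 0
        np.hstack([-np.eye(nr), -np.eye(nr)]),    # -v - t <= 0
    ])
    bounds = [(l, u) for l, u in zip(lb, ub)] + [(0, None)] * nr
    res = linprog(c, A_ub=A_ub, b_ub=np.zeros(2 * nr), A_eq=A_eq,
                  b_eq=np.zeros(nm), bounds=bounds, method="highs-ipm")
    assert res.status == 0, res.message
    return res.fun, res.x[:nr]


def fermentation_only(model_dict=None):
    """Toy model with the oxygen exchange closed (no respiration possible)."""
    d = copy.deepcopy(model_dict or toy_core_model_dict())
    for r in d["reactions"]:
        if r["id"] == "EX_o2":
            r["lb"] = 0.0
    return model_from_dict(d)


class TestModelIO:
    def test_json_round_trip(self, toy_model, tmp_path):
        path = tmp_path / "model.json"
        save_model(toy_model, path)
        back = load_model(path)
        assert back.reaction_ids == toy_model.reaction_ids
        assert back.metabolite_ids == toy_model.metabolite_ids
        np.testing.assert_allclose(back.S, toy_model.S)
        np.testing.assert_allclose(back.lb, toy_model.lb)
        assert back.exchange_map == toy_model.exchange_map
        assert back.roles == toy_model.roles

    def test_small_model_shape_read_back(self):
        d = {
            "metabolites": ["a", "b"],
            "reactions": [
                {"id": "EX_a", "stoich": {"a": -1}, "lb": -5, "ub": 0, "exchange": True},
                {"id": "conv", "stoich": {"a": -1, "b": 1}, "lb": 0, "ub": 10},
                {"id": "EX_b", "stoich": {"b": -1}, "lb": 0, "ub": 10, "exchange": True},
            ],
            "atp": "b",
        }
        m = model_from_dict(d)
        assert m.S.shape == (2, 3)
        assert m.exchange_map == {"a": "EX_a", "b": "EX_b"}

    def test_unknown_metabolite_names_reaction(self):
        d = {"metabolites": ["a"], "atp": "a",
             "reactions": [{"id": "bad", "stoich": {"ghost": 1}, "lb": 0, "ub": 1}]}
        with pytest.raises(ModelError, match="'bad'.*'ghost'"):
            model_from_dict(d)

    def test_inverted_bounds_rejected(self):
        d = {"metabolites": ["a"], "atp": "a",
             "reactions": [{"id": "r", "stoich": {"a": 1}, "lb": 2, "ub": 1}]}
        with pytest.raises(ModelError, match="'r'"):
            model_from_dict(d)

    def test_multi_metabolite_exchange_rejected(self):
        d = {"metabolites": ["a", "b"], "atp": "a",
             "reactions": [{"id": "EX", "stoich": {"a": -1, "b": 1},
                            "lb": 0, "ub": 1, "exchange": True}]}
        with pytest.raises(ModelError, match="exactly one"):
            model_from_dict(d)

    def test_sbml_round_trip_preserves_stoichiometry(self, toy_model, tmp_path):
        path = tmp_path / "toy.xml"
        write_sbml(toy_model, path)
        back = read_sbml(path, atp_meta="atp_c", inorganic=toy_model.inorganic,
                         roles=toy_model.roles)
        assert set(back.metabolite_ids) == set(toy_model.metabolite_ids)
        assert set(back.reaction_ids) == set(toy_model.reaction_ids)
        # identical S up to row/column ordering
        for j, rid in enumerate(toy_model.reaction_ids):
            jb = back.reaction_index(rid)
            for i, met in enumerate(toy_model.metabolite_ids):
                ib = back.metabolite_ids.index(met)
                assert back.S[ib, jb] == pytest.approx(toy_model.S[i, j])


class TestFitFluxes:
    def test_all_zero_measurements_give_zero_flux(self, toy_model):
        prof = UptakeProfile("idle", {m: 0.0 for m in toy_model.exchange_map})
        fit = fit_fluxes(toy_model, prof)
        np.testing.assert_allclose(fit.v, 0.0, atol=1e-9)
        assert fit.objective == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_fermentation_path(self, toy_model):
        # glucose 1 in, lactate 2 out forces GLYC_FERM = 1 and ATP_DEMAND = 2;
        # total path length 1 + 2 + 1 + 2 = 6
        prof = UptakeProfile("ferm", {"glc_e": -1.0, "lac_e": 2.0,
                                      "leu_e": 0.0, "ile_e": 0.0, "val_e": 0.0})
        fit = fit_fluxes(toy_model, prof)
        assert fit.flux("GLYC_FERM") == pytest.approx(1.0, abs=1e-9)
        assert fit.flux("RESP_GLC") == pytest.approx(0.0, abs=1e-9)
        assert fit.flux("ATP_DEMAND") == pytest.approx(2.0, abs=1e-9)
        assert fit.objective == pytest.approx(6.0, abs=1e-8)

    def test_steady_state_and_bounds_always_hold(self, toy_model):
        for prof in simulate_uptake_profiles(10, seed=23):
            fit = fit_fluxes(toy_model, prof)
            assert np.abs(toy_model.S @ fit.v).max() <= 1e-9
            assert (fit.v >= toy_model.lb - 1e-9).all()
            assert (fit.v <= toy_model.ub + 1e-9).all()

    def test_objective_matches_independent_formulation(self, toy_model):
        for prof in simulate_uptake_profiles(10, seed=31):
            fit = fit_fluxes(toy_model, prof)
            obj2, _ = pfba_oracle(toy_model, prof)
            assert fit.objective == pytest.approx(obj2, abs=1e-8)

    def test_infeasible_measurements_reported(self, toy_model):
        # lactate secretion above 2x glucose uptake cannot balance carbon
        prof = UptakeProfile("bad", {"glc_e": -1.0, "lac_e": 3.0})
        with pytest.raises(FluxFitError, match="bad"):
            fit_fluxes(toy_model, prof)

    def test_measurement_outside_bounds_rejected(self, toy_model):
        prof = UptakeProfile("pump", {"glc_e": 1.0})  # glucose secretion disallowed
        with pytest.raises(FluxFitError, match="EX_glc"):
            fit_fluxes(toy_model, prof)


class TestATPAccounting:
    def test_zero_flux_zero_atp(self, toy_model):
        prof = UptakeProfile("idle", {m: 0.0 for m in toy_model.exchange_map})
        assert total_atp(toy_model, fit_fluxes(toy_model, prof)) == pytest.approx(0.0)

    def test_fermentation_yields_two_atp_per_glucose(self, toy_model):
        prof = UptakeProfile("ferm", {"glc_e": -1.5, "lac_e": 3.0, "o2_e": 0.0})
        fit = fit_fluxes(toy_model, prof)
        assert total_atp(toy_model, fit) == pytest.approx(
            GLUCOSE_FERMENTATION_ATP * 1.5, abs=1e-9)

    def test_production_balances_consumption(self, toy_model):
        for prof in simulate_uptake_profiles(5, seed=3):
            fit = fit_fluxes(toy_model, prof)
            i = toy_model.metabolite_ids.index("atp_c")
            contrib = toy_model.S[i] * fit.v
            assert contrib.sum() == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "metabolite,expected",
        [("leu_e", LEU_ATP_YIELD), ("ile_e", ILE_ATP_YIELD), ("val_e", VAL_ATP_YIELD)],
    )
    def test_bcaa_yields_match_authored_stoichiometry(self, toy_model, metabolite, expected):
        assert substrate_atp_yield(toy_model, metabolite) == pytest.approx(expected, abs=1e-8)

    def test_fermentation_only_glucose_yield_is_two(self):
        m = fermentation_only()
        assert substrate_atp_yield(m, "glc_e") == pytest.approx(2.0, abs=1e-8)

    def test_unconsumable_metabolite_yields_zero(self):
        d = toy_core_model_dict()
        d["metabolites"].append("xx_e")
        d["reactions"].append({"id": "EX_xx", "stoich": {"xx_e": -1},
                               "lb": -10, "ub": 0, "exchange": True})
        m = model_from_dict(d)
        assert substrate_atp_yield(m, "xx_e") == 0.0

    def test_closed_pathway_yields_zero(self):
        d = copy.deepcopy(toy_core_model_dict())
        for r in d["reactions"]:
            if r["id"] == "LEU_OX":
                r["ub"] = 0.0
        m = model_from_dict(d)
        assert substrate_atp_yield(m, "leu_e") == 0.0

    def test_doubling_atp_coefficients_doubles_yield(self):
        d = copy.deepcopy(toy_core_model_dict())
        for r in d["reactions"]:
            if r["id"] == "RESP_GLC":
                r["stoich"]["atp_c"] *= 2
        m = model_from_dict(d)
        assert substrate_atp_yield(m, "glc_e") == pytest.approx(
            2 * substrate_atp_yield(toy_core_model(), "glc_e"), abs=1e-8)

    def test_missing_exchange_is_error(self, toy_model):
        with pytest.raises(ModelError, match="atp_c"):
            substrate_atp_yield(toy_model, "atp_c")


class TestATPBreakdown:
    def test_zero_bcaa_uptake_zero_fractions(self, toy_model):
        prof = UptakeProfile("x", {"glc_e": -1.0, "lac_e": 1.0,
                                   "leu_e": 0.0, "ile_e": 0.0, "val_e": 0.0})
        b = atp_breakdown(toy_model, fit_fluxes(toy_model, prof), prof)
        assert b.frac_leu == b.frac_ile == b.frac_val == 0.0

    def test_pure_fermentation_all_lactate(self, toy_model):
        prof = UptakeProfile("ferm", {"glc_e": -1.0, "lac_e": 2.0, "o2_e": 0.0,
                                      "leu_e": 0.0, "ile_e": 0.0, "val_e": 0.0})
        b = atp_breakdown(toy_model, fit_fluxes(toy_model, prof), prof)
        assert b.frac_lactate == pytest.approx(1.0, abs=1e-6)
        assert b.frac_other == pytest.approx(0.0, abs=1e-6)
        assert b.total_atp == pytest.approx(2.0, abs=1e-9)

    def test_fractions_sum_to_one(self, toy_model):
        for prof in simulate_uptake_profiles(8, seed=41):
            b = atp_breakdown(toy_model, fit_fluxes(toy_model, prof), prof)
            total = b.frac_lactate + b.frac_leu + b.frac_ile + b.frac_val + b.frac_other
            assert total == pytest.approx(1.0, abs=1e-6)
            for f in (b.frac_lactate, b.frac_leu, b.frac_ile, b.frac_val, b.frac_other):
                assert 0.0 <= f <= 1.0

    def test_bcaa_fraction_increases_with_uptake(self, toy_model):
        fracs = []
        for u in np.linspace(0.01, 0.3, 6):
            prof = UptakeProfile("sweep", {"glc_e": -0.5, "lac_e": 0.3,
                                           "leu_e": -u, "ile_e": -u, "val_e": -u})
            b = atp_breakdown(toy_model, fit_fluxes(toy_model, prof), prof)
            fracs.append(b.frac_bcaa)
        assert all(b > a for a, b in zip(fracs, fracs[1:]))

    def test_lactate_uptake_rejected(self, toy_model):
        ok = UptakeProfile("x", {"glc_e": -1.0, "lac_e": 0.5})
        flux = fit_fluxes(toy_model, ok)
        tampered = UptakeProfile("x", {"glc_e": -1.0, "lac_e": -0.5})
        with pytest.raises(ValueError, match="secretion"):
            atp_breakdown(toy_model, flux, tampered)
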