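"""FBA/pFBA engine: toy networks, LP oracle equivalence, yields, calibration."""

import numpy as np
import pytest

import xyloflux as xf
from xyloflux.model import (
    EnergeticsConfig,
    Metabolite,
    ModelValidationError,
    Reaction,
    StoichiometricModel,
)
from lp_oracle import vertex_optimum


def chain_model(uptake=10.0):
    """EX_A (uptake <= 10) -> r1: A -> B -> EX_B."""
    m = StoichiometricModel(id="chain")
    for mid in ("a_c", "b_c"):
        m.add_metabolite(Metabolite(id=mid, formula={"X": 1}, charge=0))
    m.add_reaction(Reaction("EX_A", {"a_c": -1.0}, -uptake, 0.0, subsystem="EXCHANGE"))
    m.add_reaction(Reaction("r1", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("EX_B", {"b_c": -1.0}, 0.0, 1000.0, subsystem="EXCHANGE"))
    return m


def test_linear_chain_optimum_equals_uptake_bound():
    sol = xf.solve_fba(chain_model(), {"EX_B": 1.0})
    assert sol.optimal
    assert sol.objective_value == pytest.approx(10.0)
    assert sol["r1"] == pytest.approx(10.0)


def test_all_exchanges_closed_only_zero_flux():
    m = chain_model()
    m.reactions["EX_A"].lower_bound = 0.0
    sol = xf.solve_fba(m, {"EX_B": 1.0})
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0.0)
    assert all(abs(v) < 1e-9 for v in sol.fluxes.values())


def test_unbounded_problem_reported():
    m = chain_model()
    # a free reversible cycle with an unbounded objective on it
    inf = float("inf")
    m.add_reaction(Reaction("loop", {"a_c": -1.0, "b_c": 1.0}, -inf, inf))
    m.reactions["r1"].lower_bound = -inf
    m.reactions["r1"].upper_bound = inf
    sol = xf.solve_fba(m, {"loop": 1.0})
    assert sol.status == "unbounded"
    assert sol.fluxes == {}


def test_infeasible_problem_reported():
    m = chain_model()
    m.reactions["EX_A"].lower_bound = -5.0
    m.reactions["EX_A"].upper_bound = -5.0
    m.reactions["EX_B"].upper_bound = 1.0  # cannot drain the forced uptake
    sol = xf.solve_fba(m, {"EX_B": 1.0})
    assert sol.status == "infeasible"


def test_fba_matches_vertex_enumeration_on_random_networks():
    """Solver optimum equals brute-force vertex enumeration, tiny scale."""
    rng_seeds = range(20)
    for seed in rng_seeds:
        spec = xf.RandomNetSpec(
            n_metabolites=4 + seed % 3,
            n_reactions=6 + seed % 3,
            reversibility_prob=0.3,
            seed=seed,
        )
        net = xf.simulate_network(spec)
        sol = xf.solve_fba(net, {"EX_snk": 1.0})
        assert sol.optimal
        oracle = vertex_optimum(net, {"EX_snk": 1.0})
        assert oracle is not None
        assert sol.objective_value == pytest.approx(oracle, rel=1e-8, abs=1e-8)


def test_steady_state_invariant_on_core_solutions(core_model):
    sol = xf.max_growth(core_model, "weimberg", 1.0)
    S, _, rxn_ids = core_model.stoichiometric_matrix()
    # route-applied model has same reaction set/order
    v = np.array([sol.fluxes[r] for r in rxn_ids])
    assert np.abs(S @ v).max() <= 1e-6


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------

def test_pfba_on_chain_identical_to_fba():
    m = chain_model()
    fba = xf.solve_fba(m, {"EX_B": 1.0})
    pfba = xf.solve_pfba(m, {"EX_B": 1.0})
    assert pfba.objective_value == pytest.approx(fba.objective_value, rel=1e-4)
    for rid in m.reactions:
        assert pfba[rid] == pytest.approx(fba[rid], abs=1e-6)


def test_pfba_collapses_futile_parallel_cycle():
    """Two antiparallel paths admit arbitrary cycling; pFBA removes it."""
    m = chain_model()
    m.add_reaction(Reaction("r2", {"a_c": -1.0, "b_c": 1.0}, -1000.0, 1000.0))
    pfba = xf.solve_pfba(m, {"EX_B": 1.0})
    assert pfba.objective_value == pytest.approx(10.0, rel=1e-4)
    # minimal-|v| solution carries all flux one way, no cycling
    total = sum(abs(v) for v in pfba.fluxes.values())
    assert total == pytest.approx(30.0, abs=1e-6)  # uptake + conversion + secretion
    assert abs(pfba["r1"]) + abs(pfba["r2"]) == pytest.approx(10.0, abs=1e-6)


def test_pfba_preserves_objective_value(core_model):
    routed = {"BIOMASS": 1.0}
    m = core_model.copy()
    m = xf.apply_route(m, "oxo_reductive")
    m.reactions["EX_xyl__D_e"].lower_bound = -1.0
    m.reactions["EX_xyl__D_e"].upper_bound = -1.0
    fba = xf.solve_fba(m, routed)
    pfba = xf.solve_pfba(m, routed)
    # pFBA retains >= 99.99% of the optimum by construction
    assert pfba.objective_value == pytest.approx(fba.objective_value, rel=2e-4)
    assert pfba.objective_value <= fba.objective_value + 1e-9


# ---------------------------------------------------------------------------
# ATP yields
# ---------------------------------------------------------------------------

def test_substrate_level_yields_by_hand_summation(core_model):
    """With negligible P/O, only substrate-level phosphorylation counts.

    Weimberg: +1 succinyl-CoA synthetase, +1 TCA turn of the derived
    acetyl-CoA, +1 pyruvate kinase, -1 PEP carboxykinase = 2 per xylose.
    Oxo-reductive: 5 C as 2/3 F6P + 1/3 G3P gives 10/3 + 1 - 1 (PFK) ...
    net 13/3 minus 1 ATP at xylulokinase = 10/3 per xylose.
    """
    tiny = EnergeticsConfig(po_nadh=1e-9, po_fadh2=0.5e-9)
    weim = xf.atp_yield(core_model, "weimberg", tiny).yield_value
    oxo = xf.atp_yield(core_model, "oxo_reductive", tiny).yield_value
    assert weim == pytest.approx(2.0, abs=1e-6)
    assert oxo == pytest.approx(10.0 / 3.0, abs=1e-6)


def test_atp_yield_monotone_in_po_ratios(core_model):
    for route in ("weimberg", "oxo_reductive"):
        previous = -np.inf
        for p, f in [(1.2, 0.6), (1.8, 1.0), (2.4, 1.4), (3.0, 1.9)]:
            y = xf.atp_yield(core_model, route, EnergeticsConfig(p, f)).yield_value
            assert y > previous
            previous = y


def test_weimberg_yield_below_oxo_for_admissible_configs(core_model):
    """Lower energy efficiency of the Weimberg route, for any P/O ordering."""
    for p, f in [(1.0, 0.5), (1.5, 1.49), (2.0, 1.0), (2.68, 1.58), (3.0, 2.0)]:
        cfg = EnergeticsConfig(p, f)
        weim = xf.atp_yield(core_model, "weimberg", cfg).yield_value
        oxo = xf.atp_yield(core_model, "oxo_reductive", cfg).yield_value
        assert weim < oxo, (p, f)


def test_atp_yield_infeasible_without_xylose_consumer(core_model):
    crippled = core_model.copy()
    for rid in ("XYLR", "XDH1", "XYLI"):
        crippled.reactions[rid].lower_bound = 0.0
        crippled.reactions[rid].upper_bound = 0.0
    with pytest.raises(xf.FluxInfeasibleError, match="weimberg"):
        xf.atp_yield(crippled, "weimberg")


def test_carbon_closure_at_zero_growth(core_model):
    """All substrate carbon leaves as CO2 when growth is closed."""
    for route in ("weimberg", "oxo_reductive"):
        res = xf.atp_yield(core_model, route, EnergeticsConfig(2.68, 1.58))
        sol = res.solution
        assert sol["EX_co2_e"] == pytest.approx(5.0, abs=1e-6)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def test_growth_zero_at_zero_uptake(core_model):
    sol = xf.max_growth(core_model, "oxo_reductive", 0.0)
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_growth_ordering_weimberg_below_oxo(core_model, calibrated_config):
    for cfg in (EnergeticsConfig(), calibrated_config):
        weim = xf.max_growth(core_model, "weimberg", 1.0, cfg)
        oxo = xf.max_growth(core_model, "oxo_reductive", 1.0, cfg)
        assert weim.objective_value < oxo.objective_value


def test_growth_scales_linearly_without_ngam(core_model):
    cfg = EnergeticsConfig(ngam=0.0)
    mu1 = xf.max_growth(core_model, "oxo_reductive", 1.0, cfg).objective_value
    mu2 = xf.max_growth(core_model, "oxo_reductive", 2.0, cfg).objective_value
    assert mu2 == pytest.approx(2.0 * mu1, rel=1e-6)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_calibration_reproduces_published_yields(calibration):
    assert calibration.converged
    assert abs(calibration.residuals["weimberg"]) <= 0.1
    assert abs(calibration.residuals["oxo_reductive"]) <= 0.1
    cfg = calibration.config
    assert 1.0 <= cfg.po_nadh <= 3.0
    assert 0.5 <= cfg.po_fadh2 <= 2.0
    assert cfg.po_nadh > cfg.po_fadh2


def test_calibration_single_target_closed_form_toy():
    """One NADH per substrate: the target yield pins po_nadh exactly."""
    m = StoichiometricModel(id="toy")
    mets = {
        "s_c": {"X": 1}, "p_c": {"X": 1}, "nad_c": {}, "nadh_c": {},
        "atp_c": {}, "adp_c": {}, "pi_c": {}, "h_c": {}, "h2o_c": {}, "o2_c": {},
    }
    for mid, formula in mets.items():
        m.add_metabolite(Metabolite(id=mid, formula=formula, charge=0))
    # reuse the xylose exchange id so the yield scenario recognizes it
    m.add_reaction(Reaction("EX_xyl__D_e", {"s_c": -1.0}, -1.0, 0.0, subsystem="EXCHANGE"))
    m.add_reaction(Reaction("EX_p", {"p_c": -1.0}, 0.0, 1000.0, subsystem="EXCHANGE"))
    m.add_reaction(Reaction("EX_o2", {"o2_c": -1.0}, -1000.0, 0.0, subsystem="EXCHANGE"))
    m.add_reaction(
        Reaction("DH", {"s_c": -1.0, "nad_c": -1.0, "p_c": 1.0, "nadh_c": 1.0}, 0, 1000, subsystem="OXORED")
    )
    m.add_reaction(
        Reaction(
            "NADHOR",
            {"nadh_c": -1.0, "o2_c": -0.5, "h_c": -3.5, "nad_c": 1.0,
             "h2o_c": 3.5, "adp_c": -2.5, "pi_c": -2.5, "atp_c": 2.5},
            0, 1000, subsystem="OXPHOS",
        )
    )
    m.add_reaction(
        Reaction("ATPM", {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0}, 0, 1000, subsystem="OXPHOS")
    )
    m.add_reaction(Reaction("H2O_s", {"h2o_c": -1.0}, -1000, 1000, subsystem="EXCHANGE"))
    m.add_reaction(Reaction("H_s", {"h_c": -1.0}, -1000, 1000, subsystem="EXCHANGE"))
    result = xf.calibrate_energetics(m, {"oxo_reductive": 1.75})
    assert result.config.po_nadh == pytest.approx(1.75, abs=0.005)
    assert abs(result.residuals["oxo_reductive"]) < 0.01


def test_calibration_empty_targets_errors(core_model):
    with pytest.raises(ModelValidationError):
        xf.calibrate_energetics(core_model, {})
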