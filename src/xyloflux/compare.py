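"""Paired route scenarios and route-comparison statistics.

Given growth-maximal parsimonious flux distributions for two assimilation
routes at the same xylose uptake, each reaction's absolute flux
difference is classified with the map-legend thresholds used for central
carbon flux maps: ``red`` for |dv| >= 4, ``purple`` for 2 <= |dv| < 4,
``black`` for |dv| < 2 (boundaries closed exactly as stated).

The phosphoenolpyruvate partition quantifies how a route operates the
lower EMP pathway: in Weimberg-route growth all carbon enters as
alpha-ketoglutarate, so hexose and pentose precursors must be made by
gluconeogenesis and a large share of PEP consumption flows backwards
through enolase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .fba import (
    FluxInfeasibleError,
    FluxSolution,
    YieldResult,
    atp_yield,
    max_growth,
    solve_fba,
)
from .model import (
    EnergeticsConfig,
    ModelValidationError,
    StoichiometricModel,
    apply_route,
    route_variant,
    set_energetics,
)

__all__ = [
    "FluxComparison",
    "FluxComparisonRecord",
    "PepPartition",
    "classify_flux_difference",
    "compare_routes",
    "pep_partition",
    "bt_theoretical_yield",
    "scenario_report",
    "report_json",
]


def classify_flux_difference(abs_difference: float) -> str:
    """Map-legend class of an absolute flux difference (closed boundaries)."""
    if abs_difference < 0:
        raise ValueError("absolute difference must be >= 0")
    if abs_difference >= 4:
        return "red"
    if abs_difference >= 2:
        return "purple"
    return "black"


@dataclass
class FluxComparisonRecord:
    reaction_id: str
    flux_a: float
    flux_b: float
    abs_difference: float
    klass: str


@dataclass
class FluxComparison:
    """Per-reaction flux differences between two route scenarios."""

    route_a: str
    route_b: str
    basis_uptake: float
    records: list[FluxComparisonRecord] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts = {"red": 0, "purple": 0, "black": 0}
        for rec in self.records:
            counts[rec.klass] += 1
        return counts

    def to_rows(self) -> list[dict]:
        return [
            {
                "reaction_id": r.reaction_id,
                f"flux_{self.route_a}": r.flux_a,
                f"flux_{self.route_b}": r.flux_b,
                "abs_diff": r.abs_difference,
                "class": r.klass,
            }
            for r in self.records
        ]


def compare_routes(
    model: StoichiometricModel,
    route_a,
    route_b,
    uptake: float = 1.0,
    config: EnergeticsConfig | None = None,
) -> FluxComparison:
    """Growth-maximal pFBA comparison of two routes at identical uptake."""
    route_a, route_b = route_variant(route_a), route_variant(route_b)
    solutions = {}
    for route in (route_a, route_b):
        try:
            solutions[route.name] = max_growth(model, route, uptake, config)
        except FluxInfeasibleError as exc:
            raise FluxInfeasibleError(
                f"route {route.name!r} infeasible at uptake {uptake}: {exc}"
            ) from None
    va = solutions[route_a.name].fluxes
    vb = solutions[route_b.name].fluxes
    cmp = FluxComparison(route_a.name, route_b.name, uptake)
    for rid in model.reactions:
        a, b = va.get(rid, 0.0), vb.get(rid, 0.0)
        d = abs(a - b)
        cmp.records.append(
            FluxComparisonRecord(rid, a, b, d, classify_flux_difference(d))
        )
    return cmp


# ---------------------------------------------------------------------------
# PEP partition
# ---------------------------------------------------------------------------

@dataclass
class PepPartition:
    """Steady-state split of phosphoenolpyruvate consumption.

    ``fraction_gluconeogenesis`` is None (sentinel) when total PEP
    turnover is zero.  Consumers are partitioned by what they make of
    PEP: the gluconeogenic branch (PEP -> 2-phosphoglycerate onward),
    pyruvate kinase, and everything else (anabolic drains).
    """

    pep_produced: float
    to_gluconeogenesis: float
    to_pyruvate: float
    to_other: float
    fraction_gluconeogenesis: float | None

    @property
    def total_consumed(self) -> float:
        return self.to_gluconeogenesis + self.to_pyruvate + self.to_other


def pep_partition(
    solution: FluxSolution,
    model: StoichiometricModel,
    pep_id: str = "pep_c",
    tol: float = 1e-9,
) -> PepPartition:
    """Partition net PEP consumption of an optimal solution.

    Each reaction touching PEP is inspected at its solved flux: if it
    consumes PEP and concurrently produces 2-phosphoglycerate it is a
    gluconeogenic consumer (enolase running backwards); if it produces
    pyruvate it counts toward ``to_pyruvate``; any other consumption
    (e.g. the biomass drain) is ``to_other``.
    """
    if not solution.optimal:
        raise ValueError("pep_partition requires an optimal solution")
    produced = 0.0
    gluconeo = pyruvate = other = 0.0
    for rid, rxn in model.reactions.items():
        coef = rxn.stoichiometry.get(pep_id)
        if coef is None or rid not in solution.fluxes:
            continue
        net = coef * solution.fluxes[rid]
        if net > tol:
            produced += net
        elif net < -tol:
            consumed = -net
            v = solution.fluxes[rid]
            makes_2pg = rxn.stoichiometry.get("2pg_c", 0.0) * v > tol
            makes_pyr = rxn.stoichiometry.get("pyr_c", 0.0) * v > tol
            if makes_2pg:
                gluconeo += consumed
            elif makes_pyr:
                pyruvate += consumed
            else:
                other += consumed
    total = gluconeo + pyruvate + other
    fraction = gluconeo / total if total > tol else None
    return PepPartition(produced, gluconeo, pyruvate, other, fraction)


# ---------------------------------------------------------------------------
# BT theoretical yield
# ---------------------------------------------------------------------------

def bt_theoretical_yield(
    model: StoichiometricModel,
    config: EnergeticsConfig | None = None,
    uptake: float = 1.0,
) -> YieldResult:
    """Maximum 1,2,4-butanetriol secretion per mol xylose, growth 0.

    One decarboxylation bounds the yield at 1 mol BT / mol xylose
    (C5 -> C4 + CO2); the bound is reached when the XDH-derived NADPH
    can cover the aldehyde reduction (NADPH/NADH interconversion open).
    """
    from .fba import _yield_scenario  # shared scenario builder

    bt_rxns = [r for r in model.reactions.values() if r.subsystem == "BT"]
    if bt_rxns and all(r.lower_bound == 0 and r.upper_bound == 0 for r in bt_rxns):
        raise FluxInfeasibleError("BT route is disabled in this model")
    config = config or model.parameters
    scen = _yield_scenario(model, "bt_production", config, uptake)
    ex = scen.reactions["EX_btol_e"]
    ex.lower_bound, ex.upper_bound = 0.0, 1000.0
    sol = solve_fba(scen, {"EX_btol_e": 1.0})
    if not sol.optimal:
        raise FluxInfeasibleError(f"BT yield problem is {sol.status}")
    return YieldResult(
        substrate_id="xyl__D_e",
        objective_id="EX_btol_e",
        yield_value=sol.objective_value / uptake,
        basis_uptake=uptake,
        solution=sol,
    )


# ---------------------------------------------------------------------------
# Scenario report
# ---------------------------------------------------------------------------

def scenario_report(
    model: StoichiometricModel,
    config: EnergeticsConfig | None = None,
    uptake: float = 1.0,
    routes: tuple[str, str] = ("oxo_reductive", "weimberg"),
) -> dict:
    """Deterministic summary of the paired route comparison.

    For each route: ATP yield (mol/mol xylose), growth rate at the given
    uptake, and the PEP gluconeogenesis fraction; plus the yield
    difference and flux-difference class counts.  Routes whose
    subsystems are missing from the model are marked unavailable.
    Identical inputs give identical output (and identical bytes via
    :func:`report_json`).
    """
    config = config or model.parameters
    report: dict = {
        "model_id": model.id,
        "basis_uptake": uptake,
        "energetics": {
            "po_nadh": config.po_nadh,
            "po_fadh2": config.po_fadh2,
            "gam": config.gam,
            "ngam": config.ngam,
            "nadph_nadh_interconversion": config.nadph_nadh_interconversion,
        },
        "routes": {},
    }
    available = []
    present = {r.subsystem for r in model.reactions.values()}
    for name in routes:
        variant = route_variant(name)
        if not variant.enabled_subsystems <= present:
            report["routes"][name] = {"available": False}
            continue
        y = atp_yield(model, name, config, uptake=uptake)
        growth = max_growth(model, name, uptake, config)
        part = pep_partition(growth, model)
        report["routes"][name] = {
            "available": True,
            "atp_yield_mol_per_mol": round(y.yield_value, 6),
            "growth_rate_per_h": round(growth.objective_value, 6),
            "pep_fraction_gluconeogenesis": (
                None
                if part.fraction_gluconeogenesis is None
                else round(part.fraction_gluconeogenesis, 6)
            ),
        }
        available.append(name)
    if len(available) == 2:
        a, b = available
        report["atp_yield_difference"] = round(
            report["routes"][a]["atp_yield_mol_per_mol"]
            - report["routes"][b]["atp_yield_mol_per_mol"],
            6,
        )
        cmp = compare_routes(model, a, b, uptake, config)
        report["flux_difference_class_counts"] = cmp.class_counts()
    return report


def report_json(report: dict) -> str:
    """Canonical byte representation of a scenario report."""
    return json.dumps(report, sort_keys=True, indent=1)
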