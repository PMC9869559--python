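"""Flux balance analysis on :class:`~xyloflux.model.StoichiometricModel`.

Linear programs are solved with the deterministic HiGHS solver behind
:func:`scipy.optimize.linprog`; variable order is the model's reaction
order, so repeated runs give identical flux vectors.  Three problems are
posed here:

* plain FBA (growth or any linear objective),
* parsimonious FBA (pFBA): among near-optimal flux vectors, the one of
  minimum total absolute flux, reported so that flux maps are unique,
* ATP-yield maximization: xylose uptake fixed to 1 mmol gDW^-1 h^-1,
  growth and non-growth maintenance closed, all carbon exchanges except
  CO2 shut, ATP hydrolysis maximized — a pure mol ATP / mol xylose yield.

Because the respiratory P/O ratios of the genome-scale parent model are
not published, :func:`calibrate_energetics` recovers them by a
deterministic nested grid search against target yields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .model import (
    EnergeticsConfig,
    ModelValidationError,
    StoichiometricModel,
    apply_route,
    route_variant,
    set_energetics,
)

__all__ = [
    "FluxSolution",
    "YieldResult",
    "CalibrationResult",
    "FluxInfeasibleError",
    "solve_fba",
    "solve_pfba",
    "atp_yield",
    "max_growth",
    "calibrate_energetics",
    "FEASIBILITY_TOL",
    "PFBA_OPTIMUM_FRACTION",
]

FEASIBILITY_TOL = 1e-6
#: Guaranteed fraction of the FBA optimum retained by pFBA solutions.  The
#: implementation constrains the objective to the optimum up to a tiny
#: numerical guard, so actual retention is far tighter than this floor.
PFBA_OPTIMUM_FRACTION = 0.9999
_HIGHS_OPTS = {"presolve": True}


class FluxInfeasibleError(RuntimeError):
    """The posed flux problem has no feasible (or no bounded) solution."""


@dataclass
class FluxSolution:
    """One FBA/pFBA solution: fluxes, objective value and solver status."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded
    objective_id: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class YieldResult:
    """A mol-product-per-mol-substrate yield at a given uptake basis."""

    substrate_id: str
    objective_id: str
    yield_value: float
    basis_uptake: float = 1.0
    solution: FluxSolution | None = None


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _status_of(res) -> str:
    return _STATUS.get(res.status, "infeasible")


def solve_fba(
    model: StoichiometricModel,
    objective: dict[str, float] | None = None,
    sense: str = "max",
) -> FluxSolution:
    """Solve max (or min) c'v subject to S v = 0, lb <= v <= ub."""
    if objective is None:
        objective = model.objective
    if not objective:
        raise ModelValidationError("objective is empty")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    S, _, rxn_ids = model.stoichiometric_matrix()
    index = {r: j for j, r in enumerate(rxn_ids)}
    c = np.zeros(len(rxn_ids))
    for rid, w in objective.items():
        if rid not in index:
            raise ModelValidationError(f"objective references unknown reaction {rid}")
        c[index[rid]] = w
    sign = -1.0 if sense == "max" else 1.0
    bounds = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in rxn_ids
    ]
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options=_HIGHS_OPTS,
    )
    status = _status_of(res)
    obj_id = "+".join(sorted(objective))
    if status != "optimal":
        return FluxSolution({}, None, status, obj_id)
    fluxes = dict(zip(rxn_ids, res.x))
    value = float(c @ res.x)
    sol = FluxSolution(fluxes, value, "optimal", obj_id)
    _assert_steady_state(model, sol)
    return sol


def _assert_steady_state(model: StoichiometricModel, sol: FluxSolution) -> None:
    S, _, rxn_ids = model.stoichiometric_matrix()
    v = np.array([sol.fluxes[r] for r in rxn_ids])
    resid = np.abs(S @ v).max() if len(v) else 0.0
    if resid > FEASIBILITY_TOL:
        raise FluxInfeasibleError(
            f"steady-state violation ||S v||_inf = {resid:.3e} exceeds "
            f"{FEASIBILITY_TOL}"
        )


def solve_pfba(
    model: StoichiometricModel,
    objective: dict[str, float] | None = None,
    optimum_fraction: float = PFBA_OPTIMUM_FRACTION,
) -> FluxSolution:
    """Parsimonious FBA: minimal total |v| among near-optimal solutions.

    The FBA optimum is computed first; a second LP over split variables
    v = v+ - v- then minimizes sum(v+ + v-) subject to retaining the
    optimum (up to a small numerical guard, never below
    ``optimum_fraction`` of it).  The reported objective value is the
    achieved c'v of the parsimonious solution.
    """
    if objective is None:
        objective = model.objective
    first = solve_fba(model, objective)
    if not first.optimal:
        return first
    opt = first.objective_value

    S, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    index = {r: j for j, r in enumerate(rxn_ids)}
    c = np.zeros(n)
    for rid, w in objective.items():
        c[index[rid]] = w
    lbs = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ubs = np.array([model.reactions[r].upper_bound for r in rxn_ids])

    # Split v into positive and negative parts; minimizing the sum drives
    # one of each pair to zero, so the pair never overlaps at optimum.
    A_eq = np.hstack([S, -S])
    bounds = [(max(lb, 0.0), max(ub, 0.0)) for lb, ub in zip(lbs, ubs)] + [
        (max(-ub, 0.0), max(-lb, 0.0)) for lb, ub in zip(lbs, ubs)
    ]
    guard = max(abs(opt) * 1e-9, 1e-12)
    threshold = max(opt - guard, opt - abs(opt) * (1.0 - optimum_fraction) - 1e-9)
    A_ub = -np.hstack([c, -c]).reshape(1, -1)
    b_ub = np.array([-threshold])
    res = linprog(
        np.ones(2 * n),
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options=_HIGHS_OPTS,
    )
    if _status_of(res) != "optimal":
        raise FluxInfeasibleError(
            "pFBA restriction LP failed although FBA was optimal"
        )
    v = res.x[:n] - res.x[n:]
    fluxes = dict(zip(rxn_ids, v))
    sol = FluxSolution(fluxes, float(c @ v), "optimal", first.objective_id)
    _assert_steady_state(model, sol)
    return sol


# ---------------------------------------------------------------------------
# Yield and growth scenarios
# ---------------------------------------------------------------------------

_FREE_EXCHANGES = {"EX_co2_e", "EX_h2o_e", "EX_o2_e", "EX_h_e", "EX_pi_e"}


def _carbon_exchanges(model: StoichiometricModel) -> list[str]:
    out = []
    for rxn in model.exchanges():
        (mid,) = rxn.stoichiometry
        if model.metabolites[mid].n_carbon() > 0:
            out.append(rxn.id)
    return out


def _yield_scenario(
    model: StoichiometricModel,
    route,
    config: EnergeticsConfig,
    uptake: float,
) -> StoichiometricModel:
    """Route-configured copy with unit xylose uptake, growth 0, NGAM 0."""
    scen = model.copy()
    set_energetics(scen, replace(config, ngam=0.0))
    scen = apply_route(scen, route)
    if "EX_xyl__D_e" not in scen.reactions:
        raise ModelValidationError("model lacks a xylose exchange EX_xyl__D_e")
    for rid in _carbon_exchanges(scen):
        if rid == "EX_xyl__D_e":
            continue
        rxn = scen.reactions[rid]
        if rid == "EX_co2_e":
            rxn.lower_bound, rxn.upper_bound = 0.0, 1000.0
        else:
            rxn.lower_bound, rxn.upper_bound = 0.0, 0.0
    ex = scen.reactions["EX_xyl__D_e"]
    ex.lower_bound = ex.upper_bound = -uptake
    if "BIOMASS" in scen.reactions:
        bm = scen.reactions["BIOMASS"]
        bm.lower_bound = bm.upper_bound = 0.0
    return scen


def atp_yield(
    model: StoichiometricModel,
    route,
    config: EnergeticsConfig | None = None,
    uptake: float = 1.0,
) -> YieldResult:
    """Maximum ATP yield of one assimilation route, mol ATP / mol xylose.

    Xylose uptake is fixed at ``uptake`` (default 1 mmol gDW^-1 h^-1),
    biomass is forced to zero and NGAM to zero, every carbon exchange
    but CO2 is closed, and the ATP-hydrolysis (maintenance) flux is
    maximized; the yield is that flux divided by the uptake.
    """
    route = route_variant(route)
    config = config or model.parameters
    if "ATPM" not in model.reactions:
        raise ModelValidationError("model lacks an ATP-hydrolysis reaction ATPM")
    scen = _yield_scenario(model, route, config, uptake)
    sol = solve_fba(scen, {"ATPM": 1.0})
    if not sol.optimal:
        raise FluxInfeasibleError(
            f"ATP-yield problem for route {route.name!r} is {sol.status}: the "
            "route cannot consume the fixed xylose uptake (no open "
            "xylose-assimilating reaction?)"
        )
    return YieldResult(
        substrate_id="xyl__D_e",
        objective_id="ATPM",
        yield_value=sol.objective_value / uptake,
        basis_uptake=uptake,
        solution=sol,
    )


def max_growth(
    model: StoichiometricModel,
    route,
    uptake: float = 1.0,
    config: EnergeticsConfig | None = None,
    parsimonious: bool = True,
) -> FluxSolution:
    """Growth-maximal (pFBA) solution at a fixed xylose uptake rate."""
    route = route_variant(route)
    if "BIOMASS" not in model.reactions:
        raise ModelValidationError("model lacks a biomass reaction BIOMASS")
    if uptake < 0:
        raise ValueError("uptake must be >= 0")
    scen = model.copy()
    set_energetics(scen, config or model.parameters)
    scen = apply_route(scen, route)
    ex = scen.reactions["EX_xyl__D_e"]
    ex.lower_bound = ex.upper_bound = -uptake
    solver = solve_pfba if parsimonious else solve_fba
    sol = solver(scen, {"BIOMASS": 1.0})
    if not sol.optimal:
        raise FluxInfeasibleError(
            f"growth problem for route {route.name!r} is {sol.status}"
        )
    return sol


# ---------------------------------------------------------------------------
# Energetics calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Best-fit energetics plus per-route residuals (fit minus target)."""

    config: EnergeticsConfig
    residuals: dict[str, float]
    yields: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def sse(self) -> float:
        return float(sum(r * r for r in self.residuals.values()))


def calibrate_energetics(
    model: StoichiometricModel,
    targets: dict[str, float],
    po_nadh_bounds: tuple[float, float] = (1.0, 3.0),
    po_fadh2_bounds: tuple[float, float] = (0.5, 2.0),
    tolerance: float = 0.1,
    base_config: EnergeticsConfig | None = None,
) -> CalibrationResult:
    """Recover P/O ratios reproducing target ATP yields per route.

    Deterministic nested grid search (three refinement levels, step
    0.1 -> 0.01 -> 0.001) over ``po_nadh`` x ``po_fadh2`` minimizing the
    squared error against ``targets`` (route name -> mol ATP / mol
    xylose).  The P/O ordering constraint po_nadh > po_fadh2 is
    enforced.  If no admissible grid point brings every residual within
    ``tolerance``, the best-effort result is returned with
    ``converged=False``.
    """
    if not targets:
        raise ModelValidationError("calibration requires at least one target yield")
    for name in targets:
        route_variant(name)
    base = base_config or model.parameters

    def evaluate(p: float, f: float) -> tuple[float, dict[str, float]]:
        cfg = replace(base, po_nadh=p, po_fadh2=f, ngam=0.0)
        yields = {}
        for name, target in targets.items():
            yields[name] = atp_yield(model, name, cfg).yield_value
        sse = sum((yields[n] - targets[n]) ** 2 for n in targets)
        return sse, yields

    def grid(lo: float, hi: float, step: float) -> np.ndarray:
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    best = None  # (sse, p, f, yields)
    p_lo, p_hi = po_nadh_bounds
    f_lo, f_hi = po_fadh2_bounds
    p_grid, f_grid = grid(p_lo, p_hi, 0.1), grid(f_lo, f_hi, 0.1)
    for step in (0.1, 0.01, 0.001):
        for p in p_grid:
            for f in f_grid:
                if not (p > f > 0):
                    continue
                sse, yields = evaluate(float(p), float(f))
                if best is None or sse < best[0] - 1e-12:
                    best = (sse, float(p), float(f), yields)
        # refine one coarse cell around the incumbent
        fine = step / 10.0
        p_grid = grid(max(p_lo, best[1] - step), min(p_hi, best[1] + step), fine)
        f_grid = grid(max(f_lo, best[2] - step), min(f_hi, best[2] + step), fine)

    sse, p, f, yields = best
    config = replace(base, po_nadh=p, po_fadh2=f)
    residuals = {n: yields[n] - targets[n] for n in targets}
    converged = all(abs(r) <= tolerance for r in residuals.values())
    return CalibrationResult(config, residuals, yields, converged)
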