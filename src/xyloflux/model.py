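"""Core metabolic data model for xylose-route analysis.

The package ships a reduced central-carbon network of *Myceliophthora
thermophila* (EMP glycolysis/gluconeogenesis, pentose phosphate pathway,
TCA cycle, lumped oxidative phosphorylation, a biomass drain) together
with four swappable d-xylose assimilation routes:

* the native fungal *oxo*-reductive route (xylose reductase, xylitol
  dehydrogenase, xylulokinase),
* the non-phosphorylative Weimberg route (XDH -> lactone hydrolysis ->
  xylonate dehydratase -> KdxD -> KGSADH) ending in alpha-ketoglutarate,
* the Dahms branch (KDX aldolase to pyruvate + glycolaldehyde),
* a 1,2,4-butanetriol (BT) production branch (2-keto acid decarboxylase +
  alcohol dehydrogenase), and
* the bacterial isomerase route, for completeness.

Models are plain Python objects plus a TSV reaction grammar; see
:func:`parse_reaction_table`.  Metabolite identifiers follow BiGG-style
tokens with a compartment suffix (``xyl__D_c``, ``akg_c``).
"""

from __future__ import annotations

import copy as _copy
import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "EnergeticsConfig",
    "RouteVariant",
    "BalanceReport",
    "ModelValidationError",
    "ReactionParseError",
    "ROUTE_SUBSYSTEMS",
    "ROUTE_VARIANTS",
    "route_variant",
    "parse_formula",
    "format_formula",
    "parse_equation",
    "format_equation",
    "parse_reaction_table",
    "serialize_reaction_table",
    "serialize_metabolite_table",
    "check_mass_charge_balance",
    "net_pathway_stoichiometry",
    "apply_route",
    "set_energetics",
    "load_core_model",
    "model_to_json",
    "model_from_json",
]

DEFAULT_BOUND = 1000.0

#: Subsystems that are mutually exclusive assimilation-route alternatives.
ROUTE_SUBSYSTEMS = frozenset({"OXORED", "WEIMBERG", "DAHMS", "BT", "ISOMERASE"})

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelValidationError(ValueError):
    """A model or table violates a structural invariant."""


class ReactionParseError(ValueError):
    """A reaction equation or table line could not be parsed."""


def parse_formula(text: str) -> dict[str, float]:
    """Parse an elemental formula string such as ``C5H10O5`` into a map.

    Counts may be non-integer (useful for lumped species); omitted counts
    default to 1.
    """
    text = text.strip()
    if not text:
        return {}
    out: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ModelValidationError(f"malformed formula {text!r}")
        pos = m.end()
        n = float(m.group(2)) if m.group(2) else 1.0
        if n < 0:
            raise ModelValidationError(f"negative count in formula {text!r}")
        out[m.group(1)] = out.get(m.group(1), 0.0) + n
    if pos != len(text):
        raise ModelValidationError(f"malformed formula {text!r}")
    return out


def format_formula(formula: dict[str, float]) -> str:
    def fmt(n: float) -> str:
        if n == 1:
            return ""
        return format(n, "g")

    return "".join(f"{el}{fmt(n)}" for el, n in sorted(formula.items()))


@dataclass
class Metabolite:
    """A chemical species located in a compartment.

    The compartment is encoded as the trailing ``_<token>`` of the id
    (cytosol ``c``, extracellular ``e``, mitochondrion ``m``).
    """

    id: str
    name: str = ""
    formula: dict[str, float] | None = None
    charge: int | None = None

    @property
    def compartment(self) -> str:
        return self.id.rsplit("_", 1)[-1]

    def n_carbon(self) -> float:
        return (self.formula or {}).get("C", 0.0)


@dataclass
class Reaction:
    """Signed stoichiometry over metabolites plus bounds and a gene rule.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed).  Bounds are fluxes in mmol gDW^-1 h^-1.
    ``gene_rule`` is a boolean AND/OR expression over gene ids ("" for
    spontaneous or unannotated reactions).
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gene_rule: str = ""
    subsystem: str = ""
    name: str = ""

    def validate(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise ModelValidationError(
                    f"reaction {self.id}: zero coefficient for {met}"
                )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def genes(self) -> set[str]:
        from .overlay import gene_rule_genes  # local import to avoid a cycle

        return gene_rule_genes(self.gene_rule)


@dataclass
class EnergeticsConfig:
    """Energetic parameters of the lumped respiratory chain and biomass.

    Parameters
    ----------
    po_nadh, po_fadh2 :
        Effective P/O ratios: mol ATP per mol NADH (resp. FADH2)
        oxidized by the lumped oxidative-phosphorylation reactions.
    gam :
        Growth-associated maintenance, mmol ATP per gDW of biomass.
    ngam :
        Non-growth maintenance flux (lower bound on ATP hydrolysis),
        mmol gDW^-1 h^-1.
    nadph_nadh_interconversion :
        Whether a transhydrogenase-like NADPH/NADH interconversion is
        open.  Default True; with it the two pyridine pools are
        energetically equivalent.
    """

    po_nadh: float = 2.5
    po_fadh2: float = 1.5
    gam: float = 40.0
    ngam: float = 0.0
    nadph_nadh_interconversion: bool = True

    def validate(self) -> None:
        if not (self.po_nadh > self.po_fadh2 > 0):
            raise ModelValidationError(
                "energetics require po_nadh > po_fadh2 > 0, got "
                f"po_nadh={self.po_nadh}, po_fadh2={self.po_fadh2}"
            )
        if self.gam < 0 or self.ngam < 0:
            raise ModelValidationError("gam and ngam must be non-negative")


@dataclass
class RouteVariant:
    """A xylose-assimilation scenario: which route subsystems are open.

    Applying a variant closes every reaction whose subsystem is a route
    subsystem not listed in ``enabled_subsystems``, plus any reaction in
    ``disabled_reactions`` (e.g. xylose reductase when emulating the
    Delta-Mtxyl1 strains).
    """

    name: str
    enabled_subsystems: frozenset[str]
    disabled_reactions: frozenset[str] = frozenset()


#: Route scenarios mirroring the engineered strain genotypes: the
#: oxo-reductive baseline, Delta-Mtxyl1 strains overexpressing the Weimberg
#: gene set, the Dahms branch, BT producers, and a bacterial isomerase route.
ROUTE_VARIANTS: dict[str, RouteVariant] = {
    "oxo_reductive": RouteVariant(
        "oxo_reductive", frozenset({"OXORED"})
    ),
    "weimberg": RouteVariant(
        "weimberg", frozenset({"WEIMBERG"}), frozenset({"XYLR"})
    ),
    "dahms": RouteVariant(
        "dahms",
        frozenset({"WEIMBERG", "DAHMS"}),
        frozenset({"XYLR", "KDXD", "KGSADH"}),
    ),
    "bt_production": RouteVariant(
        "bt_production",
        frozenset({"WEIMBERG", "BT"}),
        frozenset({"XYLR", "KDXD", "KGSADH"}),
    ),
    "isomerase": RouteVariant(
        "isomerase", frozenset({"ISOMERASE"})
    ),
}


def route_variant(name) -> RouteVariant:
    """Resolve a route given by name (or pass a RouteVariant through)."""
    if isinstance(name, RouteVariant):
        return name
    try:
        return ROUTE_VARIANTS[name]
    except KeyError:
        raise ModelValidationError(
            f"unknown route {name!r}; known: {sorted(ROUTE_VARIANTS)}"
        ) from None


@dataclass
class StoichiometricModel:
    """Metabolite/reaction collection with an objective.

    Reaction and metabolite order is preserved and meaningful: the
    stoichiometric matrix and the LP layer use it, which keeps solutions
    deterministic.
    """

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)
    parameters: EnergeticsConfig = field(default_factory=EnergeticsConfig)
    id: str = "model"

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        rxn.validate()
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id}")
        for met in rxn.stoichiometry:
            if met not in self.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id} references unknown metabolite {met}"
                )
        self.reactions[rxn.id] = rxn

    def copy(self) -> "StoichiometricModel":
        return _copy.deepcopy(self)

    # -- views ---------------------------------------------------------
    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S matrix, (|metabolites|, |reactions|), plus id orders."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        idx = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met, coef in self.reactions[rid].stoichiometry.items():
                S[idx[met], j] = coef
        return S, met_ids, rxn_ids

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.subsystem == "EXCHANGE"]

    def validate(self) -> None:
        for rxn in self.reactions.values():
            rxn.validate()
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {met}"
                    )
            if rxn.subsystem == "EXCHANGE" and len(rxn.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {rxn.id} must touch exactly one metabolite"
                )
        for rid in self.objective:
            if rid not in self.reactions:
                raise ModelValidationError(
                    f"objective references unknown reaction {rid}"
                )
        for met in self.metabolites.values():
            if met.formula is not None:
                for el, n in met.formula.items():
                    if n < 0:
                        raise ModelValidationError(
                            f"metabolite {met.id}: negative {el} count"
                        )


# ---------------------------------------------------------------------------
# Reaction-equation grammar
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "->")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``"c1 met1 + c2 met2 -> c3 met3"`` into (stoichiometry, reversible).

    Either side may be empty (exchange reactions).  Coefficients are
    mandatory, matching the canonical serialization.
    """
    arrow = None
    for a in _ARROWS:
        if a in text:
            arrow = a
            break
    if arrow is None:
        raise ReactionParseError(f"equation {text!r} lacks an arrow ('->' or '<->')")
    lhs, rhs = text.split(arrow, 1)
    stoich: dict[str, float] = {}

    def consume(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            parts = term.split()
            if len(parts) != 2:
                raise ReactionParseError(
                    f"malformed term {term.strip()!r} in equation {text!r}"
                )
            try:
                coef = float(parts[0])
            except ValueError:
                raise ReactionParseError(
                    f"bad coefficient {parts[0]!r} in equation {text!r}"
                ) from None
            if coef <= 0:
                raise ReactionParseError(
                    f"non-positive coefficient in equation {text!r}"
                )
            met = parts[1]
            stoich[met] = stoich.get(met, 0.0) + sign * coef
            if stoich[met] == 0:
                del stoich[met]

    consume(lhs, -1.0)
    consume(rhs, +1.0)
    if not stoich:
        raise ReactionParseError(f"equation {text!r} has no net stoichiometry")
    return stoich, arrow == "<->"


def format_equation(stoich: dict[str, float], reversible: bool) -> str:
    lhs = [(m, -c) for m, c in stoich.items() if c < 0]
    rhs = [(m, c) for m, c in stoich.items() if c > 0]

    def side(terms):
        return " + ".join(f"{format(c, 'g')} {m}" for m, c in terms)

    arrow = "<->" if reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_RXN_COLUMNS = ["id", "equation", "lb", "ub", "gene_rule", "subsystem"]
_MET_COLUMNS = ["id", "name", "formula", "charge"]


def _split_tsv(text: str, expected: list[str], what: str) -> list[list[str]]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ReactionParseError(f"{what} table is empty (no header)")
    header = lines[0].rstrip("\n").split("\t")
    if header[: len(expected)] != expected:
        raise ReactionParseError(
            f"{what} table header must start with {expected}, got {header}"
        )
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < len(expected):
            fields += [""] * (len(expected) - len(fields))
        rows.append(fields)
    return rows


def parse_reaction_table(
    reactions_tsv: str,
    metabolites_tsv: str | None = None,
    default_bound: float = DEFAULT_BOUND,
    model_id: str = "model",
) -> StoichiometricModel:
    """Build a model from the TSV reaction grammar.

    ``reactions_tsv`` columns: id, equation, lb, ub, gene_rule, subsystem.
    Empty lb/ub fields default from the arrow: ``->`` gives lb = 0 and
    ``<->`` gives lb = -default_bound; ub defaults to +default_bound.

    ``metabolites_tsv`` is the formula sidecar (columns id, name, formula,
    charge).  When provided, every metabolite referenced by an equation
    must appear in it; otherwise metabolites are created without formulas
    and the balance checker will flag them.
    """
    model = StoichiometricModel(id=model_id)
    sidecar: dict[str, Metabolite] = {}
    if metabolites_tsv is not None:
        for row in _split_tsv(metabolites_tsv, _MET_COLUMNS, "metabolite"):
            mid, name, formula, charge = row[:4]
            met = Metabolite(
                id=mid,
                name=name,
                formula=parse_formula(formula) if formula else None,
                charge=int(charge) if charge.strip() else None,
            )
            if mid in sidecar:
                raise ModelValidationError(f"duplicate metabolite id {mid}")
            sidecar[mid] = met

    rows = _split_tsv(reactions_tsv, _RXN_COLUMNS, "reaction")
    for lineno, row in enumerate(rows, start=2):
        rid, equation, lb, ub, gene_rule, subsystem = row[:6]
        try:
            stoich, reversible = parse_equation(equation)
        except ReactionParseError as exc:
            raise ReactionParseError(f"line {lineno}: {exc}") from None
        lower = float(lb) if lb.strip() else (-default_bound if reversible else 0.0)
        upper = float(ub) if ub.strip() else default_bound
        for met in stoich:
            if met in model.metabolites:
                continue
            if metabolites_tsv is not None:
                if met not in sidecar:
                    raise ModelValidationError(
                        f"line {lineno}: reaction {rid} references metabolite "
                        f"{met} absent from the formula sidecar"
                    )
                model.add_metabolite(sidecar[met])
            else:
                model.add_metabolite(Metabolite(id=met))
        rxn = Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=lower,
            upper_bound=upper,
            gene_rule=gene_rule.strip(),
            subsystem=subsystem.strip(),
        )
        if not reversible and rxn.lower_bound < 0:
            raise ModelValidationError(
                f"line {lineno}: irreversible reaction {rid} has negative "
                f"lower bound {rxn.lower_bound}"
            )
        model.add_reaction(rxn)
    model.validate()
    return model


def serialize_reaction_table(model: StoichiometricModel) -> str:
    """Canonical TSV form of the reaction table (inverse of parsing)."""
    lines = ["\t".join(_RXN_COLUMNS)]
    for rxn in model.reactions.values():
        eq = format_equation(rxn.stoichiometry, rxn.reversible)
        lines.append(
            "\t".join(
                [
                    rxn.id,
                    eq,
                    format(rxn.lower_bound, "g"),
                    format(rxn.upper_bound, "g"),
                    rxn.gene_rule,
                    rxn.subsystem,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def serialize_metabolite_table(model: StoichiometricModel) -> str:
    lines = ["\t".join(_MET_COLUMNS)]
    for met in model.metabolites.values():
        lines.append(
            "\t".join(
                [
                    met.id,
                    met.name,
                    format_formula(met.formula) if met.formula is not None else "",
                    "" if met.charge is None else str(met.charge),
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Mass/charge balance
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    """Per-reaction element/charge imbalances.

    ``imbalanced`` maps reaction id -> {element or "charge": residual}.
    Exchange and biomass pseudo-reactions are exempt and listed apart;
    reactions touching a metabolite with no formula are flagged in
    ``missing_formula`` rather than failing.
    """

    imbalanced: dict[str, dict[str, float]] = field(default_factory=dict)
    exempt_exchanges: list[str] = field(default_factory=list)
    exempt_biomass: list[str] = field(default_factory=list)
    missing_formula: dict[str, list[str]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.imbalanced and not self.missing_formula


def check_mass_charge_balance(
    model: StoichiometricModel, tol: float = 1e-6
) -> BalanceReport:
    """Verify element and charge conservation for every checked reaction."""
    report = BalanceReport()
    for rxn in model.reactions.values():
        if rxn.subsystem == "EXCHANGE":
            report.exempt_exchanges.append(rxn.id)
            continue
        if rxn.subsystem == "BIOMASS":
            report.exempt_biomass.append(rxn.id)
            continue
        totals: dict[str, float] = {}
        charge = 0.0
        missing: list[str] = []
        for mid, coef in rxn.stoichiometry.items():
            met = model.metabolites[mid]
            if met.formula is None or met.charge is None:
                missing.append(mid)
                continue
            for el, n in met.formula.items():
                totals[el] = totals.get(el, 0.0) + coef * n
            charge += coef * met.charge
        if missing:
            report.missing_formula[rxn.id] = missing
            continue
        residual = {el: v for el, v in totals.items() if abs(v) > tol}
        if abs(charge) > tol:
            residual["charge"] = charge
        if residual:
            report.imbalanced[rxn.id] = residual
    return report


def net_pathway_stoichiometry(
    model: StoichiometricModel, subsystem: str, tol: float = 1e-9
) -> dict[str, float]:
    """Net stoichiometry of a subsystem run with unit flux per open reaction.

    Internal intermediates of a linear pathway cancel; e.g. the Weimberg
    subsystem collapses to
    ``xylose + NAD+ + NADP+ -> alpha-ketoglutarate + NADH + NADPH + 2 H+``
    with the lactone, xylonate, KDX and the semialdehyde all at zero.
    Reactions closed to flux (bounds (0, 0)), such as the optional
    enzymatic lactonase, do not contribute.
    """
    members = [
        r
        for r in model.reactions.values()
        if r.subsystem == subsystem and not (r.lower_bound == 0 and r.upper_bound == 0)
    ]
    if not any(r.subsystem == subsystem for r in model.reactions.values()):
        raise ModelValidationError(f"subsystem {subsystem!r} absent from model")
    net: dict[str, float] = {}
    for rxn in members:
        for met, coef in rxn.stoichiometry.items():
            net[met] = net.get(met, 0.0) + coef
    return {m: c for m, c in net.items() if abs(c) > tol}


# ---------------------------------------------------------------------------
# Route toggling and energetics
# ---------------------------------------------------------------------------

def apply_route(model: StoichiometricModel, variant) -> StoichiometricModel:
    """Return a copy of ``model`` configured for one assimilation route.

    Reactions in route subsystems not enabled by the variant, and
    reactions named in ``disabled_reactions``, get bounds (0, 0).
    Enabled subsystems keep their curated bounds.  The input model is
    never mutated, and applying the same variant twice is idempotent.
    """
    variant = route_variant(variant)
    unknown = variant.enabled_subsystems - {
        r.subsystem for r in model.reactions.values()
    }
    if unknown:
        raise ModelValidationError(
            f"route {variant.name}: subsystems {sorted(unknown)} absent from model"
        )
    out = model.copy()
    for rxn in out.reactions.values():
        close = rxn.id in variant.disabled_reactions or (
            rxn.subsystem in ROUTE_SUBSYSTEMS
            and rxn.subsystem not in variant.enabled_subsystems
        )
        if close:
            if model.objective.get(rxn.id, 0.0):
                raise ModelValidationError(
                    f"route {variant.name} would disable objective reaction {rxn.id}"
                )
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def set_energetics(
    model: StoichiometricModel, config: EnergeticsConfig
) -> StoichiometricModel:
    """Materialize an :class:`EnergeticsConfig` into the model (in place).

    Rewrites the lumped respiratory reactions
    ``NADH + (1+p) H+ + 1/2 O2 + p ADP + p Pi -> NAD+ + (1+p) H2O + p ATP``
    (and the FADH2 analogue), the transhydrogenase bounds, the
    non-growth maintenance lower bound, and the growth-associated ATP
    cost inside the biomass equation.  Returns the model for chaining.
    """
    config.validate()

    def _oxphos(carrier_red: str, carrier_ox: str, p: float) -> dict[str, float]:
        stoich = {
            carrier_red: -1.0,
            "o2_c": -0.5,
            carrier_ox: 1.0,
        }
        # NADH oxidation consumes one scalar proton; FADH2 carries its own.
        h_base = 1.0 if carrier_red == "nadh_c" else 0.0
        stoich["h2o_c"] = 1.0 + p
        h = h_base + p
        if h:
            stoich["h_c"] = -h
        elif "h_c" in stoich:
            del stoich["h_c"]
        if p:
            stoich["adp_c"] = -p
            stoich["pi_c"] = -p
            stoich["atp_c"] = p
        return stoich

    if "NADHOR" in model.reactions:
        model.reactions["NADHOR"].stoichiometry = _oxphos(
            "nadh_c", "nad_c", config.po_nadh
        )
    if "FADHOR" in model.reactions:
        model.reactions["FADHOR"].stoichiometry = _oxphos(
            "fadh2_c", "fad_c", config.po_fadh2
        )
    if "THD" in model.reactions:
        thd = model.reactions["THD"]
        if config.nadph_nadh_interconversion:
            thd.lower_bound, thd.upper_bound = -DEFAULT_BOUND, DEFAULT_BOUND
        else:
            thd.lower_bound, thd.upper_bound = 0.0, 0.0
    if "ATPM" in model.reactions:
        model.reactions["ATPM"].lower_bound = config.ngam
    if "BIOMASS" in model.reactions:
        bm = model.reactions["BIOMASS"].stoichiometry
        for met, coef in (
            ("atp_c", -config.gam),
            ("h2o_c", -config.gam),
            ("adp_c", config.gam),
            ("pi_c", config.gam),
            ("h_c", config.gam),
        ):
            if coef:
                bm[met] = coef
            else:
                bm.pop(met, None)
    model.parameters = replace(config)
    return model


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def model_to_json(model: StoichiometricModel) -> str:
    """Exact JSON serialization of all model fields (reproducible pipelines)."""
    doc = {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": None if m.formula is None else format_formula(m.formula),
                "charge": m.charge,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule,
                "subsystem": r.subsystem,
            }
            for r in model.reactions.values()
        ],
        "objective": model.objective,
        "parameters": {
            "po_nadh": model.parameters.po_nadh,
            "po_fadh2": model.parameters.po_fadh2,
            "gam": model.parameters.gam,
            "ngam": model.parameters.ngam,
            "nadph_nadh_interconversion": model.parameters.nadph_nadh_interconversion,
        },
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def model_from_json(text: str) -> StoichiometricModel:
    doc = json.loads(text)
    model = StoichiometricModel(id=doc.get("id", "model"))
    for m in doc["metabolites"]:
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                formula=None if m.get("formula") is None else parse_formula(m["formula"]),
                charge=m.get("charge"),
            )
        )
    for r in doc["reactions"]:
        model.add_reaction(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gene_rule=r.get("gene_rule", ""),
                subsystem=r.get("subsystem", ""),
            )
        )
    model.objective = {k: float(v) for k, v in doc.get("objective", {}).items()}
    p = doc.get("parameters", {})
    model.parameters = EnergeticsConfig(
        po_nadh=p.get("po_nadh", 2.5),
        po_fadh2=p.get("po_fadh2", 1.5),
        gam=p.get("gam", 40.0),
        ngam=p.get("ngam", 0.0),
        nadph_nadh_interconversion=p.get("nadph_nadh_interconversion", True),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Shipped core network
# ---------------------------------------------------------------------------

def load_core_model(
    config: EnergeticsConfig | None = None,
    kgsadh_cofactor: str = "nad",
) -> StoichiometricModel:
    """Load the shipped central-carbon core model of *M. thermophila*.

    Parameters
    ----------
    config :
        Energetics to materialize; defaults to :class:`EnergeticsConfig`.
    kgsadh_cofactor :
        Cofactor of 2-ketoglutarate semialdehyde dehydrogenase, ``"nad"``
        (default) or ``"nadp"``.  The NADP variant swaps the pyridine
        couple in the KGSADH reaction.

    The model ships with all route subsystems open; use
    :func:`apply_route` to select a scenario.  The objective defaults to
    the biomass reaction.
    """
    data = resources.files("xyloflux") / "data"
    model = parse_reaction_table(
        (data / "core_reactions.tsv").read_text(),
        (data / "core_metabolites.tsv").read_text(),
        model_id="mthermophila_core",
    )
    model.objective = {"BIOMASS": 1.0}
    if kgsadh_cofactor not in ("nad", "nadp"):
        raise ModelValidationError("kgsadh_cofactor must be 'nad' or 'nadp'")
    if kgsadh_cofactor == "nadp":
        st = model.reactions["KGSADH"].stoichiometry
        st["nadp_c"] = st.pop("nad_c")
        st["nadph_c"] = st.pop("nadh_c")
    set_energetics(model, config or EnergeticsConfig())
    model.validate()
    return model
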