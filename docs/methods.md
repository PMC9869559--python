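# Methods

## The core network

The shipped model (`src/xyloflux/data/core_*.tsv`) is a reduced
central-carbon network of *Myceliophthora thermophila*: 64 reactions and
59 metabolites over two compartments (cytosol `c`, extracellular `e`).
It contains EMP glycolysis/gluconeogenesis, the oxidative and
non-oxidative pentose phosphate pathway, a complete TCA cycle placed in
the cytosolic compartment (the analyses concern a single flux map;
inventing inner-membrane transporters would add parameters without
information), anaplerosis (pyruvate carboxylase, PEP carboxykinase),
lumped oxidative phosphorylation, a transhydrogenase-style NADPH/NADH
interconversion, an ATP-hydrolysis maintenance reaction, a biomass
drain, and five swappable xylose-assimilation subsystems:

| subsystem | content | default |
|---|---|---|
| OXORED | xylose reductase (NADPH), xylitol dehydrogenase (NAD+), xylulokinase | open |
| WEIMBERG | XDH (NADP+) → spontaneous lactone hydrolysis → xylonate dehydratase → KdxD → KGSADH (NAD+) | open |
| DAHMS | KDX aldolase → pyruvate + glycolaldehyde; glycolaldehyde → glycolate (secreted) | open |
| BT | KDX → (2-keto acid decarboxylase) 3,4-dihydroxybutanal + CO2 → (ADH, NADH) 1,2,4-butanetriol | open |
| ISOMERASE | bacterial xylose isomerase | open |

`RouteVariant`s emulate the engineered strain genotypes: selecting the
Weimberg route closes the other route subsystems *and* the xylose
reductase reaction (the Δ*Mtxyl1* background of the Weimberg strains).
Route selection never reopens a curated-closed reaction, so the
enzymatic lactonase alternative (`XYLLACT2`, gene *xylC*) stays off
unless a user opens it; hydrolysis of d-xylonolactone proceeds through
the spontaneous, gene-free reaction by default, consistent with its
known behaviour at neutral pH. The KGSADH cofactor is NAD+ by default
with an NADP+ switch (`load_core_model(kgsadh_cofactor="nadp")`), since
the parent reconstruction's choice is not documented. The isomerase
route has no token in the classical subsystem list; `ISOMERASE` was
added as the minimal extension.

Metabolite identifiers are BiGG-style tokens with a compartment suffix,
and formulas/charges follow the usual pH-7 conventions with one
deliberate exception: **α-ketoglutarate is carried as the neutral
diacid** (C5H6O5, charge 0). Every reaction remains element- and
charge-balanced (the test suite asserts this for all non-exchange,
non-biomass reactions); the choice only fixes the proton bookkeeping so
that the lumped Weimberg equation takes its textbook form

    xylose + NAD+ + NADP+ → α-ketoglutarate + NADH + NADPH + 2 H+

with all four intermediates and all waters cancelling. Protonation
states are a convention, not chemistry the flux analysis can see: no
yield, growth rate, or partition below depends on it.

## Energetics

Oxidative phosphorylation is lumped into two reactions,

    NADH + (1+p) H+ + 1/2 O2 + p ADP + p Pi → NAD+ + (1+p) H2O + p ATP
    FADH2 +    f H+ + 1/2 O2 + f ADP + f Pi → FAD  + (1+f) H2O + f ATP

with effective P/O ratios `p = po_nadh` and `f = po_fadh2` as the only
respiratory parameters; proton-translocation detail is not resolved by
the analyses and lumping keeps the calibration two-dimensional.
`nadph_nadh_interconversion` (default on) opens a reversible
NADPH + NAD+ ⇌ NADP+ + NADH reaction, making the two pyridine pools
energetically equivalent; with it the BT route balances its own redox
(XDH's NADPH covers the ADH step) and the theoretical BT yield reaches
exactly 1 mol/mol xylose.

The parent genome-scale model's P/O and maintenance values are not
published, so `calibrate_energetics` recovers `(p, f)` by a
deterministic nested grid search (steps 0.1 → 0.01 → 0.001, refining one
coarse cell around the incumbent) over p ∈ [1, 3], f ∈ [0.5, 2] with
p > f enforced, minimizing squared error against target yields. Against
the published 26.6 (Weimberg) and 28.3 (*oxo*-reductive) mol ATP/mol
xylose the search lands at p = 2.68, f = 1.58 with zero residual. That
this is exactly solvable is no accident: with interconversion open, the
ATP-maximal strategies reduce to

    Y_weimberg = 2      + 8·p    + 2·f
    Y_oxo      = 10/3   + 25/3·p + 5/3·f

(substrate-level terms plus redox-pair counts; each route liberates 10
redox pairs per xylose in total), and the 2×2 linear system for the two
targets has its unique solution inside the admissible box. The test
suite checks the substrate-level constants independently by running the
yield LP with negligible P/O ratios.

ATP yields are computed with xylose uptake fixed at 1 mmol gDW⁻¹ h⁻¹,
biomass flux and NGAM forced to zero, and every carbon exchange but CO2
closed — a pure yield, not a rate. GAM (40 mmol ATP/gDW) and NGAM
(default 0) only matter for growth simulations.

## Biomass

The biomass drain consumes eleven precursors (G6P, F6P, R5P, E4P, G3P,
3PG, PEP, PYR, AcCoA, OAA, αKG), 11 mmol NADPH and 40 mmol ATP per gDW.
Coefficients start from the classical precursor-demand tables and were
adjusted toward a filamentous-fungus macromolecular composition —
higher hexose-phosphate demand (cell walls of filamentous fungi are
roughly 30–40 % of dry weight, mostly glucan and chitin) and
correspondingly lower pyruvate/acetyl-CoA demand than the bacterial
template — during the calibration pass that fixes the model against the
published flux predictions. With the frozen coefficients the
growth-maximal Weimberg solution routes 64.6 % of PEP consumption into
gluconeogenesis (published value: 64.7 %), while the *oxo*-reductive
solution is purely glycolytic (fraction 0).

Two consumer-accounting decisions behind that number: the
gluconeogenic share is the flux through enolase running in the
PEP → 2PG direction (the unique entry into the PEP → hexose chain); the
denominator is **total** PEP consumption, with pyruvate kinase and
anabolic drains as the other categories. Whether the published fraction
used total consumption or production net of pyruvate kinase is not
stated; total consumption is the assumption here. Cytosolic malic
enzyme is deliberately absent from the core network: it does not appear
on the reduced central-carbon map this model mirrors, and with it the
parsimonious optimum would bypass pyruvate kinase entirely, collapsing
the PEP partition into a near-degenerate statistic.

## Flux analysis

LPs are solved with HiGHS (`scipy.optimize.linprog`); variable order is
the model's reaction order, so solutions are bit-reproducible.
Tolerances: steady state ‖S·v‖∞ ≤ 1e-6 (asserted on every optimal
solution), oracle comparisons at 1e-8 relative. FBA optima are
degenerate in general; reported flux distributions use a parsimonious
tie-break (minimize Σ|v| via variable splitting) that retains the FBA
optimum up to a ~1e-9 relative numerical guard — comfortably above the
99.99 % retention floor the pFBA contract guarantees.

Flux-difference classes between two routes use the map-legend
thresholds with closed boundaries exactly as printed (≥ 4 red,
[2, 4) purple, < 2 black) on absolute differences; "flux difference" is
taken as absolute, not relative, and fluxes are expressed per unit
xylose uptake so they transfer across uptake bases.

## Expression overlay

The package consumes DESeq2-shaped tables (gene_id, log2FoldChange,
padj, baseMean); it does not fit differential expression — adjusted
p-values are taken as given, with no re-adjustment. Classification
boundaries are closed: up iff 2^log2fc ≥ threshold and padj ≤ α.
Gene rules aggregate to reactions by the standard convention — OR
(isozymes) takes the significant branch of maximum |log2fc| (falling
back to the overall maximum when none is significant), AND (complexes)
takes the member of minimum |log2fc| — the publication-style maps do
not state their rule, so this is an explicit assumption, and the
implementation is checked against a brute-force rule evaluator on
random rules. Reactions whose rule touches no measured gene are
`no_data`.

## Synthetic data

`simulate_counts` draws NB(mean μ, variance μ + αμ²) counts for two
groups with planted log2 fold changes and per-sample library factors
log-uniform in [0.7, 1.3]; generators are pure functions of their spec
(seed included). `naive_de_table` summarizes such a matrix with
median-of-ratios normalization and a pooled-variance (moderated)
z-test + BH adjustment — deliberately simple synthetic plumbing whose
job is to make the overlay stage testable offline. Under the reference
conditions (3 samples/group, dispersion 0.05, baseline means ≥ 100) the
median of per-gene estimates over a planted set recovers the planted
log2 fold change within ±0.2, and planted genes are recalled at ≥ 80 %
at the fc ≥ 2, α = 0.05 thresholds; per-gene estimates have a sampling
s.d. near 0.3, so the ±0.2 bound is a statement about the planted-set
aggregate, not individual genes.

What the generator does *not* emulate: batch effects, outlier genes,
gene-specific dispersion trends, and count–length coupling. Passing
tests therefore validate the overlay logic and thresholds, not the
behaviour of a real DE fitter on real libraries.

`simulate_network` builds chain-backbone random networks
(mass-consistent under one-atom synthetic formulas, uptake and secretion
exchanges, nonzero optimum by construction) used to validate the LP
layer against an independent brute-force vertex-enumeration oracle
(`tests/lp_oracle.py`), at sizes (≤ 12 reactions) where enumeration is
exact and cheap.

## Problem sizes and determinism

The shipped analyses are desk-scale by design: the core model solves in
milliseconds, the calibration runs ~2,400 LPs in roughly ten seconds,
and the oracle suite enumerates 50 toy networks. The full test suite
and the acceptance script are deterministic end to end.

## Known limitations

* The core model reproduces headline predictions of a genome-scale
  reconstruction at reduced scale; absolute growth rates are not
  calibrated to measured rates and should be read comparatively. The
  measured growth penalty of the Weimberg strain (−66.7 %) is larger
  than the model's (−28 %), as expected when kinetic limitations (the
  slow lower Weimberg segment) come on top of stoichiometric ones.
* Compartmentation is collapsed; NADH/NADPH shadow prices are therefore
  pool-level statements only.
* The calibrated (p, f) = (2.68, 1.58) are *effective* ratios absorbing
  everything the lumping hides (proton leak, transport costs); they are
  not measurements.
* SBML I/O targets Level 3 + fbc v2; kinetic annotations are ignored.
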