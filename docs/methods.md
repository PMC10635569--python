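# Methods

`bfgem` implements the constraint-based modeling workflow used to build
and interrogate curated genome-scale metabolic models (GEMs) of
anaerobic gut bacteria such as *Bacteroides fragilis*: flux balance
analysis and its variants, assembly of a biomass objective from
macromolecular composition data, calibration of the ATP maintenance
coefficients against observed growth rates, component-driven gap
filling, and the fermentation-oriented analyses (nutrient screens,
product envelopes, carbon accounting, growth efficiency,
co-metabolism/essentiality).

## The constraint-based model

A model is a stoichiometric matrix **S** (metabolite instances ×
reactions) over three compartments — cytosol `c`, periplasm `p`,
extracellular space `e` — with flux bounds `lb ≤ v ≤ ub` in mmol/gDW/h.
Flux balance analysis (FBA) solves the linear program

```
max  c·v   s.t.   S v = 0,   lb ≤ v ≤ ub
```

where the objective is normally the biomass pseudo-reaction, whose flux
is the specific growth rate μ (h⁻¹). Assumptions inherited from the
formalism: steady state for all internal metabolites, no explicit
enzyme capacities or regulation, reversibility encoded purely through
bounds. Exchange pseudo-reactions are written `met_e ⇌ ∅` so negative
flux is uptake; a medium is a map from exchange id to a maximal uptake
rate, applied by setting that exchange's lower bound to `−limit`,
closing all unlisted exchanges to uptake, and opening secretion at
1000 mmol/gDW/h. Default internal bounds are ±1000 (reversible) or
[0, 1000] (irreversible). Charge is not tracked; formulas are element
maps with rational counts, and the pseudo-element `R` denotes a cycled
carrier moiety (tRNA, acyl-carrier protein) with zero mass. The
mass-balance audit requires every element except hydrogen — including
`R` — to balance in every internal reaction; hydrogen is exempt because
protonation state is not modeled.

## Linear programming

All LPs go through SciPy's HiGHS interface with presolve on and a
single deterministic configuration, so repeated runs return bitwise-
identical objective values even when the optimal flux *vector* is
degenerate. Tolerances: LP feasibility is the solver default (~1e-9);
a flux below **1e-6 mmol/gDW/h** counts as zero for "blocked reaction",
"no growth", and essentiality decisions. Infeasible and unbounded
problems are reported as statuses, never silently coerced to zero —
except in growth *prediction* during calibration, where an infeasible
condition is deliberately scored as μ = 0 (maximal error) so the
fitter can traverse infeasible regions of parameter space.

Flux variability analysis (FVA) minimizes and maximizes each reaction
subject to the objective being at least a stated fraction of its
optimum; the 95% growth window used in product envelopes is the
two-sided interval [0.95 μ*, μ*] imposed directly on the biomass
bounds. Blocked reactions are assessed with every exchange opened to
±1000 so only structural gaps, not media, can block flux. Dead-end
metabolites are detected structurally, honouring reversibility; a
metabolite touched by a single reaction is a dead end regardless of
that reaction's reversibility, since it has no partner to cycle with.

Gene knockouts use GPR (gene–protein–reaction) boolean evaluation:
isozymes are OR, complex subunits are AND, and a reaction is closed
(bounds to zero) only when its rule evaluates false under the knockout
set. A flat gene list without operators is read as OR — the
conservative interpretation, since it never over-predicts lethality.
An empty rule means no gene association and is never disabled.

## Biomass assembly

The biomass reaction is built from (i) dry-weight mass fractions per
macromolecular category (protein, lipid, carbohydrate, DNA, RNA), with
any shortfall from 1 treated as the unmeasured cofactor/mineral
remainder; (ii) within-category monomer distributions on an explicit
mass or mole basis (mole-basis tables are converted through the free
monomer's molar mass); and (iii) a carrier map naming, per monomer,
the charged and released carrier species. Incomplete monomer tables
(classically asparagine/glutamine/tryptophan missing from acid-
hydrolysis amino-acid data) are completed by dividing the unmeasured
share equally among the missing monomers; lipid chain-class data are
expanded by dividing each class's share equally among its modeled
representative species.

Coefficients are normalized so one unit of biomass flux draws exactly
1 g of dry weight, computed with **free-monomer** molar masses — the
carrier moiety weighs nothing and is returned, not consumed. The
charged form is consumed and the free carrier released at the same
coefficient, which forces flux through the charging reactions and
charges their ATP cost to growth. Polymerization water loss is
ignored, consistent with the free-metabolite mass rule; this slightly
overcounts monomer mass but keeps the normalization exact and
auditable. Growth-associated maintenance (GAM, mmol ATP/gDW) is added
to the biomass reaction as `GAM ATP + GAM H2O → GAM ADP + GAM Pi +
GAM H`; non-growth maintenance (NGAM, mmol ATP/gDW/h) is a dedicated
hydrolysis reaction whose lower bound pins the drain. Re-installing
maintenance replaces the previous coefficients; the GAM currency
species are recorded on the reaction so downstream producibility
analyses can distinguish them from true precursors.

## Maintenance calibration

GAM and NGAM are fitted by minimizing the **maximum** relative error
between predicted and observed growth rates over a panel of media —
a minimax criterion, so the worst-fitting condition drives the fit.
The search is Nelder–Mead with standard coefficients from the initial
guess (100, 6), termination at simplex tolerance 1e-4 and objective
tolerance 1e-6, with negative parameters repelled by a penalty rather
than hard bounds. An optional grid of restarts re-runs the search and
keeps the best basin, doubling as a uniqueness check; on the synthetic
problems all starts converge to one basin. At least two observations
with distinct energetic demands are required — with one condition the
two coefficients are confounded (one equation, two unknowns). The
mean percent error is reported alongside the minimax error. A
literature "within 20% of observed" band is treated as a post-hoc
check, not a fitting constraint; the minimax objective already drives
errors well below it whenever the data allow.

## Producibility and gap filling

A biomass component is *producible* when a temporary demand reaction
for it can carry more than 1e-6 flux with all exchanges open (or under
a stated medium). Two refinements matter in practice:

- **GAM currency is not a precursor.** ATP/H2O consumed by the
  maintenance term are energetic bookkeeping; they are excluded from
  the component list (they would otherwise be trivially "unproducible"
  in any network where the adenylate pool is conserved).
- **Carrier-charged components are probed as conversions.** The
  carrier moiety is a conserved pool, so a bare demand on an
  amino-acyl-tRNA can never carry flux. The probe used is
  `charged → free carrier`, i.e. the net charging capacity, which is
  the biologically meaningful question.

Gap filling is greedy and count-driven: in each round every candidate
from the universal pool is scored by how many additional biomass
components become producible; the best strictly-improving candidate is
added, ties broken by lexicographic reaction id so runs are
deterministic. Candidates that only enlarge flux magnitudes are never
added. When no single candidate helps, unordered pairs are scored
jointly (serial two-reaction gaps require it), capped at a
configurable pair budget (default 200 evaluations per round).
Minimality is not claimed — the procedure is greedy — but on networks
with a unique single-reaction repair it provably selects exactly that
reaction. Components still unproducible at termination are reported,
not raised. Pool reactions carry no gene rules and are flagged for
downstream evidence review (sequence or literature support), which is
outside this package's scope. A media-conditional mode restricts the
loop's exchanges to a given medium.

## Analysis workflows

Default parameters follow the conventions of curated-anaerobe studies:
per-nutrient uptake 20 mmol/gDW/h in screens, a positive call at
Δμ ≥ 0.01 h⁻¹; product envelopes at the 95% growth window with CO2
always appended to the reported columns; growth efficiency offers
every substrate the same 120 C-mmol/gDW/h of carbon (uptake bound =
120 / carbon count) and reports μ per realized C-mmol; co-metabolism
uses a fermentation-product mixture (acetate, propionate, butyrate,
ethanol, pyruvate exchanges, filtered to those present), an amino-acid
mixture supplied by the caller, caps of 20 mmol/gDW/h (optionally a
separate amino-acid cap, e.g. 0.01 for robustness checks), and an
improvement threshold of 0.001 h⁻¹; supplementation scans add each
carbon-containing exchange at 10 C-mmol/gDW/h and rank the change in
each product's maximum, also reporting the acetate:propionate ratio
shift where both exist. Carbon balance sums carbon over uptaking and
secreting exchanges; at steady state influx minus product efflux is
the carbon fixed into biomass. A product whose pathway is incomplete
maximizes to zero — a phenotype, not an error. Only envelope
*diagonals* are reproducible point values; off-diagonal co-production
entries depend on which optimal vertex the solver returns under
degeneracy and are treated as members of the FVA-feasible range.

## Synthetic study systems

The generator builds a toy anaerobic fermenter mirroring the topology
of a saccharolytic gut bacterium: glucose import (optionally through a
periplasmic step), a lumped glycolysis yielding 2 ATP + 2 pyruvate per
glucose, fermentation exits (acetate with one substrate-level ATP per
pyruvate; lactate and ethanol without), and biosynthesis of three
biomass precursors — an amino acid charged onto a tRNA-like carrier,
a representative lipid, and a cell-wall carbohydrate unit — assembled
into a biomass objective by the package's own builder from a
composition of 55% protein, 25% lipid, 15% carbohydrate and a 5%
unmeasured remainder, with maintenance defaults GAM = 24.9 and
NGAM = 38.9 and a default glucose cap of 20 mmol/gDW/h. Every optimum
is closed-form: in the ATP-limited regime

```
μ = (4U − NGAM) / (GAM + 3a + 6l + 5c)
```

with U the glucose uptake and a, l, c the three biomass coefficients
(the denominator folds the biosynthetic ATP and pyruvate costs into
the growth-associated term). Envelope diagonals have analogous closed
forms. A `supplement_exchanges` variant adds direct amino-acid import
and an acetate-to-lipid assimilation route priced so that glucose
routes stay optimal on minimal medium; it reproduces, in miniature,
the qualitative co-metabolism phenomenology: a carbon-only
fermentation-product mixture cannot raise an ATP-limited optimum (the
cell already spills carbon), while amino-acid import removes a
pyruvate+ATP synthesis cost, raises growth ~30%, and converts the
amino-acid-synthesis gene from essential to dispensable.

What the fixtures do **not** emulate: real pathway content and scale
(thousands of reactions), redundancy structure, realistic P/O or
fermentation stoichiometries, transcriptional effects, or the specific
blocked-reaction census of any curated model. Passing tests therefore
demonstrate correctness of the algorithms and bookkeeping, not
biological accuracy of any particular reconstruction; analyses of a
real model require its distributed file, which the readers accept in
SBML-FBC, COBRA-JSON, and tabular form.

Second-tier fixtures: a 5-reaction linear chain (optimum = 2 × uptake
by construction), a duplicated-step network (degenerate optimum; FVA
must report the full [0, total] range per duplicate), and a capped
rich-branch network (the optimum mixes branches). These are small
enough for an exhaustive vertex-enumeration oracle, which the test
suite and acceptance script use to confirm the LP engine to 1e-8.
Gapped variants remove biosynthesis reactions (preferring removals
that actually orphan a component) and pool them with seeded decoy
reactions over fresh dead-end metabolites that can never help.
Calibration data are generated by the model itself at known (GAM,
NGAM), optionally with seeded multiplicative Gaussian noise; all
randomness is seed-parameterized and identical seeds give identical
fixtures. Fixtures are generated at run time rather than checked in,
so every test also exercises the writers and readers.

## Numerical and design choices

- Stoichiometric coefficients are floats; formula counts are exact
  rationals (fractions admit averaged lipid formulas).
- Degenerate FVA subproblems whose min marginally exceeds their max
  through solver noise are collapsed to the midpoint.
- SBML I/O (Level 3 + FBC v2, via libsbml) carries reaction class as
  SBO terms, gene associations as FBC gene-product trees, and bounds
  as shared parameters; COBRA-JSON carries the class in `notes`;
  the tabular dialect is a two-sheet workbook (or TSV pair) with
  equations in `2 a_c + b_c --> c_c` form. Readers fall back to
  structural classification (an exchange touches one extracellular
  metabolite; a transport spans compartments) when class metadata is
  absent. A best-effort importer accepts common alternative column
  spellings from externally produced workbooks.
- Problem sizes in the shipped tests and acceptance script: micro
  networks of 4–8 reactions for the enumeration oracle, the 26-reaction
  toy fermenter for everything else, three media for calibration.

## Known limitations

No pFBA, MOMA, sampling, dynamic or thermodynamic FBA — the analyses
here need only FBA/FVA. Gene counts are reported as stored in the
model file; pseudogene annotations are not reconstructed. Gap filling
scores producibility counts only, not growth rate, and pairs are the
largest joint addition considered. The `.mat` binary format is not
read; use the SBML, JSON, or spreadsheet distribution of a model.
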