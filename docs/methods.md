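# Methods

`gmnforge` implements the full workflow for building and interrogating an
orthology-derived genome-scale metabolic network (GMN): GPR transfer from a
template organism, compartmentalisation of an uncompartmentalised
database-derived network, metabolite/reaction curation, energy-leak repair,
gap-filling, constraint-based phenotyping, and expression-guided
differential flux analysis. This note records the models, assumptions,
parameter choices and numerical conventions behind each stage, and what the
synthetic validation does and does not demonstrate.

## Constraint-based model and solvers

A model is a stoichiometric matrix S (metabolites × reactions) with flux
bounds lb ≤ v ≤ ub in mmol·gDW⁻¹·h⁻¹, boolean GPR rules, and a biomass
objective. Reversibility is encoded solely by `lower_bound < 0`; there is
no separate flag, so the bounds are the single source of truth. Bounds
omitted by an input file default to ±1000 (reversible) or [0, 1000]
(irreversible), the conventional "unlimited" rate for genome-scale models.

FBA solves max cᵀv s.t. S·v = 0, lb ≤ v ≤ ub with the HiGHS simplex
through `scipy.optimize.linprog`; FVA minimises and maximises each flux
under the same constraints. A reaction is blocked when |v_min| + |v_max| <
10⁻⁵ from FVA. Optimal solutions satisfy ‖S·v‖∞ ≤ 10⁻⁶ and respect bounds
to 10⁻⁹ (asserted in tests). Degenerate optima: the objective value is the
contract; the returned flux vector is an arbitrary optimal vertex, so tests
never assert non-objective fluxes. Matrix construction sorts reaction and
metabolite ids, making repeated runs bit-identical.

Mixed-integer subproblems (gap-filling, ΔFBA consistency maximisation) use
HiGHS through `scipy.optimize.milp` with sparse constraint matrices.

## Orthology transfer

The orthology table carries per-pair DIOPT confidence scores (the number of
prediction tools supporting the pair; 3–15 in practice). Filtering keeps,
per source gene, only the target(s) tied at the maximum score; a gene with
more than nine surviving targets is unspecific and its association is
dropped — but the reaction is kept, because the existence of orthologs is
evidence the reaction occurs in the target organism ("over nine" is read
strictly: exactly nine survivors are legal). GPR leaves are rewritten: one
ortholog substitutes, k orthologs substitute as an OR over the k targets,
and dropped/no-ortholog leaves are deleted from the tree. A reaction whose
every gene lacks any ortholog is removed; non-enzymatic reactions pass
through unchanged.

Deletion semantics inside AND were genuinely open: an AND node that loses a
child keeps its remaining children (the deleted gene is treated as
satisfied), and a node losing all children collapses to the empty rule.
The alternative — treating a lost subunit as absent — would delete every
complex-catalysed reaction with one unmapped subunit, over-constraining a
draft whose purpose is to retain evidenced chemistry; unspecific evidence
should widen, not narrow, the draft.

## Compartmentalisation

Localisation annotations from any number of sources are unioned per gene
(no source ranking), restricted to the compartments declared by the draft
model; genes left empty fall back to predictor output, then to cytosol.
Each reaction is replicated once per compartment in the union of its genes'
compartments, the replica's metabolites re-homed to that compartment and
its GPR pruned to the locally present genes (same pruning semantics as
orthology transfer). Bounds are inherited by replicas. No connecting
transport is added: the compartmentation is deliberately flexible, and
implausible replicas are removed downstream by compartment-insensitive
duplicate screening and leak testing.

## Curation

**Synonymous metabolites.** Each metabolite gets an identifier set:
normalised names (case-folded, punctuation stripped, α/β/γ mapped to
alpha/beta/gamma) plus external ids per namespace (KEGG, ChEBI restricted
to curation rank 3, PubChem, LIPID MAPS). Candidate pairs are classified by
three ordered criteria: (1) a pair sharing an identifier and sharing none
with any third metabolite is merged; (2) in larger connected groups, the
unique pair with the maximum shared-identifier count is merged and the rest
re-examined iteratively; (3) a tie at the maximum flags the tied
metabolites as one ambiguous group — exported for human review, never
auto-merged. Within-model matching never pairs metabolites from different
compartments. Merging rewrites the removed id to the kept id, sums
coefficients when both occur in one reaction, drops zero-sum terms, and
removes (with a log entry) any reaction emptied by the merge; across-model
mode renames only, preparing the second network for merging.

**Duplicate reactions.** The canonical form drops the currency metabolites
H⁺, H₂O and Pi (matched per compartment by a name table, extensible in
config), optionally strips compartments from metabolite keys, and takes the
lexicographically smaller of ±stoichiometry so a reaction equals its exact
reverse. One survivor per group is kept — template provenance preferred
over database provenance, ties lexicographic — with the OR-combined
normalised GPR and the widest bounds in the group; a post-merge assertion
guarantees no gene leaves the model.

## Energy-leak testing

An energy leak is production of a charged cofactor with every uptake
closed. The test sets all exchange lower bounds to ≥ 0 (secretion only),
relaxes any maintenance floor (a forced ATP drain is meaningless without
nutrients and would make the closed problem infeasible), adds a discharge
reaction per cofactor and compartment (ATP + H₂O → ADP + Pi + H⁺;
NAD(P)H → NAD(P)⁺ + H⁺; FADH₂ → FAD + 2H⁺; GTP analogous; optional species
included only where present), and maximises its rate; an optimum above
10⁻⁶ is a leak. The screened list defaults to ATP, NADH, NADPH, FADH₂, GTP
and H⁺. A bare proton has no charged/discharged pair, so it discharges
down the gradient (H⁺[k] → H⁺[c]) — a recorded choice. Localisation takes
the reactions with nonzero FVA range on the leak LP as candidates (capped
at 200), screens single deletions first for interpretability, then tests
every unordered pair; pairs driving the optimum to ≤ 10⁻⁶ are the
authoritative output. Repair itself is advisory-then-manual: the curation
stage removes one member per confirmed duplicated pair.

## Gap-filling

Unproducible biomass precursors are found with temporary per-precursor
sinks. A substrate failing the plain sink test is retested with temporary
sources for the biomass products: conserved-moiety carriers (ATP/ADP-style
pairs consumed and regenerated by biomass) cannot be net-produced by any
mass-balanced network and should only count as unproducible when the
discharged partner cannot be recharged. Repair minimises the *count* of
added reference reactions (one binary per candidate, flux gated by
lb·z ≤ v ≤ ub·z) subject to steady state and biomass ≥ 0.1 with the
model's own bounds respected; plain count minimisation is the recorded
reading of an objective the source tooling leaves unstated. Ties among
equal-size minimal sets are broken toward lexicographically earlier ids by
an infinitesimal (10⁻⁶·rank) objective perturbation, making results
deterministic. Added reactions are imported gene-free with `gapfill`
provenance. A greedy fallback (repeatedly add the candidate with the
largest growth improvement) is exposed and results are labelled
`exact`/`greedy`; minimality of the exact route is verified against
exhaustive subset search for candidate pools ≤ 12.

## Diet, phenotyping and essentiality

The holidic-diet builder turns a composition table into exchange bounds:
with flexible intake the carbon source is capped (default 2.212
mmol·gDW⁻¹·h⁻¹), vitamins at 1/100 of it, remaining substances except
salts and water at 1/10, salts/water unbounded, oxygen at 24; the measured
mode takes uptake rates verbatim from the table. The non-growth-associated
maintenance (NGAM) reaction, when fixed, drains 8.55 mmol ATP·gDW⁻¹·h⁻¹.
Titration curves set one nutrient's maximum uptake per grid point,
optionally pinning the minimum to a fraction of the maximum (a flexible
interval that avoids infeasibility at forced-consumption points);
infeasible points are reported as missing, never as zero growth.

Essentiality screening excludes genes found only in blocked reactions
(they cannot affect biomass), then classifies the rest by single-gene
deletion at a growth-ratio cutoff of 0.3 (the 30% convention). "Unlimited
intake" sets every exchange to 1000. Scoring against a gold standard
tallies TP/FP/TN/FN over genes with known labels; unknown-label genes are
counted separately as unclassified and excluded from every denominator.
Metrics (sensitivity, specificity, precision, accuracy, F1, MCC) are
reported to two decimals with round-half-even; a zero denominator yields
"undefined", never 0.

## ΔFBA

Probe-level expression is filtered at p < 0.01, aggregated per gene (any
probe ≥ 1.5 → max, assuming up-regulation; any probe ≤ 0.67 → min; all
moderate or conflicting → mean) and mapped to reactions through GPR logic:
min over AND (a complex is limited by its scarcest subunit), max over OR
(isozymes add), with unmeasured children skipped and fully unmeasured
reactions left uncalled. Before mapping, exchange bounds are opened to
±1000 so the difference polytope is not artificially clipped.

Δv is the difference of two steady-state flux vectors, hence S·Δv = 0 with
Δv ∈ [lb−ub, ub−lb] per reaction and Δv = 0 for the NGAM reaction
(maintenance assumed unchanged between conditions). Step 1 maximises the
number of called reactions with sign-consistent Δv of magnitude ≥ ε;
step 2 fixes that count and minimises Σ|Δv| over the *uncalled* reactions
(consistent called reactions stay unconstrained in magnitude — the
"minimise inconsistency" reading; swappable via config). Regulated sets
threshold at |Δv| > 0.1% of the largest bound (1.0 at default bounds); ε
defaults to that same threshold, the only magnitude scale the method
states, so a consistent reaction clears the reporting threshold by
construction. Unmeasured reactions are uncalled and enter the step-2
parsimony term.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (parameters, seed); the planted truth
(essential genes, synonym pairs, leak pair, regulation directions,
orthology ambiguities) is recoverable by the corresponding stage.

The template emulates a compartmentalised sterol-auxotroph network at
deliberately small scale (default 4 pathways × 3 compartments, 38
reactions): a capped carbon source (10 mmol·gDW⁻¹·h⁻¹ on the rich medium),
lumped aerobic respiration as the sole ATP source, NGAM at 8.55, linear
biosynthetic chains feeding a biomass reaction (20 ATP per unit growth),
a sterol-derived precursor producible only from dietary sterol, an
aspartate-like precursor available both from the diet and by de novo
synthesis, and one structurally blocked reaction whose gene must be
excluded from essentiality calls. GPR shapes (single gene, AND-complex,
OR-isozymes, mixed) are drawn per pathway step from the seed, and a gene
is truth-essential iff it is required by the sole route to some biomass
precursor. The de novo aspartate-analog synthesis refixes respiratory CO₂
with unlimited nitrogen, so it does not compete for the limiting carbon —
this is the deliberate abstraction that makes dietary depletion exactly
growth-neutral, at the cost of lumping the carbon skeleton.

The leaky variant adds a two-reaction ATP-generating cycle (a spurious
carrier reduction feeding a duplicated oxidative-phosphorylation step),
emulating the incorrectly compartmentalised duplicates that real merges
produce. The gap fixture severs the middle step of one or more pathways.
Expression fixtures draw regulated fold changes log-uniformly from
[1.5, 4] (up) and [0.25, 0.67] (down) with p uniform in (0, 0.01), include
multi-probe genes exercising every aggregation rule and
strong-but-insignificant probes exercising the p-filter. The default
planted regulation (one chain up, the de novo aspartate branch down) is
chosen to be stoichiometrically recoverable; planting opposite directions
on two biomass-coupled chains is structurally unrecoverable because
biomass stoichiometry ties all chains to one growth difference — the test
suite asserts this as a property of the method, not a defect.

Passing on these fixtures demonstrates algorithmic correctness —
recovery of planted structure under clean, fully observed conditions. It
does not demonstrate robustness to the noise sources of real
reconstructions: annotation errors, incomplete orthology, name chaos
beyond the planted synonyms, thermodynamically infeasible loops subtler
than a two-reaction cycle, or microarray normalisation artifacts
(expression fixtures supply fold changes and p-values directly;
preprocessing is out of scope).

## Problem sizes and determinism

Validation runs use the default template (≈40 reactions), candidate pools
≤ 12 for exhaustive gap-fill comparison, ≤ 6-reaction random networks for
vertex-enumeration FBA oracles, and ≤ 8-gene GPR trees for exhaustive
truth tables — sizes at which every independent oracle is exact. Solver
inputs are built from sorted id lists, generators accept explicit seeds,
and the acceptance script derives all randomness from its `--seed`
argument, so every reported number is reproducible bit-for-bit.

## Known limitations

- SBML I/O targets Level 3 + fbc (plus a notes-field GPR fallback); MAT
  format and annotation-rich SBML extensions are out of scope.
- The synonym matcher is identifier-driven; structure-based (InChI)
  matching is not attempted, and name normalisation is validated only on
  the synthetic fixtures.
- Gap-filling optimises cardinality, not biological plausibility weights.
- ΔFBA's step-2 norm and ε are config-exposed conventions; other
  published variants weight consistency or penalise called reactions
  differently.
- The double-deletion leak localiser is O(candidates²) LPs and caps the
  candidate set at 200; genome-scale leak hunting needs the pre-filter.
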