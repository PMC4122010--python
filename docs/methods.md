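# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `gutflux`, in the spirit of the methods documentation that
accompanies constraint-based and simulation packages.

## Flux balance analysis

A metabolic model is a stoichiometric matrix **S** (metabolites ×
reactions), flux bounds per reaction in mmol·gDW⁻¹·h⁻¹, boolean
gene–protein–reaction (GPR) rules, and one biomass pseudo-reaction whose
flux is the growth rate (h⁻¹). FBA solves `max cᵀv s.t. S·v = 0,
lb ≤ v ≤ ub` with HiGHS (`scipy.optimize.linprog`). Assumptions: steady
state (no metabolite accumulation), a single cellular objective (biomass),
and capacity/directionality expressed entirely through bounds.

Energy parameters follow the iAF1260 convention: growth-associated ATP
maintenance (GAM, 59.81 mmol ATP per gDW) is embedded in the biomass
stoichiometry; non-growth maintenance (NGAM) is a fixed lower bound of
8.39 mmol·gDW⁻¹·h⁻¹ on the ATP-hydrolysis reaction `ATPM`; the effective
P/O ratio is implied by the electron-transport stoichiometry (proton-
pumping NADH dehydrogenase + cytochrome bd oxidase + 4 H⁺/ATP synthase,
≈ 1.25 ATP per NADH).

Numerical choices: LP primal/dual feasibility 1e−9; reported flux vectors
are guaranteed to satisfy |S·v|∞ ≤ 1e−6 and bounds to ±1e−9; a reaction is
"blocked" when |v| < 1e−9. Degenerate alternate optima are real: `solve_fba`
returns one optimal vertex, and only the objective value (plus any flux
whose FVA interval collapses) is solver-independent. Tests and downstream
analyses respect this.

### Media

A medium is a map *exchange reaction → maximum uptake rate* plus an aerobic
flag. Applying a medium sets the listed exchanges' lower bounds to −uptake,
closes every other carbon-bearing exchange for uptake (carbon content is
read from metabolite formulas), and sets the oxygen exchange lower bound to
−18 mmol·gDW⁻¹·h⁻¹ (aerobic) or 0 (anaerobic) unless oxygen is listed
explicitly. Secretion is never restricted by a medium. Negative exchange
flux is uptake throughout the package.

### FVA, robustness

FVA first computes the FBA optimum μ\*, then per reaction solves min and
max of that flux subject to cᵀv ≥ f·μ\* (default f = 1.0, with an absolute
slack of 1e−9 so the optimal face is numerically non-empty). Directionality
classes: forward (min ≥ 0 < max), reverse (min < 0 ≥ max), bidirectional
(min < 0 < max), blocked (both within 1e−9 of zero). Robustness scans fix
one reaction's flux at evenly spaced points across its objective-free
feasible range and re-solve FBA, reporting infeasible points as such.

## Uniform flux sampling

Sampling uses artificial-centering hit-and-run (ACHR). Warmup points are
optimal vertices of LPs with standard-normal random objectives (2·n by
default); the chain starts at their centroid, which is interior to every
non-degenerate facet. Each step draws a stored point, forms the direction
to the running center, projects it onto the null space of S (computed once
by SVD) so mass balance is preserved exactly, computes the feasible chord
within the bounds, and jumps to a uniform point on the chord. Every
`thinning`-th point (default 100) is recorded; recorded points also enter
the direction pool (classic ACHR). One integer seed drives warmup and
chain; identical seeds give bit-identical sample matrices.

Two numerical details matter. First, direction components smaller than
1e−12 in magnitude are excluded from the chord ratio tests: they are
projection dust on structurally fixed fluxes, and treating them as real
directions would pin every chord at zero length. Second, the chord is
computed against bounds widened by 1e−7; this keeps dust components at
bound-tight coordinates from blocking movement while bounding any excursion
at 1e−7 absolute (excursions do not accumulate because directions are never
modified — mass-balance residuals stay at ~1e−11 over 10⁶ steps). Biomass
is *not* constrained during sampling by default (the whole solution space
is characterised, not the optimal face); `at_optimum_fraction` optionally
adds cᵀv ≥ f·μ\*.

The sample count, thinning and the unconstrained-growth default are
assumptions of this package, exposed as parameters.

Pearson correlations between sampled fluxes are reported per reaction pair;
a constant flux gives an explicitly undefined correlation rather than NaN.

## Context-specific extraction (GIMME, iMAT)

Both algorithms start from per-reaction evidence obtained by evaluating the
GPR over per-gene scores (AND = min, OR = max; genes missing from a profile
count as absent; reactions without a GPR are always retained). Binary 0/1
presence profiles are the primary use case.

**GIMME** (LP): minimise Σ (threshold − evidence)·|v| over reactions with
evidence below the threshold (default 0.5), subject to mass balance, bounds
and biomass ≥ growth_fraction · pan-optimum (default 0.9). |v| is
linearised by splitting into v⁺ − v⁻. Below-threshold reactions with zero
flux (|v| < 1e−9) in the minimiser are removed; below-threshold reactions
that must carry flux are retained and reported as *inconsistent* (evidence
says absent, growth says needed). When the optimal penalty is exactly zero
— the case for growth-dispensable accessory reactions — every penalised
flux is zero in all optima, so the removal set is solver-independent and no
tie-breaking is needed; for nonzero optimal penalties the removal set is
that of the (deterministic) HiGHS minimiser.

**iMAT** (MILP, HiGHS via `scipy.optimize.milp`): maximise the number of
high-evidence reactions with |v| ≥ ε (default ε = 1.0, two binaries per
reaction for forward/reverse activity with big-M equal to the reaction
bounds) plus the number of low-evidence reactions forced to zero (one
binary each). Low-evidence reactions whose inactivity indicator is set at
the optimum are removed. This implementation adds a biomass floor at
`growth_fraction` of the pan optimum — a design choice so that extracted
models are growth-feasible by construction rather than by post-hoc
validation; set `growth_fraction=0` for the textbook behaviour. A guard
refuses problems above 10⁴ binary variables.

After removal, metabolites appearing in no remaining reaction are dropped;
"non-shared metabolites" in model comparisons are defined on the resulting
metabolite sets. Model comparison reports, per model, reactions present in
it and absent from *all* others, the union of their GPR genes, metabolites
outside the all-model intersection, and subsystem tallies.

## Strain profiling

Alignments are ingested from tabular BLAST (outfmt 6) or SAM (identity from
the NM tag). Coordinates are 1-based inclusive on ingestion and converted
to 0-based half-open internally; that conversion is the single boundary
between conventions. Subject intervals are strand-normalised (start ≤ end);
gene overlap is strand-agnostic.

Filtering keeps alignments with identity ≥ 99 % (inclusive), then drops
every query retaining more than one alignment — multi-mappers are discarded
outright, without bitscore rescue (the conservative reading of "aligned
onto only a single position"). Depth is Σ aligned bases / genome length;
breadth is the fraction of positions covered at least once (interval
union). The presence verdict uses **depth** ≥ 10 (boundary inclusive);
breadth is reported alongside for transparency, since a fold-coverage
criterion phrased against genome size supports the depth reading. Gene
coverage is the best *single-scaffold* covered fraction (merged intervals
per scaffold; two scaffolds covering half each do not combine), with the
covered flag at fraction ≥ 0.8.

Enrichment uses the one-sided Fisher exact test (upper hypergeometric
tail), computed with log-gamma sums and `logsumexp` so p-values far below
float underflow remain finite in log space; `enrichment_test` returns the
plain p, `enrichment_log_pvalue` its natural log.

## Diet response

A diet condition opens exactly one carbon exchange (acetate, ethanol,
glucose or succinate; default uptake 9 mmol·gDW⁻¹·h⁻¹) aerobically or
anaerobically. Between two optimal flux vectors, a reaction is
*diet-stressed* when its flux changes by more than ±10 %:
|flux_x| > 1.1·|flux_y| or |flux_x| < 0.9·|flux_y|. The ratio is undefined
at zero, so the closure is: both fluxes below 1e−9 → not stressed; exactly
one zero → stressed; a sign reversal between nonzero fluxes → stressed (a
reaction running backwards is more than a 10 % change under any reading).
The criterion is applied to magnitudes and is invariant under positive
rescaling of both vectors. Because single FBA vertices are degenerate,
`robust_condition_fluxes` offers FVA-midpoint vectors as a
degeneracy-insensitive alternative input. Stress genes are the union of GPR
leaves over stressed reactions.

## Synthetic data

The generators define the test conditions; all are deterministic under a
seed.

*Toy networks* (chain, parallel, diamond, cycle; ≤ 8 reactions) carry a
closed-form optimum computed from their own capacities (chain: min along
the path; parallel: capped branch sum; diamond: sum of arm bottlenecks;
cycle: chain optimum, with a reversible 2-cycle exercising bidirectional
FVA classes). They anchor the solver against an independent brute-force
vertex-enumeration oracle.

*Core fixture*: a hand-curated, deterministic ~70-reaction, 63-metabolite
core *E. coli* metabolism — glycolysis/gluconeogenesis, pentose-phosphate
pathway, TCA cycle with glyoxylate shunt, anaplerosis, acetate/ethanol/
lactate/formate fermentation, proton-translocating oxidative
phosphorylation, ammonium assimilation, and a lumped biomass reaction with
GAM. It is curated in source code (not a data file) so scenario tests can
rely on stable reaction ids (ACS, PTAr, ACKr, PGK, PGL, GND, RPI). Default
medium: glucose 10, oxygen 18, aerobic. By construction it grows
aerobically on all four carbon sources, ferments glucose anaerobically
(slower than aerobically), and cannot meet maintenance ATP on acetate
without oxygen. Simplifications relative to a genome-scale model: lumped
acetyl-CoA synthetase (AMP cost folded into 2 ATP→ADP), one respiratory
chain, no biosynthesis subsystems beyond the biomass lump — so absolute
growth rates are fixture-specific even though the qualitative orderings
(glucose best, aerobic > anaerobic) are the biologically expected ones.

*Pan-genome models*: the core fixture plus accessory reactions, each gated
by a distinct synthetic gene; even-indexed accessories are
energy-forfeiting bypasses between core metabolites, odd-indexed ones drain
into a novel dead-end metabolite. Dispensability is enforced at build time
by asserting that the pan optimum equals the core optimum, which makes the
GIMME/iMAT removal sets well-posed and the planted strain models exactly
recoverable. Strains carry each accessory gene independently with
probability 0.5.

*Alignment cohorts*: 100-bp reads tile the genome cyclically so summed
aligned length is exactly depth × genome length (boundary depths like 10.0
are hit exactly); identity is constant per cohort; a strain with prevalence
p occurs in exactly round(p·n) samples. This emulates coverage structure
only — no sequence content, no error model, no multi-mapping ambiguity —
so passing recovery tests demonstrates threshold logic, not aligner
robustness on real reads.

## Pipeline

`gutflux run config.yaml` executes simulate → detect → extract → compare →
fba → fva → sample → diet, writing per-stage TSV/JSON outputs and a
manifest with checksums and timings. Re-runs with an unchanged
configuration skip completed stages (idempotence); a stage failure aborts
naming the stage and keeps partial outputs. The report renderer emits
markdown tables per stage and omits sections whose stage did not run. All
thresholds (identity 99, depth 10, gene fraction 0.8, stress band 0.9/1.1,
FVA fraction 1.0, GIMME/iMAT parameters) live in the config with those
defaults.

## Problem sizes used in tests

The test suite and the acceptance script run at desk scale by design: toy
networks ≤ 8 reactions (100 random instances against the vertex oracle),
the ~70-reaction core fixture for FVA/sampling/diet properties, 5,000
sampler draws, 20 seeded pan-genome models (×3 strains) for the
GIMME-vs-iMAT property, and a 10-sample planted cohort on 50-kb genomes for
strain calling. These sizes give exact, reproducible oracles; they are not
genome-scale benchmarks.

## Known limitations

- One optimal vertex is returned under degeneracy; analyses needing unique
  fluxes should use FVA intervals or sampling means.
- No parsimonious FBA, loopless FVA or thermodynamic constraints; internal
  2-cycles (e.g. succinate dehydrogenase / fumarate reductase) can carry
  arbitrary bounded circulation, which FVA reports honestly as
  bidirectional.
- The SBML reader covers the constraint-based subset (Level 2 with
  GENE_ASSOCIATION notes, Level 3 with fbc); kinetic laws, events and unit
  definitions beyond the mmol·gDW⁻¹·h⁻¹ convention are ignored.
- iMAT's MILP is exact but desk-scale; genome-scale extractions should use
  GIMME or raise the binary-variable guard consciously.
- Sampling uniformity is verified distributionally only on cases with
  closed-form marginals; on general polytopes ACHR's mixing is assumed, not
  certified.
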