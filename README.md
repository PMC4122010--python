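# gutflux

Constraint-based metabolic analysis of *Escherichia coli* strains in the
human gut microbiome. The package covers the full workflow from metagenome
alignments to simulated phenotypes:

1. **Strain detection** — call strain presence from read alignments
   (BLAST tabular or SAM) using an identity filter (default 99 %),
   a uniqueness filter, and a fold-coverage threshold (default 10×);
   score gene coverage by the best single scaffold (default 80 % of gene
   length) and test enrichment with a one-sided Fisher exact test computed
   in log space.
2. **Strain-specific model extraction** — derive each strain's metabolic
   network from a pan-genome model using gene presence profiles, with two
   algorithms: GIMME (linear programming) and iMAT (mixed-integer linear
   programming). Networks are compared for strain-specific reactions,
   catalysing genes and non-shared metabolites.
3. **Phenotype simulation** — flux balance analysis (FBA), flux
   variability analysis (FVA), robustness scans, uniform flux sampling
   (artificial-centering hit-and-run) with pairwise flux correlations, and
   growth simulation across carbon sources (acetate, ethanol, glucose,
   succinate) with detection of diet-stress reactions whose optimal flux
   changes by more than ±10 % between conditions.

It is aimed at microbiome researchers who want these analyses as a tested,
scriptable library rather than a collection of one-off scripts.

## The model

FBA predicts steady-state fluxes **v** (mmol·gDW⁻¹·h⁻¹) by solving the
linear program

```
max  cᵀv     s.t.   S·v = 0,   lb ≤ v ≤ ub
```

where **S** is the stoichiometric matrix, the bounds encode enzyme
capacities, directionality and the growth medium (negative exchange flux =
uptake), and **c** selects the biomass pseudo-reaction whose flux is the
growth rate μ (h⁻¹). FVA reports, per reaction, min/max flux subject to
cᵀv ≥ f·μ\*; sampling draws near-uniform points of the polytope with a
hit-and-run Markov chain. GIMME minimises Σ penalty·|v| over low-evidence
reactions subject to biomass ≥ f·μ\*; iMAT maximises the count of
high-evidence reactions carrying flux (|v| ≥ ε) plus low-evidence reactions
shut off. All linear and integer programs are solved with HiGHS via SciPy.

Everything is exercisable without downloads: `gutflux.synthetic_data`
builds toy networks with closed-form optima, a hand-curated ~70-reaction
core *E. coli* metabolism (glycolysis, pentose-phosphate pathway, TCA cycle
with glyoxylate shunt, fermentation, oxidative phosphorylation), pan-genome
models with planted strain profiles, and alignment cohorts with planted
depth/identity/prevalence.

## Worked example

```python
from gutflux.synthetic_data import make_core_fixture
from gutflux.constraint_analysis import Medium, apply_medium, solve_fba

model = make_core_fixture()
for source in ("EX_glc__D_e", "EX_succ_e", "EX_etoh_e", "EX_ac_e"):
    grown = apply_medium(model, Medium(exchanges={source: 9.0}, aerobic=True))
    print(source, round(solve_fba(grown).objective_value, 4))
anaerobic = apply_medium(model, Medium(exchanges={"EX_glc__D_e": 9.0}, aerobic=False))
print("glucose anaerobic", round(solve_fba(anaerobic).objective_value, 4))
```

prints

```
EX_glc__D_e 0.7408
EX_succ_e 0.3591
EX_etoh_e 0.2916
EX_ac_e 0.1517
glucose anaerobic 0.2233
```

— growth rates (h⁻¹) at 9 mmol·gDW⁻¹·h⁻¹ uptake: glucose supports the
fastest growth of the four carbon sources, and closing the oxygen exchange
cuts glucose growth to fermentative levels, both expected behaviours for
gut *E. coli*.

The same computations drive the command line:

```sh
gutflux simulate-data core --out-dir demo
gutflux fba demo/core_model.json --out demo/fluxes.tsv
gutflux fva demo/core_model.json --out demo/fva.tsv
gutflux diet demo/core_model.json --out-dir demo
gutflux sample demo/core_model.json --n 1000 --seed 42 --out demo/samples.tsv
gutflux run config.yaml          # full pipeline with manifest + report
```

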