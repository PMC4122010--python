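"""Synthetic inputs for every pipeline stage.

Four generator families, all deterministic under their seed:

* toy stoichiometric networks (chain / parallel / diamond / cycle) with a
  closed-form FBA optimum,
* a hand-curated core *E. coli* metabolism fixture (~70 reactions:
  glycolysis, pentose-phosphate, TCA + glyoxylate shunt, fermentation,
  oxidative phosphorylation) with exchanges for glucose, acetate, ethanol,
  succinate and oxygen and a lumped biomass objective,
* pan-genome models: the core fixture plus growth-dispensable accessory
  reactions gated by distinct genes, with per-strain presence profiles and
  the planted strain models they imply,
* alignment tables (BLAST outfmt-6 layout) with planted per-sample depth,
  identity and prevalence, for strain-calling recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import GPRRule, MetabolicModel, Metabolite, Reaction, parse_gpr
from .constraint_analysis import solve_fba

__all__ = [
    "ToySpec",
    "PlantedCohort",
    "PlantedStrain",
    "make_toy_model",
    "make_core_fixture",
    "make_pan_with_strains",
    "make_alignments",
    "make_scaffold_alignments",
    "BLAST6_COLUMNS",
]


# ---------------------------------------------------------------------------
# Toy networks with analytic optima
# ---------------------------------------------------------------------------


@dataclass
class ToySpec:
    topology: str = "chain"  # chain | parallel | diamond | cycle
    n_reactions: int = 3
    uptake: float = 10.0
    reversible_internal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("chain", "parallel", "diamond", "cycle"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")


def _met(i: int) -> Metabolite:
    return Metabolite(id=f"m{i}", name=f"metabolite {i}", compartment="c")


def make_toy_model(spec: ToySpec) -> tuple[MetabolicModel, float]:
    """Build a toy network and return it with its closed-form FBA optimum.

    * chain: source → m1 → … → m_n → sink; optimum = min of all capacities.
    * parallel: n branches m1 → m2, each with its own capacity; optimum =
      min(uptake, Σ branch capacities, demand capacity).
    * diamond: two 2-step arms from m1 to m4; optimum = min(uptake,
      Σ arm bottlenecks, demand).
    * cycle: a chain whose middle metabolite carries a reversible 2-cycle
      (two opposing reversible reactions), exercising the bidirectional FVA
      class without changing the optimum.
    """
    rng = np.random.default_rng(spec.seed)
    rev_lb = -1000.0 if spec.reversible_internal else 0.0
    rxns: list[Reaction] = []
    mets: list[Metabolite] = []

    def cap() -> float:
        return float(np.round(rng.uniform(1.0, 20.0), 3))

    if spec.topology == "chain":
        n = spec.n_reactions
        mets = [_met(i) for i in range(1, n + 2)]
        rxns.append(Reaction("EX_src", stoichiometry={"m1": 1.0},
                             lower_bound=0.0, upper_bound=spec.uptake))
        caps = [cap() for _ in range(n)]
        for i in range(n):
            rxns.append(Reaction(f"C{i + 1}",
                                 stoichiometry={f"m{i + 1}": -1.0, f"m{i + 2}": 1.0},
                                 lower_bound=rev_lb, upper_bound=caps[i]))
        rxns.append(Reaction("DM_sink", stoichiometry={f"m{n + 1}": -1.0},
                             lower_bound=0.0, upper_bound=1000.0,
                             objective_coefficient=1.0))
        optimum = min([spec.uptake] + caps)

    elif spec.topology == "parallel":
        n = spec.n_reactions
        mets = [_met(1), _met(2)]
        rxns.append(Reaction("EX_src", stoichiometry={"m1": 1.0},
                             lower_bound=0.0, upper_bound=spec.uptake))
        caps = [cap() for _ in range(n)]
        for i in range(n):
            rxns.append(Reaction(f"B{i + 1}", stoichiometry={"m1": -1.0, "m2": 1.0},
                                 lower_bound=rev_lb, upper_bound=caps[i]))
        demand = cap() + 10.0
        rxns.append(Reaction("DM_sink", stoichiometry={"m2": -1.0},
                             lower_bound=0.0, upper_bound=demand,
                             objective_coefficient=1.0))
        optimum = min(spec.uptake, sum(caps), demand)

    elif spec.topology == "diamond":
        mets = [_met(i) for i in range(1, 5)]
        rxns.append(Reaction("EX_src", stoichiometry={"m1": 1.0},
                             lower_bound=0.0, upper_bound=spec.uptake))
        a1, a2, b1, b2 = cap(), cap(), cap(), cap()
        rxns.append(Reaction("A1", stoichiometry={"m1": -1.0, "m2": 1.0},
                             lower_bound=rev_lb, upper_bound=a1))
        rxns.append(Reaction("A2", stoichiometry={"m2": -1.0, "m4": 1.0},
                             lower_bound=rev_lb, upper_bound=a2))
        rxns.append(Reaction("B1", stoichiometry={"m1": -1.0, "m3": 1.0},
                             lower_bound=rev_lb, upper_bound=b1))
        rxns.append(Reaction("B2", stoichiometry={"m3": -1.0, "m4": 1.0},
                             lower_bound=rev_lb, upper_bound=b2))
        rxns.append(Reaction("DM_sink", stoichiometry={"m4": -1.0},
                             lower_bound=0.0, upper_bound=1000.0,
                             objective_coefficient=1.0))
        optimum = min(spec.uptake, min(a1, a2) + min(b1, b2))

    else:  # cycle
        mets = [_met(i) for i in range(1, 4)]
        rxns.append(Reaction("EX_src", stoichiometry={"m1": 1.0},
                             lower_bound=0.0, upper_bound=spec.uptake))
        c1, c2 = cap(), cap()
        rxns.append(Reaction("C1", stoichiometry={"m1": -1.0, "m2": 1.0},
                             lower_bound=0.0, upper_bound=c1))
        rxns.append(Reaction("C2", stoichiometry={"m2": -1.0, "m3": 1.0},
                             lower_bound=0.0, upper_bound=c2))
        # opposing reversible pair: a 2-cycle carrying arbitrary circulation
        rxns.append(Reaction("L1", stoichiometry={"m2": -1.0, "m3": 1.0},
                             lower_bound=-10.0, upper_bound=10.0))
        rxns.append(Reaction("L2", stoichiometry={"m3": -1.0, "m2": 1.0},
                             lower_bound=-10.0, upper_bound=10.0))
        rxns.append(Reaction("DM_sink", stoichiometry={"m3": -1.0},
                             lower_bound=0.0, upper_bound=1000.0,
                             objective_coefficient=1.0))
        optimum = min(spec.uptake, c1)  # L1/L2 also forward-carry m2→m3

    model = MetabolicModel(id=f"toy_{spec.topology}_{spec.seed}",
                           metabolites=mets, reactions=rxns)
    return model, float(optimum)


# ---------------------------------------------------------------------------
# Core metabolism fixture
# ---------------------------------------------------------------------------

# (id, name, formula) — external species carry formulas so media handling can
# recognise carbon sources; internal bookkeeping species stay formula-free.
_CORE_METS_E = [
    ("glc__D_e", "D-Glucose", "C6H12O6"),
    ("ac_e", "Acetate", "C2H3O2"),
    ("etoh_e", "Ethanol", "C2H6O"),
    ("succ_e", "Succinate", "C4H4O4"),
    ("lac__D_e", "D-Lactate", "C3H5O3"),
    ("for_e", "Formate", "CHO2"),
    ("o2_e", "O2", "O2"),
    ("co2_e", "CO2", "CO2"),
    ("h2o_e", "H2O", "H2O"),
    ("h_e", "H+", "H"),
    ("pi_e", "Phosphate", "HO4P"),
    ("nh4_e", "Ammonium", "H4N"),
]
_CORE_METS_C = [
    "glc__D", "g6p", "f6p", "fdp", "dhap", "g3p", "13dpg", "3pg", "2pg",
    "pep", "pyr", "6pgl", "6pgc", "ru5p__D", "r5p", "xu5p__D", "s7p", "e4p",
    "accoa", "coa", "cit", "icit", "akg", "succoa", "succ", "fum", "mal__L",
    "oaa", "glx", "ac", "actp", "acald", "etoh", "lac__D", "for",
    "nad", "nadh", "nadp", "nadph", "atp", "adp", "pi", "h", "h2o", "o2",
    "co2", "nh4", "q8", "q8h2", "glu__L", "gln__L",
]

# (id, name, stoichiometry, lb, ub, subsystem, gpr, objective)
_CORE_RXNS: list[tuple] = [
    # exchanges — default medium: glucose 10, oxygen 18, aerobic
    ("EX_glc__D_e", "D-Glucose exchange", {"glc__D_e": -1}, -10.0, 1000.0, "Exchange", ""),
    ("EX_ac_e", "Acetate exchange", {"ac_e": -1}, 0.0, 1000.0, "Exchange", ""),
    ("EX_etoh_e", "Ethanol exchange", {"etoh_e": -1}, 0.0, 1000.0, "Exchange", ""),
    ("EX_succ_e", "Succinate exchange", {"succ_e": -1}, 0.0, 1000.0, "Exchange", ""),
    ("EX_lac__D_e", "D-Lactate exchange", {"lac__D_e": -1}, 0.0, 1000.0, "Exchange", ""),
    ("EX_for_e", "Formate exchange", {"for_e": -1}, 0.0, 1000.0, "Exchange", ""),
    ("EX_o2_e", "O2 exchange", {"o2_e": -1}, -18.0, 1000.0, "Exchange", ""),
    ("EX_co2_e", "CO2 exchange", {"co2_e": -1}, -1000.0, 1000.0, "Exchange", ""),
    ("EX_h2o_e", "H2O exchange", {"h2o_e": -1}, -1000.0, 1000.0, "Exchange", ""),
    ("EX_h_e", "H+ exchange", {"h_e": -1}, -1000.0, 1000.0, "Exchange", ""),
    ("EX_pi_e", "Phosphate exchange", {"pi_e": -1}, -1000.0, 1000.0, "Exchange", ""),
    ("EX_nh4_e", "Ammonium exchange", {"nh4_e": -1}, -1000.0, 1000.0, "Exchange", ""),
    # transport
    ("O2t", "O2 diffusion", {"o2_e": -1, "o2": 1}, -1000.0, 1000.0, "Transport", "b0241"),
    ("CO2t", "CO2 diffusion", {"co2_e": -1, "co2": 1}, -1000.0, 1000.0, "Transport", "b0875"),
    ("H2Ot", "H2O diffusion", {"h2o_e": -1, "h2o": 1}, -1000.0, 1000.0, "Transport", "b0875"),
    ("NH4t", "Ammonium transport", {"nh4_e": -1, "nh4": 1}, -1000.0, 1000.0, "Transport", "b0451"),
    ("PIt2r", "Phosphate symport", {"pi_e": -1, "h_e": -1, "pi": 1, "h": 1}, -1000.0, 1000.0, "Transport", "b2987 or b3493"),
    ("ACt2r", "Acetate symport", {"ac_e": -1, "h_e": -1, "ac": 1, "h": 1}, -1000.0, 1000.0, "Transport", "b4067"),
    ("ETOHt2r", "Ethanol symport", {"etoh_e": -1, "h_e": -1, "etoh": 1, "h": 1}, -1000.0, 1000.0, "Transport", ""),
    ("SUCCt2r", "Succinate symport", {"succ_e": -1, "h_e": -1, "succ": 1, "h": 1}, -1000.0, 1000.0, "Transport", "b3528"),
    ("D_LACt2", "D-Lactate symport", {"lac__D_e": -1, "h_e": -1, "lac__D": 1, "h": 1}, -1000.0, 1000.0, "Transport", "b3603 or b2975"),
    ("FORt", "Formate symport", {"for_e": -1, "h_e": -1, "for": 1, "h": 1}, -1000.0, 1000.0, "Transport", "b0904 or b2492"),
    # glycolysis / gluconeogenesis
    ("GLCpts", "Glucose PTS uptake", {"glc__D_e": -1, "pep": -1, "g6p": 1, "pyr": 1}, 0.0, 1000.0, "Glycolysis/Gluconeogenesis", "b2415 and b2416 and b1101"),
    ("PGI", "Glucose-6-phosphate isomerase", {"g6p": -1, "f6p": 1}, -1000.0, 1000.0, "Glycolysis/Gluconeogenesis", "b4025"),
    ("PFK", "Phosphofructokinase", {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1, "h": 1}, 0.0, 1000.0, "Glycolysis/Gluconeogenesis", "b3916 or b1723"),
    ("FBP", "Fructose-1,6-bisphosphatase", {"fdp": -1, "h2o": -1, "f6p": 1, "pi": 1}, 0.0, 1000.0, "Glycolysis/Gluconeogenesis", "b4232 or b3925"),
    ("FBA", "Fructose-bisphosphate aldolase", {"fdp": -1, "dhap": 1, "g3p": 1}, -1000.0, 1000.0, "Glycolysis/Gluconeogenesis", "b2925 or b2097"),
    ("TPI", "Triose-phosphate isomerase", {"dhap": -1, "g3p": 1}, -1000.0, 1000.0, "Glycolysis/Gluconeogenesis", "b3919"),
    ("GAPD", "Glyceraldehyde-3-phosphate dehydrogenase", {"g3p": -1, "nad": -1, "pi": -1, "13dpg": 1, "h": 1, "nadh": 1}, -1000.0, 1000.0, "Glycolysis/Gluconeogenesis", "b1779"),
    ("PGK", "Phosphoglycerate kinase", {"13dpg": -1, "adp": -1, "3pg": 1, "atp": 1}, -1000.0, 1000.0, "Glycolysis/Gluconeogenesis", "b2926"),
    ("PGM", "Phosphoglycerate mutase", {"3pg": -1, "2pg": 1}, -1000.0, 1000.0, "Glycolysis/Gluconeogenesis", "b3612 or b4395 or b0755"),
    ("ENO", "Enolase", {"2pg": -1, "pep": 1, "h2o": 1}, -1000.0, 1000.0, "Glycolysis/Gluconeogenesis", "b2779"),
    ("PYK", "Pyruvate kinase", {"pep": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1}, 0.0, 1000.0, "Glycolysis/Gluconeogenesis", "b1854 or b1676"),
    ("PPS", "PEP synthase", {"pyr": -1, "atp": -2, "h2o": -1, "pep": 1, "adp": 2, "pi": 1, "h": 1}, 0.0, 1000.0, "Glycolysis/Gluconeogenesis", "b1702"),
    # pentose phosphate pathway
    ("G6PDH2r", "Glucose-6-phosphate dehydrogenase", {"g6p": -1, "nadp": -1, "6pgl": 1, "h": 1, "nadph": 1}, -1000.0, 1000.0, "Pentose Phosphate Pathway", "b1852"),
    ("PGL", "6-Phosphogluconolactonase", {"6pgl": -1, "h2o": -1, "6pgc": 1, "h": 1}, 0.0, 1000.0, "Pentose Phosphate Pathway", "b0767"),
    ("GND", "Phosphogluconate dehydrogenase", {"6pgc": -1, "nadp": -1, "co2": 1, "nadph": 1, "ru5p__D": 1}, 0.0, 1000.0, "Pentose Phosphate Pathway", "b2029"),
    ("RPI", "Ribose-5-phosphate isomerase", {"r5p": -1, "ru5p__D": 1}, -1000.0, 1000.0, "Pentose Phosphate Pathway", "b2914 or b4090"),
    ("RPE", "Ribulose-5-phosphate 3-epimerase", {"ru5p__D": -1, "xu5p__D": 1}, -1000.0, 1000.0, "Pentose Phosphate Pathway", "b3386 or b4301"),
    ("TKT1", "Transketolase 1", {"r5p": -1, "xu5p__D": -1, "g3p": 1, "s7p": 1}, -1000.0, 1000.0, "Pentose Phosphate Pathway", "b2935 or b2465"),
    ("TALA", "Transaldolase", {"g3p": -1, "s7p": -1, "e4p": 1, "f6p": 1}, -1000.0, 1000.0, "Pentose Phosphate Pathway", "b2464 or b0008"),
    ("TKT2", "Transketolase 2", {"e4p": -1, "xu5p__D": -1, "f6p": 1, "g3p": 1}, -1000.0, 1000.0, "Pentose Phosphate Pathway", "b2935 or b2465"),
    # TCA cycle + glyoxylate shunt + anaplerosis
    ("PDH", "Pyruvate dehydrogenase", {"pyr": -1, "coa": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1}, 0.0, 1000.0, "Citric Acid Cycle", "b0114 and b0115 and b0116"),
    ("CS", "Citrate synthase", {"accoa": -1, "oaa": -1, "h2o": -1, "cit": 1, "coa": 1, "h": 1}, 0.0, 1000.0, "Citric Acid Cycle", "b0720"),
    ("ACONT", "Aconitase", {"cit": -1, "icit": 1}, -1000.0, 1000.0, "Citric Acid Cycle", "b0118 or b1276"),
    ("ICDHyr", "Isocitrate dehydrogenase (NADP)", {"icit": -1, "nadp": -1, "akg": 1, "co2": 1, "nadph": 1}, -1000.0, 1000.0, "Citric Acid Cycle", "b1136"),
    ("AKGDH", "2-Oxoglutarate dehydrogenase", {"akg": -1, "coa": -1, "nad": -1, "co2": 1, "nadh": 1, "succoa": 1}, 0.0, 1000.0, "Citric Acid Cycle", "b0726 and b0727 and b0116"),
    ("SUCOAS", "Succinyl-CoA synthetase", {"atp": -1, "coa": -1, "succ": -1, "adp": 1, "pi": 1, "succoa": 1}, -1000.0, 1000.0, "Citric Acid Cycle", "b0728 and b0729"),
    ("SUCDi", "Succinate dehydrogenase", {"q8": -1, "succ": -1, "fum": 1, "q8h2": 1}, 0.0, 1000.0, "Citric Acid Cycle", "b0721 and b0722 and b0723 and b0724"),
    ("FRD7", "Fumarate reductase", {"fum": -1, "q8h2": -1, "q8": 1, "succ": 1}, 0.0, 1000.0, "Citric Acid Cycle", "b4151 and b4152 and b4153 and b4154"),
    ("FUM", "Fumarase", {"fum": -1, "h2o": -1, "mal__L": 1}, -1000.0, 1000.0, "Citric Acid Cycle", "b1612 or b4122 or b1611"),
    ("MDH", "Malate dehydrogenase", {"mal__L": -1, "nad": -1, "h": 1, "nadh": 1, "oaa": 1}, -1000.0, 1000.0, "Citric Acid Cycle", "b3236"),
    ("ICL", "Isocitrate lyase", {"icit": -1, "glx": 1, "succ": 1}, 0.0, 1000.0, "Anaplerotic Reactions", "b4015"),
    ("MALS", "Malate synthase", {"accoa": -1, "glx": -1, "h2o": -1, "coa": 1, "h": 1, "mal__L": 1}, 0.0, 1000.0, "Anaplerotic Reactions", "b4014 or b2976"),
    ("ME1", "Malic enzyme (NAD)", {"mal__L": -1, "nad": -1, "co2": 1, "nadh": 1, "pyr": 1}, 0.0, 1000.0, "Anaplerotic Reactions", "b1479"),
    ("PPC", "PEP carboxylase", {"pep": -1, "co2": -1, "h2o": -1, "h": 1, "oaa": 1, "pi": 1}, 0.0, 1000.0, "Anaplerotic Reactions", "b3956"),
    ("PPCK", "PEP carboxykinase", {"atp": -1, "oaa": -1, "adp": 1, "co2": 1, "pep": 1}, 0.0, 1000.0, "Anaplerotic Reactions", "b3403"),
    # acetate, ethanol, fermentation
    ("ACKr", "Acetate kinase", {"ac": -1, "atp": -1, "actp": 1, "adp": 1}, -1000.0, 1000.0, "Pyruvate Metabolism", "b3115 or b2296 or b1849"),
    ("PTAr", "Phosphotransacetylase", {"accoa": -1, "pi": -1, "actp": 1, "coa": 1}, -1000.0, 1000.0, "Pyruvate Metabolism", "b2297 or b2458"),
    ("ACS", "Acetyl-CoA synthetase", {"ac": -1, "atp": -2, "coa": -1, "h2o": -1, "accoa": 1, "adp": 2, "pi": 2, "h": 1}, 0.0, 1000.0, "Pyruvate Metabolism", "b4069"),
    ("ACALD", "Acetaldehyde dehydrogenase", {"acald": -1, "coa": -1, "nad": -1, "accoa": 1, "h": 1, "nadh": 1}, -1000.0, 1000.0, "Pyruvate Metabolism", "b0351 or b1241"),
    ("ALCD2x", "Alcohol dehydrogenase", {"etoh": -1, "nad": -1, "acald": 1, "h": 1, "nadh": 1}, -1000.0, 1000.0, "Pyruvate Metabolism", "b0356 or b1478 or b1241"),
    ("LDH_D", "D-Lactate dehydrogenase", {"lac__D": -1, "nad": -1, "h": 1, "nadh": 1, "pyr": 1}, -1000.0, 1000.0, "Pyruvate Metabolism", "b2133 or b1380"),
    ("PFL", "Pyruvate formate lyase", {"coa": -1, "pyr": -1, "accoa": 1, "for": 1}, 0.0, 1000.0, "Pyruvate Metabolism", "b0902 and b0903"),
    # oxidative phosphorylation and redox
    ("NADH16", "NADH dehydrogenase (proton-pumping)", {"h": -4, "nadh": -1, "q8": -1, "h_e": 3, "nad": 1, "q8h2": 1}, 0.0, 1000.0, "Oxidative Phosphorylation", "b2276 and b2277 and b2278"),
    ("CYTBD", "Cytochrome oxidase bd", {"h": -2, "o2": -0.5, "q8h2": -1, "h2o": 1, "h_e": 2, "q8": 1}, 0.0, 1000.0, "Oxidative Phosphorylation", "b0733 and b0734"),
    ("ATPS4r", "ATP synthase", {"adp": -1, "pi": -1, "h_e": -4, "atp": 1, "h2o": 1, "h": 3}, -1000.0, 1000.0, "Oxidative Phosphorylation", "b3731 and b3732 and b3733 and b3734"),
    ("NADTRHD", "NAD transhydrogenase (soluble)", {"nad": -1, "nadph": -1, "nadh": 1, "nadp": 1}, 0.0, 1000.0, "Oxidative Phosphorylation", "b3962"),
    ("THD2", "NAD(P) transhydrogenase (membrane)", {"h_e": -2, "nadh": -1, "nadp": -1, "h": 2, "nad": 1, "nadph": 1}, 0.0, 1000.0, "Oxidative Phosphorylation", "b1602 and b1603"),
    # nitrogen assimilation
    ("GLUDy", "Glutamate dehydrogenase (NADP)", {"akg": -1, "h": -1, "nadph": -1, "nh4": -1, "glu__L": 1, "h2o": 1, "nadp": 1}, -1000.0, 1000.0, "Glutamate Metabolism", "b1761"),
    ("GLNS", "Glutamine synthetase", {"atp": -1, "glu__L": -1, "nh4": -1, "adp": 1, "gln__L": 1, "h": 1, "pi": 1}, 0.0, 1000.0, "Glutamate Metabolism", "b3870 or b1297"),
    # maintenance + biomass
    ("ATPM", "ATP maintenance requirement", {"atp": -1, "h2o": -1, "adp": 1, "h": 1, "pi": 1}, 8.39, 1000.0, "Biomass and maintenance", ""),
]

_BIOMASS_STOICH = {
    "3pg": -1.496, "accoa": -3.7478, "atp": -59.81, "e4p": -0.361,
    "f6p": -0.0709, "g3p": -0.129, "g6p": -0.205, "gln__L": -0.2557,
    "glu__L": -4.9414, "h2o": -59.81, "nad": -3.547, "nadph": -13.0279,
    "oaa": -1.7867, "pep": -0.5191, "pyr": -2.8328, "r5p": -0.8977,
    "adp": 59.81, "akg": 4.1182, "coa": 3.7478, "h": 59.81,
    "nadh": 3.547, "nadp": 13.0279, "pi": 59.81,
}


def make_core_fixture() -> MetabolicModel:
    """Deterministic core-metabolism model (~70 reactions, 63 metabolites).

    Default medium: glucose 10, oxygen 18 mmol·gDW⁻¹·h⁻¹, aerobic.  Growth-
    associated ATP (59.81 mmol/gDW) is embedded in the biomass stoichiometry
    and non-growth maintenance is the 8.39 lower bound on ``ATPM``, following
    the iAF1260 convention.  Grows aerobically and (fermentatively) an-
    aerobically on glucose, and aerobically on acetate, ethanol and
    succinate.  Contains the scenario reaction ids ACS, PTAr, ACKr, PGK,
    PGL, GND and RPI.
    """
    mets = [Metabolite(id=i, name=n, formula=f, compartment="e")
            for i, n, f in _CORE_METS_E]
    mets += [Metabolite(id=i, name=i, compartment="c") for i in _CORE_METS_C]
    rxns = [
        Reaction(id=rid, name=name,
                 stoichiometry={k: float(v) for k, v in stoich.items()},
                 lower_bound=lb, upper_bound=ub, subsystem=sub,
                 gpr=parse_gpr(gpr))
        for rid, name, stoich, lb, ub, sub, gpr in _CORE_RXNS
    ]
    rxns.append(
        Reaction(id="BIOMASS", name="Biomass objective (with GAM)",
                 stoichiometry=dict(_BIOMASS_STOICH), lower_bound=0.0,
                 upper_bound=1000.0, subsystem="Biomass and maintenance",
                 objective_coefficient=1.0)
    )
    return MetabolicModel(id="core_gut_ecoli", metabolites=mets, reactions=rxns)


# ---------------------------------------------------------------------------
# Pan-genome models with planted strains
# ---------------------------------------------------------------------------

# src → dst conversions that forfeit the energy/redox yield of the native
# route; adding them can never raise the optimum, which keeps accessory
# reactions growth-dispensable (asserted at build time).
_WASTE_PAIRS = [
    ("g6p", "pyr"), ("f6p", "g3p"), ("r5p", "g3p"), ("mal__L", "pyr"),
    ("akg", "succ"), ("pep", "pyr"), ("fdp", "pyr"), ("3pg", "pyr"),
    ("dhap", "pyr"), ("icit", "succ"), ("g6p", "g3p"), ("oaa", "pyr"),
]


@dataclass
class PlantedStrain:
    strain_id: str
    profile: dict[str, float]
    absent_reactions: set[str]
    model: MetabolicModel


def make_pan_with_strains(
    n_strains: int = 3,
    n_accessory: int = 8,
    seed: int = 0,
    carry_probability: float = 0.5,
) -> tuple[MetabolicModel, list[PlantedStrain]]:
    """Core fixture + accessory reactions, with per-strain presence profiles.

    Each accessory reaction is gated by a distinct synthetic gene and is
    growth-dispensable by construction: bypasses are energy-forfeiting
    conversions between core metabolites, peripheral reactions drain into a
    novel dead-end metabolite.  Build-time check: the pan optimum equals the
    core optimum, so extraction at any growth fraction can zero every
    accessory flux.

    Each strain carries each accessory gene independently with
    ``carry_probability`` (at least one strain lacks at least one gene when
    possible, so extraction has work to do).  The planted truth for a strain
    is the pan model minus its absent-gene-only reactions.
    """
    if n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    rng = np.random.default_rng(seed)
    core = make_core_fixture()
    core_opt = solve_fba(core).objective_value

    pan = core.copy(new_id=f"pan_{seed}")
    accessory: list[tuple[str, str]] = []  # (reaction id, gene id)
    for k in range(n_accessory):
        gene = f"acc_g{k:03d}"
        if k % 2 == 0:
            src, dst = _WASTE_PAIRS[int(rng.integers(len(_WASTE_PAIRS)))]
            rid = f"ACC{k:03d}_{src}_{dst}"
            stoich = {src: -1.0, dst: 1.0}
        else:
            src = _CORE_METS_C[int(rng.integers(8, 28))]
            xid = f"xacc{k:03d}"
            pan.metabolites.append(Metabolite(id=xid, name=f"accessory dead-end {k}",
                                              compartment="c"))
            rid = f"ACC{k:03d}_{src}_deadend"
            stoich = {src: -1.0, xid: 1.0}
        pan.reactions.append(
            Reaction(id=rid, name=f"accessory {k}", stoichiometry=stoich,
                     lower_bound=0.0, upper_bound=1000.0,
                     subsystem="Accessory", gpr=parse_gpr(gene))
        )
        accessory.append((rid, gene))
    pan.validate()
    pan_opt = solve_fba(pan).objective_value
    if abs(pan_opt - core_opt) > 1e-6 * max(1.0, abs(core_opt)):
        raise AssertionError(
            "accessory reactions changed the pan optimum "
            f"({core_opt} -> {pan_opt}); construction invariant violated"
        )

    core_genes = sorted(core.genes)
    strains: list[PlantedStrain] = []
    carries = rng.random((n_strains, n_accessory)) < carry_probability
    if n_accessory and carries.all():
        carries[int(rng.integers(n_strains)), int(rng.integers(n_accessory))] = False
    for s in range(n_strains):
        profile = {g: 1.0 for g in core_genes}
        absent: set[str] = set()
        for k, (rid, gene) in enumerate(accessory):
            profile[gene] = float(carries[s, k])
            if not carries[s, k]:
                absent.add(rid)
        model = pan.remove_reactions(absent) if absent else pan.copy()
        model.id = f"strain_{s}"
        strains.append(PlantedStrain(strain_id=f"strain_{s}", profile=profile,
                                     absent_reactions=absent, model=model))
    return pan, strains


# ---------------------------------------------------------------------------
# Alignment tables with planted coverage
# ---------------------------------------------------------------------------

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

READ_LENGTH = 100  # bp; fixed for alignment synthesis


@dataclass
class PlantedCohort:
    """Planted truth for a read-alignment cohort: per strain, the fraction of
    samples it occurs in and the fold coverage it reaches there."""

    n_samples: int = 10
    strains: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"strainA": (1.0, 12.0)}
    )  # strain id -> (prevalence, depth)
    identity: float = 99.5  # percent identity of every planted read
    seed: int = 0

    def __post_init__(self) -> None:
        for sid, (prev, depth) in self.strains.items():
            if not (0.0 <= prev <= 1.0):
                raise ValueError(f"{sid}: prevalence must be in [0, 1]")
            if depth < 0:
                raise ValueError(f"{sid}: depth must be >= 0")


def make_alignments(
    cohort: PlantedCohort, genome_length: int = 100_000
) -> list[pd.DataFrame]:
    """Per-sample alignment tables (BLAST outfmt-6 layout) with planted
    depth, identity and prevalence.

    Reads (100 bp) tile the genome cyclically so the summed aligned length is
    exactly ``depth × genome_length`` — boundary depths like 10.0 are hit
    exactly.  Every read aligns once (passes a uniqueness filter).  A strain
    with prevalence p occurs in exactly ``round(p · n_samples)`` samples,
    chosen by seeded permutation.
    """
    rng = np.random.default_rng(cohort.seed)
    present_in: dict[str, set[int]] = {}
    for sid, (prev, _depth) in cohort.strains.items():
        k = int(round(prev * cohort.n_samples))
        order = rng.permutation(cohort.n_samples)
        present_in[sid] = set(int(i) for i in order[:k])

    tables: list[pd.DataFrame] = []
    for sample in range(cohort.n_samples):
        rows: list[tuple] = []
        for sid, (_prev, depth) in cohort.strains.items():
            if sample not in present_in[sid]:
                continue
            total = int(round(depth * genome_length))
            pos = 0
            read_idx = 0
            while total > 0:
                ln = min(READ_LENGTH, total)
                start = pos % genome_length + 1
                end = min(start + ln - 1, genome_length)
                ln = end - start + 1
                mism = int(round((100.0 - cohort.identity) / 100.0 * ln))
                rows.append(
                    (f"s{sample}_{sid}_r{read_idx}", sid, cohort.identity, ln,
                     mism, 0, 1, ln, start, end, 1e-30, 2.0 * ln)
                )
                total -= ln
                pos += ln
                read_idx += 1
        tables.append(pd.DataFrame(rows, columns=BLAST6_COLUMNS))
    return tables


def make_scaffold_alignments(
    genes: list[tuple[str, int, int]],
    covered_fraction: dict[str, float],
    identity: float = 99.5,
) -> pd.DataFrame:
    """Scaffold-vs-genome alignment table in which each gene is covered by a
    single scaffold over exactly ``covered_fraction`` of its length (from the
    gene start); genes absent from the mapping get no scaffold."""
    rows = []
    for i, (gid, start, end) in enumerate(genes):
        frac = covered_fraction.get(gid)
        if frac is None or frac <= 0:
            continue
        glen = end - start + 1
        cov = int(round(frac * glen))
        if cov <= 0:
            continue
        s, e = start, start + cov - 1
        ln = e - s + 1
        rows.append((f"scaffold_{i}", "genome", identity, ln, 0, 0, 1, ln,
                     s, e, 1e-50, 2.0 * ln))
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)
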