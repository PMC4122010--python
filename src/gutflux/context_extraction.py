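"""Context-specific model extraction from a pan-genome model.

Two extraction algorithms driven by per-gene presence/evidence scores:

* GIMME — a linear program that minimises Σ penalty·|v| over low-evidence
  reactions while forcing biomass to stay above a fraction of the pan-model
  optimum; low-evidence reactions left without flux are removed.
* iMAT — a mixed-integer program that maximises the number of high-evidence
  reactions carrying flux (|v| ≥ ε) plus the number of low-evidence
  reactions shut off; low-evidence reactions inactive at the optimum are
  removed.

On binary presence profiles over growth-dispensable accessory reactions the
two removal sets coincide, which is the property the strain models rest on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp
from scipy.sparse import coo_matrix

from .constraint_analysis import InfeasibleModelError, solve_fba
from .model_io import MetabolicModel, evaluate_gpr, stoichiometric_matrix

__all__ = [
    "PresenceProfile",
    "ExtractionResult",
    "ModelComparison",
    "reaction_evidence",
    "gimme_extract",
    "imat_extract",
    "compare_models",
]

ZERO_FLUX_TOL = 1e-9
MILP_BINARY_GUARD = 10_000  # desk-scale limit on binary variables


@dataclass
class PresenceProfile:
    """Per-strain gene evidence: 0/1 presence calls or non-negative
    expression-like scores; genes not listed count as absent (0)."""

    strain_id: str
    gene_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: s for g, s in self.gene_scores.items() if s < 0}
        if bad:
            raise ValueError(f"negative evidence scores: {bad}")


@dataclass
class ExtractionResult:
    model: MetabolicModel
    removed_reactions: list[str]
    algorithm: str  # "gimme" | "imat"
    objective_achieved: float
    # low-evidence reactions the optimum could not silence (flux required
    # for growth despite the gene evidence saying "absent")
    inconsistent_reactions: list[str] = field(default_factory=list)


@dataclass
class ModelComparison:
    """Cross-model network differences: reactions unique to one model,
    metabolites outside the all-model intersection, the genes catalysing the
    specific reactions, and subsystem tallies of the specific reactions."""

    specific_reactions: dict[str, set[str]]
    specific_genes: dict[str, set[str]]
    nonshared_metabolites: set[str]
    shared_reaction_count: int
    subsystem_tallies: dict[str, dict[str, int]]


def reaction_evidence(
    pan: MetabolicModel, profile: PresenceProfile
) -> dict[str, float]:
    """Per-reaction evidence from the GPR (OR = max, AND = min over gene
    scores).  Reactions with an empty GPR get ``inf`` — they are retained
    regardless of any threshold."""
    evidence: dict[str, float] = {}
    for r in pan.reactions:
        if r.gpr.is_empty:
            evidence[r.id] = math.inf
        else:
            evidence[r.id] = evaluate_gpr(r.gpr, profile.gene_scores)
    return evidence


def _bounds_arrays(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([r.lower_bound for r in model.reactions], dtype=float),
        np.array([r.upper_bound for r in model.reactions], dtype=float),
    )


def _pan_optimum(pan: MetabolicModel) -> float:
    base = solve_fba(pan)
    if not base.optimal or base.objective_value is None:
        raise InfeasibleModelError(f"pan model {pan.id!r} is {base.status}")
    if base.objective_value <= 0:
        raise InfeasibleModelError("pan model optimum must be positive for extraction")
    return base.objective_value


def gimme_extract(
    pan: MetabolicModel,
    profile: PresenceProfile,
    threshold: float = 0.5,
    growth_fraction: float = 0.9,
) -> ExtractionResult:
    """GIMME extraction.

    Minimises Σ (threshold − evidence)·(v⁺ + v⁻) over below-threshold
    reactions (|v| linearised by flux splitting), subject to S·v = 0, the
    model bounds, and biomass ≥ growth_fraction × pan optimum.  Below-
    threshold reactions with zero flux in the minimiser are removed; the
    extracted model is re-validated to reach the growth floor.
    """
    opt = _pan_optimum(pan)
    evidence = reaction_evidence(pan, profile)
    penalized = [j for j, r in enumerate(pan.reactions) if evidence[r.id] < threshold]
    n = len(pan.reactions)
    S = stoichiometric_matrix(pan)
    lb, ub = _bounds_arrays(pan)
    c_obj = np.array([r.objective_coefficient for r in pan.reactions])

    k = len(penalized)
    # variables: v (n), then v⁺, v⁻ (k each) for penalized reactions
    ntot = n + 2 * k
    c = np.zeros(ntot)
    for t, j in enumerate(penalized):
        pen = threshold - evidence[pan.reactions[j].id]
        c[n + t] = pen
        c[n + k + t] = pen

    A_eq = np.zeros((S.shape[0] + k, ntot))
    A_eq[: S.shape[0], :n] = S
    for t, j in enumerate(penalized):  # v_j − v⁺ + v⁻ = 0
        A_eq[S.shape[0] + t, j] = 1.0
        A_eq[S.shape[0] + t, n + t] = -1.0
        A_eq[S.shape[0] + t, n + k + t] = 1.0
    b_eq = np.zeros(S.shape[0] + k)

    floor = growth_fraction * opt
    A_ub = np.zeros((1, ntot))
    A_ub[0, :n] = -c_obj
    b_ub = np.array([-floor])

    bounds = list(zip(lb, ub)) + [(0.0, None)] * (2 * k)
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                  bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleModelError(
            f"GIMME infeasible at growth_fraction={growth_fraction}; "
            "try a lower fraction"
        )
    if res.status != 0:
        raise RuntimeError(f"GIMME LP failed: {res.message}")

    v = res.x[:n]
    removed = [
        pan.reactions[j].id for j in penalized if abs(v[j]) < ZERO_FLUX_TOL
    ]
    inconsistent = [
        pan.reactions[j].id for j in penalized if abs(v[j]) >= ZERO_FLUX_TOL
    ]
    extracted = pan.remove_reactions(removed)
    extracted.id = profile.strain_id
    check = solve_fba(extracted)
    if not check.optimal or check.objective_value < floor - 1e-6:
        raise InfeasibleModelError(
            "extracted model fails the growth floor after removal; "
            "inconsistent evidence/threshold combination"
        )
    return ExtractionResult(model=extracted, removed_reactions=sorted(removed),
                            algorithm="gimme",
                            objective_achieved=check.objective_value,
                            inconsistent_reactions=sorted(inconsistent))


def imat_extract(
    pan: MetabolicModel,
    profile: PresenceProfile,
    high_threshold: float = 0.5,
    low_threshold: float = 0.5,
    epsilon: float = 1.0,
    growth_fraction: float = 0.9,
    time_limit: float = 300.0,
) -> ExtractionResult:
    """iMAT extraction as a MILP.

    Maximises (# high-evidence reactions with |v| ≥ ε) + (# low-evidence
    reactions with v = 0), with big-M indicator linking (M = the reaction
    bounds themselves) and a biomass floor at ``growth_fraction`` of the pan
    optimum so extracted models stay growth-feasible.  Low-evidence
    reactions whose inactivity indicator is set at the optimum are removed.
    """
    opt = _pan_optimum(pan)
    evidence = reaction_evidence(pan, profile)
    high = [j for j, r in enumerate(pan.reactions)
            if evidence[r.id] >= high_threshold and not math.isinf(evidence[r.id])]
    low = [j for j, r in enumerate(pan.reactions) if evidence[r.id] < low_threshold]
    n = len(pan.reactions)
    n_bin = 2 * len(high) + len(low)
    if n_bin > MILP_BINARY_GUARD:
        raise RuntimeError(
            f"iMAT needs {n_bin} binary variables (> {MILP_BINARY_GUARD}); "
            "use a smaller model"
        )
    S = stoichiometric_matrix(pan)
    lb, ub = _bounds_arrays(pan)
    c_obj = np.array([r.objective_coefficient for r in pan.reactions])

    # variables: v (n), yf (len high), yr (len high), y0 (len low)
    nh, nl = len(high), len(low)
    ntot = n + 2 * nh + nl
    c = np.zeros(ntot)
    c[n:] = -1.0  # milp minimises; maximize indicator count

    rows, cols, vals = [], [], []
    con_lb, con_ub = [], []
    r_idx = 0

    def add_row(entries: list[tuple[int, float]], lo: float, hi: float) -> None:
        nonlocal r_idx
        for cc, vv in entries:
            rows.append(r_idx)
            cols.append(cc)
            vals.append(vv)
        con_lb.append(lo)
        con_ub.append(hi)
        r_idx += 1

    for i in range(S.shape[0]):  # S·v = 0
        entries = [(j, S[i, j]) for j in range(n) if S[i, j] != 0.0]
        add_row(entries or [(0, 0.0)], 0.0, 0.0)

    add_row([(j, c_obj[j]) for j in range(n) if c_obj[j] != 0.0],
            growth_fraction * opt, np.inf)

    for t, j in enumerate(high):
        yf, yr = n + t, n + nh + t
        # forward-active: v_j ≥ lb_j + yf (ε − lb_j)
        add_row([(j, 1.0), (yf, -(epsilon - lb[j]))], lb[j], np.inf)
        # reverse-active: v_j ≤ ub_j − yr (ub_j + ε)
        add_row([(j, 1.0), (yr, ub[j] + epsilon)], -np.inf, ub[j])
        add_row([(yf, 1.0), (yr, 1.0)], 0.0, 1.0)

    for t, j in enumerate(low):
        y0 = n + 2 * nh + t
        # y0 = 1 forces v_j = 0:  lb_j (1 − y0) ≤ v_j ≤ ub_j (1 − y0)
        add_row([(j, 1.0), (y0, ub[j])], -np.inf, ub[j])
        add_row([(j, 1.0), (y0, lb[j])], lb[j], np.inf)

    A = coo_matrix((vals, (rows, cols)), shape=(r_idx, ntot))
    constraints = LinearConstraint(A, np.array(con_lb), np.array(con_ub))
    integrality = np.zeros(ntot)
    integrality[n:] = 1
    var_lb = np.concatenate([lb, np.zeros(2 * nh + nl)])
    var_ub = np.concatenate([ub, np.ones(2 * nh + nl)])
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
        options={"time_limit": time_limit},
    )
    if res.status == 1:
        raise RuntimeError(
            "iMAT MILP hit the time limit; use a smaller model or raise "
            "time_limit"
        )
    if res.status == 2:
        raise InfeasibleModelError(
            f"iMAT infeasible at growth_fraction={growth_fraction}"
        )
    if not res.success:
        raise RuntimeError(f"iMAT MILP failed: {res.message}")

    y0 = res.x[n + 2 * nh:]
    removed = [pan.reactions[j].id for t, j in enumerate(low) if y0[t] > 0.5]
    inconsistent = [pan.reactions[j].id for t, j in enumerate(low) if y0[t] <= 0.5]
    extracted = pan.remove_reactions(removed)
    extracted.id = profile.strain_id
    check = solve_fba(extracted)
    if not check.optimal:
        raise InfeasibleModelError("iMAT-extracted model no longer grows")
    return ExtractionResult(model=extracted, removed_reactions=sorted(removed),
                            algorithm="imat",
                            objective_achieved=check.objective_value,
                            inconsistent_reactions=sorted(inconsistent))


def compare_models(models: list[MetabolicModel]) -> ModelComparison:
    """Network differences across ≥ 2 models: per-model specific reactions
    (present in that model, absent from all others), their catalysing genes
    (union of GPR leaves), metabolites outside the all-model intersection,
    and subsystem tallies of the specific reactions."""
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    rxn_sets = {m.id: set(m.reaction_ids()) for m in models}
    met_sets = {m.id: set(m.metabolite_ids()) for m in models}

    specific_reactions: dict[str, set[str]] = {}
    specific_genes: dict[str, set[str]] = {}
    subsystem_tallies: dict[str, dict[str, int]] = {}
    for m in models:
        others: set[str] = set()
        for other in models:
            if other.id != m.id:
                others |= rxn_sets[other.id]
        spec = rxn_sets[m.id] - others
        specific_reactions[m.id] = spec
        genes: set[str] = set()
        tally: dict[str, int] = {}
        for rid in spec:
            r = m.get_reaction(rid)
            genes |= r.gpr.genes()
            key = r.subsystem or "(unassigned)"
            tally[key] = tally.get(key, 0) + 1
        specific_genes[m.id] = genes
        subsystem_tallies[m.id] = tally

    all_mets = set.union(*met_sets.values())
    shared_mets = set.intersection(*met_sets.values())
    shared_rxns = set.intersection(*rxn_sets.values())
    return ModelComparison(
        specific_reactions=specific_reactions,
        specific_genes=specific_genes,
        nonshared_metabolites=all_mets - shared_mets,
        shared_reaction_count=len(shared_rxns),
        subsystem_tallies=subsystem_tallies,
    )
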