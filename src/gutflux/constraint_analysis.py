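"""Flux balance analysis, growth media, flux variability, robustness scans.

FBA is the linear program  max cᵀv  s.t.  S·v = 0,  lb ≤ v ≤ ub, solved with
HiGHS through :func:`scipy.optimize.linprog`.  FVA re-solves min/max per
reaction at a fixed fraction of the optimum; robustness scans fix one flux at
a grid of values and re-optimise the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel, Reaction, stoichiometric_matrix, parse_formula

__all__ = [
    "Medium",
    "FluxResult",
    "FVAResult",
    "RobustnessCurve",
    "InfeasibleModelError",
    "apply_medium",
    "solve_fba",
    "flux_variability",
    "robustness_scan",
]

FEASIBILITY_TOL = 1e-9  # LP primal/dual feasibility
REPORT_TOL = 1e-6  # mass-balance residual we guarantee on reported fluxes
BLOCKED_TOL = 1e-9  # |v| below this counts as zero for directionality

DEFAULT_O2_EXCHANGE = "EX_o2_e"
DEFAULT_O2_UPTAKE = 18.0  # mmol·gDW⁻¹·h⁻¹, aerobic oxygen availability


class InfeasibleModelError(RuntimeError):
    """The LP is infeasible or unbounded where an optimum was required."""


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------


@dataclass
class Medium:
    """Growth medium: maximum uptake rate per open exchange reaction plus an
    aerobic flag governing the oxygen exchange.

    Uptake rates are non-negative magnitudes; they become negative lower
    bounds on the exchanges (negative flux = uptake).  Carbon exchanges not
    listed are closed for uptake.
    """

    exchanges: dict[str, float] = field(default_factory=dict)
    aerobic: bool = True
    oxygen_exchange: str = DEFAULT_O2_EXCHANGE
    oxygen_uptake: float = DEFAULT_O2_UPTAKE

    def __post_init__(self) -> None:
        for rid, rate in self.exchanges.items():
            if rate < 0:
                raise ValueError(f"uptake rate for {rid} must be >= 0, got {rate}")


def _carbon_exchanges(model: MetabolicModel) -> list[str]:
    """Exchange reactions whose species contains carbon (by formula)."""
    out = []
    for r in model.exchanges:
        (mid,) = r.stoichiometry
        formula = model.get_metabolite(mid).formula
        if parse_formula(formula).get("C", 0) > 0:
            out.append(r.id)
    return out


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy of the model with exchange bounds set to the medium.

    Listed exchanges get lower_bound = −uptake; every other carbon-bearing
    exchange is closed for uptake (lower_bound = 0, secretion untouched); the
    oxygen exchange opens to −oxygen_uptake when aerobic and closes when
    anaerobic, unless oxygen is itself listed in the medium.
    """
    exchange_ids = {r.id for r in model.exchanges}
    unknown = set(medium.exchanges) - exchange_ids
    if unknown:
        raise KeyError(
            f"unknown exchange reactions {sorted(unknown)}; "
            f"valid exchanges: {sorted(exchange_ids)}"
        )
    out = model.copy()
    for rid in _carbon_exchanges(out):
        if rid not in medium.exchanges:
            out.get_reaction(rid).lower_bound = 0.0
    for rid, rate in medium.exchanges.items():
        out.get_reaction(rid).lower_bound = -rate
    if medium.oxygen_exchange in exchange_ids and medium.oxygen_exchange not in medium.exchanges:
        out.get_reaction(medium.oxygen_exchange).lower_bound = (
            -medium.oxygen_uptake if medium.aerobic else 0.0
        )
    return out


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _solve_lp(
    c: np.ndarray,
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
):
    """min cᵀv over the flux polytope; thin wrapper around HiGHS."""
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
        options={
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL,
        },
    )
    return res


def _status_name(res) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "failed")


def solve_fba(model: MetabolicModel, sense: str = "max") -> FluxResult:
    """Optimise the model's objective (biomass by convention).

    Returns one optimal vertex; under degenerate alternate optima only the
    objective value (and FVA-certified unique fluxes) are stable across
    solvers.  Infeasible/unbounded statuses are reported, never silently
    zeroed.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    obj = model.objective_reactions
    if not obj:
        raise ValueError(f"model {model.id!r} has no objective reaction")
    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.array([r.objective_coefficient for r in model.reactions])
    sign = -1.0 if sense == "max" else 1.0
    res = _solve_lp(sign * c, S, lb, ub)
    status = _status_name(res)
    if status != "optimal":
        return FluxResult(status=status, objective_value=None, fluxes={})
    v = res.x
    return FluxResult(
        status="optimal",
        objective_value=float(c @ v),
        fluxes={r.id: float(v[j]) for j, r in enumerate(model.reactions)},
    )


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------


@dataclass
class FVAResult:
    """Per-reaction allowable flux range at a fixed objective fraction, with
    a directionality class per reaction:

    * ``forward``: min ≥ 0 and max > 0
    * ``reverse``: max ≤ 0 and min < 0
    * ``bidirectional``: min < 0 < max
    * ``blocked``: min = max = 0 (within tolerance)
    """

    ranges: dict[str, tuple[float, float]]
    direction: dict[str, str]
    objective_fraction: float
    objective_value: float

    def min_flux(self, rid: str) -> float:
        return self.ranges[rid][0]

    def max_flux(self, rid: str) -> float:
        return self.ranges[rid][1]


def _classify(vmin: float, vmax: float) -> str:
    if abs(vmin) < BLOCKED_TOL and abs(vmax) < BLOCKED_TOL:
        return "blocked"
    if vmin >= -BLOCKED_TOL:
        return "forward"
    if vmax <= BLOCKED_TOL:
        return "reverse"
    return "bidirectional"


def flux_variability(
    model: MetabolicModel,
    objective_fraction: float = 1.0,
    reactions: Sequence[str] | None = None,
) -> FVAResult:
    """Min and max flux per reaction subject to cᵀv ≥ fraction · optimum.

    The optimum is computed first by FBA; each reaction then gets two LPs.
    A tiny slack (1e−9 absolute) is left on the objective floor at fraction
    1.0 so the optimal face is numerically non-empty.
    """
    if not (0.0 < objective_fraction <= 1.0):
        raise ValueError("objective_fraction must be in (0, 1]")
    base = solve_fba(model)
    if not base.optimal:
        raise InfeasibleModelError(
            f"FVA base problem is {base.status} for model {model.id!r}"
        )
    opt = base.objective_value
    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.array([r.objective_coefficient for r in model.reactions])
    # cᵀv >= fraction·opt as A_ub x <= b_ub
    floor = objective_fraction * opt - 1e-9 * max(1.0, abs(opt))
    A_ub = -c.reshape(1, -1)
    b_ub = np.array([-floor])

    rids = list(reactions) if reactions is not None else [r.id for r in model.reactions]
    index = {r.id: j for j, r in enumerate(model.reactions)}
    ranges: dict[str, tuple[float, float]] = {}
    direction: dict[str, str] = {}
    for rid in rids:
        j = index[rid]
        e = np.zeros(len(model.reactions))
        e[j] = 1.0
        lo = _solve_lp(e, S, lb, ub, A_ub, b_ub)
        hi = _solve_lp(-e, S, lb, ub, A_ub, b_ub)
        if _status_name(lo) != "optimal" or _status_name(hi) != "optimal":
            raise InfeasibleModelError(f"FVA subproblem failed for reaction {rid}")
        vmin, vmax = float(lo.x[j]), float(hi.x[j])
        if vmin > vmax:  # numerical inversion at degenerate faces
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rid] = (vmin, vmax)
        direction[rid] = _classify(vmin, vmax)
    return FVAResult(
        ranges=ranges,
        direction=direction,
        objective_fraction=objective_fraction,
        objective_value=opt,
    )


# ---------------------------------------------------------------------------
# Robustness
# ---------------------------------------------------------------------------


@dataclass
class RobustnessCurve:
    """Objective value as one reaction's flux is fixed across its feasible
    range; infeasible points carry ``None``."""

    reaction_id: str
    points: list[tuple[float, float | None]]

    def feasible_points(self) -> list[tuple[float, float]]:
        return [(x, y) for x, y in self.points if y is not None]


def robustness_scan(
    model: MetabolicModel, reaction_id: str, n_points: int = 20
) -> RobustnessCurve:
    """Fix ``reaction_id``'s flux at ``n_points`` evenly spaced values across
    its FVA-feasible range (at objective fraction → 0⁺, i.e. the whole
    feasible range) and re-solve FBA at each."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    model.get_reaction(reaction_id)  # raises KeyError if unknown
    # feasible range irrespective of the objective: min/max with no floor
    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    index = {r.id: j for j, r in enumerate(model.reactions)}
    j = index[reaction_id]
    e = np.zeros(len(model.reactions))
    e[j] = 1.0
    lo = _solve_lp(e, S, lb, ub)
    hi = _solve_lp(-e, S, lb, ub)
    if _status_name(lo) != "optimal" or _status_name(hi) != "optimal":
        raise InfeasibleModelError(f"cannot bracket feasible range of {reaction_id}")
    vmin, vmax = float(lo.x[j]), float(hi.x[j])
    grid = np.linspace(vmin, vmax, n_points)
    points: list[tuple[float, float | None]] = []
    for val in grid:
        scanned = model.copy()
        rxn = scanned.get_reaction(reaction_id)
        rxn.lower_bound = rxn.upper_bound = float(val)
        res = solve_fba(scanned)
        points.append((float(val), res.objective_value if res.optimal else None))
    return RobustnessCurve(reaction_id=reaction_id, points=points)
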