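"""Growth simulation across carbon sources and diet-stress detection.

A diet condition opens exactly one carbon-source exchange at a given uptake
rate, aerobic or anaerobic.  Between two conditions, a reaction is
diet-stressed when its optimal flux changes by more than ±10 %:
|flux_x| > 1.1·|flux_y| or |flux_x| < 0.9·|flux_y|, compared on magnitudes.
The ratio criterion is undefined at flux_y = 0; the closure used here is:
both fluxes (numerically) zero → not stressed; one zero, the other not →
stressed; a sign reversal between nonzero fluxes → stressed (a reaction
running backwards is more than a 10 % change under any reading).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constraint_analysis import Medium, apply_medium, flux_variability, solve_fba
from .model_io import MetabolicModel

__all__ = [
    "DietCondition",
    "DietStressReport",
    "CARBON_SOURCES",
    "simulate_conditions",
    "diet_stress_reactions",
    "stress_genes",
]

CARBON_SOURCES = {
    "acetate": "EX_ac_e",
    "ethanol": "EX_etoh_e",
    "glucose": "EX_glc__D_e",
    "succinate": "EX_succ_e",
}

STRESS_UPPER = 1.1
STRESS_LOWER = 0.9
ZERO_TOL = 1e-9


@dataclass
class DietCondition:
    """One growth condition: a single open carbon source at a given uptake
    rate (mmol·gDW⁻¹·h⁻¹), aerobic or anaerobic."""

    carbon_exchange: str
    uptake: float = 9.0
    aerobic: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.uptake <= 0:
            # uptake 0 is legal for what-if runs but flagged via name only
            if self.uptake < 0:
                raise ValueError("uptake must be >= 0")
        if not self.name:
            regime = "aerobic" if self.aerobic else "anaerobic"
            self.name = f"{self.carbon_exchange}@{self.uptake:g}_{regime}"


@dataclass
class DietStressReport:
    condition_x: str
    condition_y: str
    stressed: list[str]
    table: pd.DataFrame  # reaction, flux_x, flux_y, ratio, stressed
    gene_ids: set[str] = field(default_factory=set)


def simulate_conditions(
    model: MetabolicModel, conditions: Sequence[DietCondition]
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Optimal growth and flux vector per condition.

    Returns a growth table (condition, carbon_exchange, uptake, aerobic,
    growth_rate, status) and the per-condition flux vectors.  Infeasible
    conditions report growth 0 with status 'infeasible' rather than
    vanishing silently.
    """
    exchange_ids = {r.id for r in model.exchanges}
    rows = []
    fluxes: dict[str, dict[str, float]] = {}
    for cond in conditions:
        if cond.carbon_exchange not in exchange_ids:
            raise KeyError(
                f"condition {cond.name}: exchange {cond.carbon_exchange!r} "
                f"not in model {model.id!r}"
            )
        medium = Medium(exchanges={cond.carbon_exchange: cond.uptake},
                        aerobic=cond.aerobic)
        res = solve_fba(apply_medium(model, medium))
        growth = res.objective_value if res.optimal else 0.0
        rows.append((cond.name, cond.carbon_exchange, cond.uptake,
                     cond.aerobic, growth, res.status))
        fluxes[cond.name] = res.fluxes if res.optimal else {}
    table = pd.DataFrame(
        rows,
        columns=["condition", "carbon_exchange", "uptake", "aerobic",
                 "growth_rate", "status"],
    )
    return table, fluxes


def _is_stressed(x: float, y: float) -> bool:
    ax, ay = abs(x), abs(y)
    if ax < ZERO_TOL and ay < ZERO_TOL:
        return False
    if ax < ZERO_TOL or ay < ZERO_TOL:
        return True
    if x * y < 0:  # direction reversal
        return True
    return ax > STRESS_UPPER * ay or ax < STRESS_LOWER * ay


def diet_stress_reactions(
    flux_x: Mapping[str, float],
    flux_y: Mapping[str, float],
    condition_x: str = "x",
    condition_y: str = "y",
) -> DietStressReport:
    """Reactions whose flux changes by more than ±10 % between two optimal
    flux vectors (magnitude comparison with the zero/sign closure described
    in the module docstring).  Both vectors must cover the same reactions.
    """
    if set(flux_x) != set(flux_y):
        only_x = sorted(set(flux_x) - set(flux_y))[:5]
        only_y = sorted(set(flux_y) - set(flux_x))[:5]
        raise ValueError(
            f"flux vectors cover different reactions (e.g. only-x {only_x}, "
            f"only-y {only_y})"
        )
    rows = []
    stressed = []
    for rid in flux_x:
        x, y = flux_x[rid], flux_y[rid]
        hit = _is_stressed(x, y)
        ratio = abs(x) / abs(y) if abs(y) >= ZERO_TOL else np.inf if abs(x) >= ZERO_TOL else 1.0
        rows.append((rid, x, y, ratio, hit))
        if hit:
            stressed.append(rid)
    table = pd.DataFrame(
        rows, columns=["reaction", "flux_x", "flux_y", "ratio", "stressed"]
    ).sort_values("reaction").reset_index(drop=True)
    return DietStressReport(condition_x=condition_x, condition_y=condition_y,
                            stressed=sorted(stressed), table=table)


def stress_genes(report: DietStressReport, model: MetabolicModel) -> set[str]:
    """Union of GPR leaf genes over the stressed reactions (reactions with
    an empty GPR contribute none); also stored on the report."""
    genes: set[str] = set()
    for rid in report.stressed:
        genes |= model.get_reaction(rid).gpr.genes()
    report.gene_ids = genes
    return genes


def robust_condition_fluxes(
    model: MetabolicModel, condition: DietCondition, objective_fraction: float = 1.0
) -> dict[str, float]:
    """FVA-midpoint flux vector for a condition — a degeneracy-insensitive
    alternative to a single FBA vertex for stress comparison."""
    medium = Medium(exchanges={condition.carbon_exchange: condition.uptake},
                    aerobic=condition.aerobic)
    constrained = apply_medium(model, medium)
    fva = flux_variability(constrained, objective_fraction=objective_fraction)
    return {rid: 0.5 * (lo + hi) for rid, (lo, hi) in fva.ranges.items()}
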