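import numpy as np
import pytest

from gutflux.model_io import MetabolicModel, Metabolite, Reaction
from gutflux.synthetic_data import make_core_fixture


@pytest.fixture(scope="session")
def core_model() -> MetabolicModel:
    """The hand-curated core metabolism fixture (shared, read-only)."""
    return make_core_fixture()


@pytest.fixture()
def chain3():
    """∅ → A → B → C → ∅ with uptake 10: forced flux along a single path."""
    mets = [Metabolite(id=m, compartment="c") for m in "ABC"]
    rxns = [
        Reaction("EX_in", stoichiometry={"A": 1.0}, lower_bound=0.0, upper_bound=10.0),
        Reaction("R1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0,
                 upper_bound=1000.0),
        Reaction("R2", stoichiometry={"B": -1.0, "C": 1.0}, lower_bound=0.0,
                 upper_bound=1000.0),
        Reaction("DM_out", stoichiometry={"C": -1.0}, lower_bound=0.0,
                 upper_bound=1000.0, objective_coefficient=1.0),
    ]
    return MetabolicModel(id="chain3", metabolites=mets, reactions=rxns)


def brute_force_fba_optimum(model: MetabolicModel, tol: float = 1e-9) -> float:
    """Independent FBA oracle: enumerate polytope vertices of
    {v : S·v = 0, lb ≤ v ≤ ub} by fixing every size-(n−rank) coordinate
    subset at a bound and solving the remaining equality system; the LP
    optimum of a bounded feasible LP is attained at one of these points.

    Exponential — only for networks with ≤ ~8 reactions.
    """
    from itertools import combinations, product

    from gutflux.model_io import stoichiometric_matrix

    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.array([r.objective_coefficient for r in model.reactions])
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S, tol=1e-10)
    n_fix = n - rank
    best = None
    for fixed in combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for choice in product([0, 1], repeat=n_fix):
            v = np.zeros(n)
            for j, pick in zip(fixed, choice):
                v[j] = ub[j] if pick else lb[j]
            if free:
                A = S[:, free]
                b = -S[:, fixed] @ v[list(fixed)]
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = sol
            if np.abs(S @ v).max() > 1e-7:
                continue
            if (v < lb - tol).any() or (v > ub + tol).any():
                continue
            obj = float(c @ v)
            if best is None or obj > best:
                best = obj
    if best is None:
        raise AssertionError("oracle found no feasible vertex")
    return best
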