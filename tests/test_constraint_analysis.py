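"""FBA, media, FVA and robustness scans, cross-checked against a brute-force
polytope-vertex oracle and an independent solver (cobrapy) on the core
fixture."""

import numpy as np
import pytest

from gutflux.constraint_analysis import (
    Medium,
    apply_medium,
    flux_variability,
    robustness_scan,
    solve_fba,
)
from gutflux.model_io import MetabolicModel, Metabolite, Reaction, stoichiometric_matrix
from gutflux.synthetic_data import ToySpec, make_toy_model

from conftest import brute_force_fba_optimum


class TestSolveFBA:
    def test_chain_optimum_forced_by_uptake_bound(self, chain3):
        res = solve_fba(chain3)
        assert res.optimal
        assert res.objective_value == pytest.approx(10.0, abs=1e-8)
        # a single path forces every flux to the optimum
        for rid in ("EX_in", "R1", "R2", "DM_out"):
            assert res.fluxes[rid] == pytest.approx(10.0, abs=1e-8)

    def test_optimal_solution_satisfies_mass_balance_and_bounds(self, core_model):
        res = solve_fba(core_model)
        assert res.optimal
        S = stoichiometric_matrix(core_model)
        v = np.array([res.fluxes[r.id] for r in core_model.reactions])
        assert np.abs(S @ v).max() <= 1e-6
        for r in core_model.reactions:
            assert r.lower_bound - 1e-9 <= res.fluxes[r.id] <= r.upper_bound + 1e-9

    def test_matches_vertex_enumeration_on_small_networks(self):
        for seed in range(10):
            for topo in ("chain", "parallel", "diamond"):
                model, _ = make_toy_model(ToySpec(topology=topo, n_reactions=3,
                                                  seed=seed))
                lp = solve_fba(model).objective_value
                oracle = brute_force_fba_optimum(model)
                assert lp == pytest.approx(oracle, abs=1e-8), (topo, seed)

    def test_matches_independent_solver_on_core_fixture(self, core_model, tmp_path):
        """Dual-route check: our HiGHS-based FBA vs cobrapy on the same SBML."""
        cobra = pytest.importorskip("cobra")
        from gutflux.model_io import write_model

        path = tmp_path / "core.xml"
        write_model(core_model, path)
        ours = solve_fba(core_model).objective_value
        theirs = cobra.io.read_sbml_model(str(path)).optimize().objective_value
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_infeasible_status_propagated(self, chain3):
        broken = chain3.copy()
        broken.get_reaction("R1").upper_bound = 0.0
        broken.get_reaction("DM_out").lower_bound = 5.0  # demands impossible flux
        res = solve_fba(broken)
        assert res.status == "infeasible"
        assert res.objective_value is None

    def test_no_objective_raises(self, chain3):
        stripped = chain3.copy()
        for r in stripped.reactions:
            r.objective_coefficient = 0.0
        with pytest.raises(ValueError, match="objective"):
            solve_fba(stripped)

    def test_minimisation_sense(self, chain3):
        assert solve_fba(chain3, sense="min").objective_value == pytest.approx(0.0, abs=1e-9)


class TestMedium:
    def test_glucose_aerobic_bounds(self, core_model):
        m = apply_medium(core_model, Medium(exchanges={"EX_glc__D_e": 10.0},
                                            aerobic=True))
        assert m.get_reaction("EX_glc__D_e").lower_bound == -10.0
        assert m.get_reaction("EX_o2_e").lower_bound == -18.0
        # other carbon exchanges closed for uptake, secretion still open
        for rid in ("EX_ac_e", "EX_etoh_e", "EX_succ_e"):
            assert m.get_reaction(rid).lower_bound == 0.0
            assert m.get_reaction(rid).upper_bound > 0.0

    def test_anaerobic_closes_oxygen(self, core_model):
        m = apply_medium(core_model, Medium(exchanges={"EX_glc__D_e": 10.0},
                                            aerobic=False))
        assert m.get_reaction("EX_o2_e").lower_bound == 0.0

    def test_aerobic_optimum_dominates_anaerobic(self, core_model):
        med = {"EX_glc__D_e": 10.0}
        aero = solve_fba(apply_medium(core_model, Medium(exchanges=med, aerobic=True)))
        anaero = solve_fba(apply_medium(core_model, Medium(exchanges=med, aerobic=False)))
        assert aero.objective_value > anaero.objective_value > 0

    def test_zero_uptake_sole_carbon_kills_growth(self, core_model):
        m = apply_medium(core_model, Medium(exchanges={"EX_glc__D_e": 0.0},
                                            aerobic=True))
        res = solve_fba(m)
        # the maintenance floor (NGAM > 0) cannot be met without carbon
        assert res.status == "infeasible" or res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unknown_exchange_lists_valid_ones(self, core_model):
        with pytest.raises(KeyError, match="EX_glc__D_e"):
            apply_medium(core_model, Medium(exchanges={"EX_nope_e": 5.0}))

    def test_negative_uptake_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            Medium(exchanges={"EX_glc__D_e": -1.0})


class TestFVA:
    def test_parallel_branches_range_zero_to_capacity(self):
        """Two interchangeable branches of capacity 10 feeding a fixed
        demand of 10: each branch individually spans [0, 10]."""
        mets = [Metabolite(id="A", compartment="c"), Metabolite(id="B", compartment="c")]
        rxns = [
            Reaction("EX_A", stoichiometry={"A": 1.0}, lower_bound=0.0, upper_bound=20.0),
            Reaction("B1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction("B2", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction("DM_B", stoichiometry={"B": -1.0}, lower_bound=0.0, upper_bound=10.0,
                     objective_coefficient=1.0),
        ]
        model = MetabolicModel(id="par", metabolites=mets, reactions=rxns)
        fva = flux_variability(model, objective_fraction=1.0)
        for rid in ("B1", "B2"):
            lo, hi = fva.ranges[rid]
            assert lo == pytest.approx(0.0, abs=1e-6)
            assert hi == pytest.approx(10.0, abs=1e-6)

    def test_fba_flux_inside_interval_and_biomass_collapses(self, core_model):
        res = solve_fba(core_model)
        fva = flux_variability(core_model, objective_fraction=1.0)
        for rid, (lo, hi) in fva.ranges.items():
            assert lo - 1e-6 <= res.fluxes[rid] <= hi + 1e-6
        blo, bhi = fva.ranges["BIOMASS"]
        assert blo == pytest.approx(res.objective_value, abs=1e-6)
        assert bhi == pytest.approx(res.objective_value, abs=1e-6)

    def test_internal_two_cycle_classified_bidirectional(self):
        """Opposing reversible pair around the chain's middle: both members
        can circulate either way at the optimum."""
        model, opt = make_toy_model(ToySpec(topology="cycle", seed=1))
        fva = flux_variability(model, objective_fraction=1.0)
        assert fva.direction["L1"] == "bidirectional"
        assert fva.direction["L2"] == "bidirectional"
        assert solve_fba(model).objective_value == pytest.approx(opt, abs=1e-8)

    def test_direction_classes(self, chain3):
        fva = flux_variability(chain3, objective_fraction=1.0)
        assert fva.direction["R1"] == "forward"

    def test_invalid_fraction_rejected(self, chain3):
        with pytest.raises(ValueError):
            flux_variability(chain3, objective_fraction=0.0)


class TestRobustness:
    def test_essential_chain_reaction_controls_growth(self, chain3):
        curve = robustness_scan(chain3, "R1", n_points=6)
        pts = curve.feasible_points()
        # single-path stoichiometry: objective equals the forced flux
        for x, y in pts:
            assert y == pytest.approx(x, abs=1e-7)

    def test_redundant_branch_leaves_objective_flat(self):
        mets = [Metabolite(id="A", compartment="c"), Metabolite(id="B", compartment="c")]
        rxns = [
            Reaction("EX_A", stoichiometry={"A": 1.0}, lower_bound=0.0, upper_bound=20.0),
            Reaction("B1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction("B2", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction("DM_B", stoichiometry={"B": -1.0}, lower_bound=0.0, upper_bound=10.0,
                     objective_coefficient=1.0),
        ]
        model = MetabolicModel(id="par", metabolites=mets, reactions=rxns)
        curve = robustness_scan(model, "B1", n_points=6)
        objs = [y for _, y in curve.feasible_points()]
        assert all(o == pytest.approx(10.0, abs=1e-7) for o in objs)

    def test_scanning_biomass_traces_identity(self, chain3):
        curve = robustness_scan(chain3, "DM_out", n_points=5)
        for x, y in curve.points:
            if x <= 10.0 + 1e-9:
                assert y == pytest.approx(x, abs=1e-7)

    def test_unknown_reaction_raises(self, chain3):
        with pytest.raises(KeyError):
            robustness_scan(chain3, "NOPE", n_points=3)
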