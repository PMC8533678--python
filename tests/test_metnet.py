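"""Model I/O, environments, and FBA/pFBA/FVA against brute-force LP oracles."""

import numpy as np
import pytest

from stressflux import (
    ConfigurationError,
    EnvironmentSpec,
    FormatError,
    InfeasibleError,
    ToyNetworkSpec,
    fba,
    fva,
    generate_toy_model,
    pfba_reference,
    read_model,
    write_model,
)
from stressflux.gpr import BoolOp
from stressflux.metnet import MetabolicModel, Metabolite, Reaction

from _oracles import brute_fba, brute_fva, enumerate_vertices, model_polytope

ALL_VARIANTS = ["chain", "branched", "reversible"]


def _equal_models(a: MetabolicModel, b: MetabolicModel) -> bool:
    if [m.id for m in a.metabolites] != [m.id for m in b.metabolites]:
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if (
            ra.id != rb.id
            or ra.metabolites != rb.metabolites
            or ra.lower_bound != rb.lower_bound
            or ra.upper_bound != rb.upper_bound
            or ra.objective_coefficient != rb.objective_coefficient
            or ra.gpr != rb.gpr
        ):
            return False
    return True


class TestModelIO:
    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_json_round_trip_is_lossless(self, variant, tmp_path):
        model = generate_toy_model(ToyNetworkSpec(variant=variant))
        path = tmp_path / "model.json"
        write_model(model, path)
        loaded = read_model(path)
        assert _equal_models(model, loaded)
        assert loaded.notes["fba_optimum"] == model.notes["fba_optimum"]
        # write(read(x)) == read(x)
        path2 = tmp_path / "again.json"
        write_model(loaded, path2)
        assert _equal_models(loaded, read_model(path2))

    def test_gpr_parsed_into_ast(self, tmp_path, chain_model):
        path = tmp_path / "m.json"
        write_model(chain_model, path)
        r2 = read_model(path).reaction("R2")
        assert isinstance(r2.gpr, BoolOp) and r2.gpr.op == "and"

    def test_sbml_fbc_read(self, tmp_path, branched_model):
        cobra_io = pytest.importorskip("cobra.io")
        import cobra

        cm = cobra.Model("toy")
        mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment)
                for m in branched_model.metabolites}
        for r in branched_model.reactions:
            cr = cobra.Reaction(r.id)
            cr.add_metabolites({mets[k]: v for k, v in r.metabolites.items()})
            cr.bounds = (r.lower_bound, r.upper_bound)
            cr.gene_reaction_rule = r.gene_reaction_rule
            cm.add_reactions([cr])
        cm.objective = "BIOMASS"
        path = tmp_path / "toy.xml"
        cobra_io.write_sbml_model(cm, str(path))
        loaded = read_model(path, fmt="sbml-fbc")
        assert _equal_models(branched_model, loaded)

    def test_malformed_inputs_raise_format_error(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(FormatError):
            read_model(bad)
        with pytest.raises(ConfigurationError, match="format"):
            read_model(bad, fmt="csv")

    def test_structural_validation(self):
        model = MetabolicModel(
            id="broken",
            metabolites=[Metabolite("a_c")],
            reactions=[Reaction("R1", {"a_c": -1, "ghost": 1}, 0, 10, objective_coefficient=1)],
        )
        with pytest.raises(FormatError, match="R1"):
            model.validate()
        model2 = MetabolicModel(
            id="bounds",
            metabolites=[Metabolite("a_c")],
            reactions=[Reaction("R1", {"a_c": -1}, 5, 1, objective_coefficient=1)],
        )
        with pytest.raises(FormatError, match="lower bound"):
            model2.validate()


class TestEnvironment:
    def test_overrides_and_maintenance(self, chain_model):
        env = EnvironmentSpec(
            exchange_bounds={"EX_a": (-4.0, 0.0)}, atp_maintenance=1.0
        )
        state = fba(chain_model, env)
        assert state.objective_value == pytest.approx(3.0, abs=1e-9)

    def test_unknown_override_rejected(self, chain_model):
        with pytest.raises(ConfigurationError, match="EX_b"):
            EnvironmentSpec(exchange_bounds={"EX_b": (0, 0)}).apply(chain_model)

    def test_maintenance_requires_reaction(self, branched_model):
        env = EnvironmentSpec(atp_maintenance=1.0, atp_maintenance_reaction="NOPE")
        with pytest.raises(ConfigurationError, match="NOPE"):
            env.apply(branched_model)

    def test_nutrient_pool_caps_uptake(self, chain_model):
        env = EnvironmentSpec(nutrient_pools={"EX_a": 2.5})
        assert fba(chain_model, env).objective_value == pytest.approx(2.5)


class TestFba:
    def test_chain_optimum_is_uptake_bound(self, chain_model):
        assert fba(chain_model).objective_value == pytest.approx(10.0, abs=1e-9)

    def test_branched_prefers_high_yield_route(self, branched_model):
        state = pfba_reference(branched_model)
        assert state.objective_value == pytest.approx(10.0, abs=1e-9)
        # the optimum is re-imposed with relative slack 1e-9, so fluxes are
        # reproduced to ~1e-8 on a value of magnitude 10
        assert state["LO"] == pytest.approx(0.0, abs=1e-7)
        assert state["HI"] == pytest.approx(10.0, abs=1e-7)

    def test_excessive_maintenance_is_infeasible(self, chain_model):
        env = EnvironmentSpec(atp_maintenance=50.0)  # uptake is only 10
        with pytest.raises(InfeasibleError):
            fba(chain_model, env)

    def test_steady_state_residual(self, reversible_model):
        state = fba(reversible_model)
        S, _, rxn_ids = reversible_model.stoichiometric_matrix()
        resid = S @ state.fluxes.reindex(rxn_ids).to_numpy()
        assert np.max(np.abs(resid)) <= 1e-6

    def test_scaling_equivariance(self, branched_model):
        scaled = branched_model.copy()
        c = 3.0
        for r in scaled.reactions:
            r.lower_bound *= c
            r.upper_bound *= c
        assert fba(scaled).objective_value == pytest.approx(
            c * fba(branched_model).objective_value, rel=1e-9
        )


class TestPfba:
    def test_futile_cycle_is_silenced(self, reversible_model):
        state = pfba_reference(reversible_model)
        assert state["CYC1"] == pytest.approx(0.0, abs=1e-8)
        assert state["CYC2"] == pytest.approx(0.0, abs=1e-8)
        assert state.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_degenerate_routes_minimum_total_flux(self, branched_model):
        # make both routes yield 1: the optimal face is a segment and the
        # minimal total flux over it is attained at a vertex
        model = branched_model.copy()
        model.reaction("LO").metabolites["b_c"] = 1.0
        state = pfba_reference(model)
        total = float(np.abs(state.fluxes).sum())
        S, lb, ub, rxn_ids = model_polytope(model)
        verts = enumerate_vertices(S, lb, ub)
        obj = np.array([1.0 if r == "BIOMASS" else 0.0 for r in rxn_ids])
        opt = (verts @ obj).max()
        face = verts[np.abs(verts @ obj - opt) < 1e-7]
        assert total == pytest.approx(np.abs(face).sum(axis=1).min(), abs=1e-7)

    def test_flux_within_fva_ranges(self, reversible_model):
        state = pfba_reference(reversible_model)
        rng = fva(reversible_model, fix_objective_at=state.objective_value)
        for rid in reversible_model.reaction_ids:
            lo, hi = rng[rid]
            assert lo - 1e-7 <= state[rid] <= hi + 1e-7


class TestFva:
    def test_chain_is_fully_determined_at_optimum(self, chain_model):
        rng = fva(chain_model, fix_objective_at=10.0)
        width = rng.upper - rng.lower
        assert (width.abs() < 1e-7).all()

    def test_futile_cycle_width_equals_cycle_bound(self, reversible_model):
        rng = fva(reversible_model, fix_objective_at=10.0)
        assert rng["CYC1"] == pytest.approx((0.0, 5.0), abs=1e-7)
        assert rng["CYC2"] == pytest.approx((0.0, 5.0), abs=1e-7)
        assert rng["R1"] == pytest.approx((10.0, 10.0), abs=1e-6)

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_unfixed_ranges_match_vertex_enumeration(self, variant):
        model = generate_toy_model(ToyNetworkSpec(variant=variant))
        mine = fva(model, fix_objective_at=None)
        ref = brute_fva(model, None, None)
        for rid, (lo, hi) in ref.items():
            assert mine[rid][0] == pytest.approx(lo, abs=1e-8)
            assert mine[rid][1] == pytest.approx(hi, abs=1e-8)

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_agrees_with_cobrapy_solver(self, variant, tmp_path):
        # independent established implementation on the same model file
        import cobra.io
        from cobra.flux_analysis import flux_variability_analysis

        model = generate_toy_model(ToyNetworkSpec(variant=variant))
        path = tmp_path / "toy.json"
        write_model(model, path)
        cm = cobra.io.load_json_model(str(path))
        sol = cm.optimize()
        mine = fba(model)
        assert mine.objective_value == pytest.approx(sol.objective_value, abs=1e-7)
        theirs = flux_variability_analysis(cm, fraction_of_optimum=1.0)
        ours = fva(model, fix_objective_at=mine.objective_value)
        for rid in model.reaction_ids:
            assert ours[rid][0] == pytest.approx(theirs.loc[rid, "minimum"], abs=1e-6)
            assert ours[rid][1] == pytest.approx(theirs.loc[rid, "maximum"], abs=1e-6)

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_objective_matches_vertex_enumeration(self, variant):
        model = generate_toy_model(ToyNetworkSpec(variant=variant, atp_maintenance=2.0))
        z_ref, _ = brute_fba(model, model.objective)
        assert fba(model).objective_value == pytest.approx(z_ref, abs=1e-8)
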