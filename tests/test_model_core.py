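"""Model data structures, readers, preparation and gene screening."""

import math

import pytest

from epistanet.fba import fba
from epistanet.gpr import Gene, UNSATISFIABLE, parse_gpr
from epistanet.model import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    apply_medium,
    apply_strain_background,
    gene_deletion_bounds,
    read_tabular_model,
    screen_nonessential_unblocked_genes,
    write_tabular_model,
)
from epistanet.sbml_io import read_sbml, write_sbml
from epistanet.validation import fba_by_vertex_enumeration

TABULAR = """id\tequation\tlb\tub\tgpr
EX_A\tA ->\t-10\t1000\t
E1\tA -> B\t0\t1000\tg1
SHUTTLE\tB <-> C\t-1000\t1000\tg1 and g2
BIOMASS\tB ->\t0\t1000\t
"""


@pytest.fixture
def tabular_path(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(TABULAR)
    return path


class TestTabularDialect:
    def test_read_minimal_model(self, tabular_path):
        model = read_tabular_model(tabular_path)
        assert len(model.reactions) == 4
        assert model.genes == {"g1", "g2"}
        e1 = model.reaction("E1")
        assert e1.stoich == {"A": -1.0, "B": 1.0}
        assert (e1.lb, e1.ub) == (0.0, 1000.0)
        assert e1.gpr == Gene("g1")
        assert not e1.reversible
        assert model.reaction("EX_A").is_exchange
        assert model.biomass_reaction_id == "BIOMASS"

    def test_reversible_arrow_gives_negative_lb(self, tabular_path):
        model = read_tabular_model(tabular_path)
        shuttle = model.reaction("SHUTTLE")
        assert shuttle.reversible and shuttle.lb < 0

    def test_round_trip_is_identical(self, tabular_path, tmp_path):
        model = read_tabular_model(tabular_path)
        out = tmp_path / "rt.tsv"
        write_tabular_model(model, out)
        model2 = read_tabular_model(out)
        assert [r.id for r in model2.reactions] == [r.id for r in model.reactions]
        for r1, r2 in zip(model.reactions, model2.reactions):
            assert (r1.stoich, r1.lb, r1.ub, r1.gpr, r1.is_exchange) == (
                r2.stoich, r2.lb, r2.ub, r2.gpr, r2.is_exchange)

    def test_irreversible_arrow_with_negative_lb_is_row_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tequation\tlb\tub\tgpr\nR1\tA -> B\t-5\t10\t\n")
        with pytest.raises(ModelError, match="line 2"):
            read_tabular_model(path)

    def test_malformed_equation_is_row_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tequation\tlb\tub\tgpr\nBIOMASS\tA = B\t0\t10\t\n")
        with pytest.raises(ModelError, match="line 2"):
            read_tabular_model(path)


class TestSbmlRoundTrip:
    def test_round_trip_preserves_network_and_gprs(self, tmp_path, two_route_model):
        path = tmp_path / "toy.xml"
        write_sbml(two_route_model, path)
        model2 = read_sbml(path)
        assert model2.genes == two_route_model.genes
        assert set(model2.reaction_ids) == set(two_route_model.reaction_ids)
        assert model2.reaction("DIRECT").gpr == Gene("gd")
        assert model2.biomass_reaction_id == "BIOMASS"

    def test_sbml_and_tabular_models_agree_on_fba(self, tmp_path, two_route_model):
        sbml = tmp_path / "toy.xml"
        tsv = tmp_path / "toy.tsv"
        write_sbml(two_route_model, sbml)
        write_tabular_model(two_route_model, tsv)
        v_sbml = fba(read_sbml(sbml)).objective_value
        v_tsv = fba(read_tabular_model(tsv)).objective_value
        assert v_sbml == pytest.approx(v_tsv, abs=1e-6)
        assert v_sbml == pytest.approx(10.0, abs=1e-6)

    def test_unreadable_file_raises_format_error(self, tmp_path):
        path = tmp_path / "junk.xml"
        path.write_text("this is not SBML")
        with pytest.raises(ModelError, match="junk.xml"):
            read_sbml(path)


class TestStrainBackground:
    def test_or_survivor_keeps_bounds(self, two_route_model):
        model = apply_strain_background(two_route_model, ["gi1"])
        direct = model.reaction("DIRECT")
        assert (direct.lb, direct.ub) == (0.0, 1000.0)
        ind1 = model.reaction("IND1")
        assert (ind1.lb, ind1.ub) == (0.0, 0.0)
        assert ind1.gpr is UNSATISFIABLE
        assert "gi1" not in model.genes

    def test_and_member_removal_closes_reaction(self):
        model = MetabolicModel(
            [Metabolite("A"), Metabolite("B")],
            [
                Reaction("EX_A", {"A": -1.0}, lb=-10, is_exchange=True),
                Reaction("R", {"A": -1.0, "B": 1.0}, gpr=parse_gpr("g1 and g2")),
                Reaction("BIOMASS", {"B": -1.0}),
            ],
            {"g1", "g2"},
            "BIOMASS",
        )
        out = apply_strain_background(model, ["g1"])
        assert (out.reaction("R").lb, out.reaction("R").ub) == (0.0, 0.0)

    def test_removing_nothing_is_identity(self, two_route_model):
        out = apply_strain_background(two_route_model, [])
        assert out.genes == two_route_model.genes
        for r1, r2 in zip(two_route_model.reactions, out.reactions):
            assert (r1.lb, r1.ub, r1.gpr) == (r2.lb, r2.ub, r2.gpr)

    def test_missing_gene_warns_not_raises(self, two_route_model, caplog):
        with caplog.at_level("WARNING"):
            out = apply_strain_background(two_route_model, ["CAN1"])
        assert "CAN1" in caplog.text
        assert out.genes == two_route_model.genes

    def test_background_removal_commutes_with_deletion_bounds(self, two_route_model):
        """Encoding a deletion as background removal or as knockout bounds
        must close the same reactions with the same bounds."""
        background = {"gd", "gi1"}
        via_background = apply_strain_background(two_route_model, background)
        bounds_a = {r.id: (r.lb, r.ub) for r in via_background.reactions}
        bounds_b = gene_deletion_bounds(two_route_model, background)
        assert bounds_a == bounds_b


class TestMedium:
    def test_single_carbon_source(self, two_route_model):
        out = apply_medium(two_route_model, {"EX_A": 5.0})
        assert out.reaction("EX_A").lb == -5.0

    def test_empty_medium_closes_uptake_and_growth(self, two_route_model):
        out = apply_medium(two_route_model, {})
        assert out.reaction("EX_A").lb == 0.0
        assert fba(out).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_non_exchange_key_is_config_error(self, two_route_model):
        with pytest.raises(ModelError, match="non-exchange"):
            apply_medium(two_route_model, {"DIRECT": 5.0})

    def test_two_carbon_sources_both_open(self):
        model = MetabolicModel(
            [Metabolite("A"), Metabolite("B")],
            [
                Reaction("EX_A", {"A": -1.0}, lb=0.0, is_exchange=True),
                Reaction("EX_B", {"B": -1.0}, lb=0.0, is_exchange=True),
                Reaction("R", {"A": -1.0, "B": 1.0}),
                Reaction("BIOMASS", {"B": -1.0}),
            ],
            set(),
            "BIOMASS",
        )
        out = apply_medium(model, {"EX_A": 3.0, "EX_B": 4.0})
        assert out.reaction("EX_A").lb == -3.0
        assert out.reaction("EX_B").lb == -4.0
        assert fba(out).objective_value == pytest.approx(7.0, abs=1e-6)


class TestGeneDeletionBounds:
    GPR_MODEL_RULE = "(g1 and g2) or g3"

    @pytest.fixture
    def gated_model(self):
        return MetabolicModel(
            [Metabolite("A"), Metabolite("B")],
            [
                Reaction("EX_A", {"A": -1.0}, lb=-10, is_exchange=True),
                Reaction("R", {"A": -1.0, "B": 1.0}, gpr=parse_gpr(self.GPR_MODEL_RULE)),
                Reaction("BIOMASS", {"B": -1.0}),
            ],
            {"g1", "g2", "g3"},
            "BIOMASS",
        )

    def test_isoenzyme_rescues(self, gated_model):
        assert gene_deletion_bounds(gated_model, {"g1"})["R"] == (0.0, 1000.0)

    def test_double_deletion_closes(self, gated_model):
        assert gene_deletion_bounds(gated_model, {"g1", "g3"})["R"] == (0.0, 0.0)

    def test_empty_deletion_is_identity(self, gated_model):
        bounds = gene_deletion_bounds(gated_model, set())
        assert all(bounds[r.id] == (r.lb, r.ub) for r in gated_model.reactions)

    def test_unknown_gene_raises(self, gated_model):
        with pytest.raises(ModelError, match="unknown gene"):
            gene_deletion_bounds(gated_model, {"nope"})


class TestScreening:
    def test_essential_blocked_and_kept_genes(self, screen_model):
        kept = screen_nonessential_unblocked_genes(screen_model)
        assert kept == {"g1", "g2"}  # gbio essential, gdead blocked

    def test_agrees_with_brute_force_single_knockouts(self, screen_model):
        """Independent check: single-knockout fitness by vertex enumeration."""
        wt = fba_by_vertex_enumeration(screen_model)
        essential = set()
        for gene in screen_model.genes:
            v = fba_by_vertex_enumeration(
                screen_model, gene_deletion_bounds(screen_model, {gene})
            )
            if v is None or v / wt < 1e-3:
                essential.add(gene)
        kept = screen_nonessential_unblocked_genes(screen_model)
        assert essential == {"gbio"}
        assert kept == screen_model.genes - essential - {"gdead"}
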