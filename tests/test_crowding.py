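"""MOMENT and ccFBA: closed forms, kcat imputation, multifunctional
accounting, and the structural invariants of the crowding formulation."""

import pytest

from epistanet.crowding import (
    EnzymeCostParams,
    ccfba,
    crowding_wildtype_and_knockouts,
    impute_kcats,
    moment_fba,
)
from epistanet.gpr import Gene, parse_gpr
from epistanet.model import MetabolicModel, Metabolite, Reaction
from epistanet.synth import (
    build_converging_pathway_motif,
    build_parallel_isoenzyme_motif,
    random_toy_model,
)


def single_enzyme_chain(kcat, mw, C):
    model = MetabolicModel(
        [Metabolite("A"), Metabolite("B")],
        [
            Reaction("EX_A", {"A": -1.0}, lb=-10.0, is_exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, gpr=Gene("g1")),
            Reaction("BIOMASS", {"B": -1.0}),
        ],
        {"g1"},
        "BIOMASS",
    )
    return model, EnzymeCostParams({"R1": kcat}, {"g1": mw}, C=C)


class TestImputation:
    @pytest.fixture
    def three_gated_model(self):
        mets = [Metabolite(m) for m in "ABCD"]
        rxns = [
            Reaction("EX_A", {"A": -1.0}, lb=-10.0, is_exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, gpr=Gene("g1")),
            Reaction("R2", {"B": -1.0, "C": 1.0}, gpr=Gene("g2")),
            Reaction("R3", {"C": -1.0, "D": 1.0}, gpr=Gene("g3")),
            Reaction("SPONT", {"B": -1.0, "C": 1.0}),
            Reaction("BIOMASS", {"D": -1.0}),
        ]
        return MetabolicModel(mets, rxns, {"g1", "g2", "g3"}, "BIOMASS")

    def test_missing_entries_get_the_median_default(self, three_gated_model):
        kcat = impute_kcats({"R1": 40.0}, three_gated_model, kcat_med=11.5)
        assert kcat == {"R1": 40.0, "R2": 11.5, "R3": 11.5}

    def test_full_table_unchanged(self, three_gated_model):
        table = {"R1": 1.0, "R2": 2.0, "R3": 3.0}
        assert impute_kcats(table, three_gated_model) == table

    def test_empty_table_imputes_everything(self, three_gated_model):
        kcat = impute_kcats({}, three_gated_model)
        assert set(kcat.values()) == {11.5}
        assert "SPONT" not in kcat and "EX_A" not in kcat and "BIOMASS" not in kcat

    def test_non_positive_kcat_rejected(self, three_gated_model):
        with pytest.raises(ValueError, match="non-positive"):
            impute_kcats({"R1": -3.0}, three_gated_model)


class TestClosedForms:
    @pytest.mark.parametrize("method", [moment_fba, ccfba])
    @pytest.mark.parametrize(
        "kcat, mw, C, expected",
        [
            (10.0, 1.0, 1.0, 10.0),
            (11.5, 1.0, 0.27, 3.105),  # median kcat x default budget
            (20.0, 2.5, 0.5, 4.0),
        ],
    )
    def test_single_gated_step_growth_is_kcat_C_over_mw(self, method, kcat, mw, C, expected):
        model, params = single_enzyme_chain(kcat, mw, C)
        sol = method(model, params)
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)
        assert sol.budget_used == pytest.approx(C, abs=1e-6)  # budget active

    @pytest.mark.parametrize("method", [moment_fba, ccfba])
    def test_doubling_kcats_doubles_growth(self, method):
        model, params = single_enzyme_chain(10.0, 1.0, 1.0)
        doubled = EnzymeCostParams({"R1": 20.0}, {"g1": 1.0}, C=1.0)
        assert method(model, doubled).objective_value == pytest.approx(
            2 * method(model, params).objective_value, abs=1e-6
        )

    def test_reversible_gated_reaction_is_capped_forward(self):
        model = MetabolicModel(
            [Metabolite("A"), Metabolite("B")],
            [
                Reaction("EX_A", {"A": -1.0}, lb=-10.0, is_exchange=True),
                Reaction("R1", {"A": -1.0, "B": 1.0}, lb=-1000.0, gpr=Gene("g1")),
                Reaction("BIOMASS", {"B": -1.0}),
            ],
            {"g1"},
            "BIOMASS",
        )
        params = EnzymeCostParams({"R1": 10.0}, {"g1": 1.0}, C=1.0)
        assert moment_fba(model, params).objective_value == pytest.approx(10.0, abs=1e-6)


class TestMultifunctionalAccounting:
    def test_serial_reactions_moment_reuses_ccfba_splits(self, serial_multifunctional_model):
        """One gene gating A->B->C: MOMENT reuses the full pool for both
        steps (flux kcat*C/m = 10), ccFBA splits it (flux 5) — a factor-2 gap."""
        model, params = serial_multifunctional_model
        v_moment = moment_fba(model, params).objective_value
        v_ccfba = ccfba(model, params).objective_value
        assert v_moment == pytest.approx(10.0, abs=1e-6)
        assert v_ccfba == pytest.approx(5.0, abs=1e-6)

    def test_isoenzyme_budget_goes_to_the_fast_isoform(self):
        model, params = build_parallel_isoenzyme_motif(kcats=(10.0, 1.0), C=1.0)
        sol = ccfba(model, params)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)
        assert sol.enzyme_concentrations["g1"] == pytest.approx(1.0, abs=1e-6)
        assert sol.enzyme_concentrations["g2"] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5, 6])
    def test_ccfba_never_beats_moment(self, seed):
        model, params = random_toy_model(n_branch_points=3, seed=seed, p_reuse=0.5)
        v_m = moment_fba(model, params).objective_value
        v_c = ccfba(model, params).objective_value
        assert v_c <= v_m + 1e-6

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_methods_coincide_without_multifunctional_genes(self, seed):
        model, params = random_toy_model(n_branch_points=3, seed=seed, p_reuse=0.0)
        v_m = moment_fba(model, params).objective_value
        v_c = ccfba(model, params).objective_value
        assert v_c == pytest.approx(v_m, abs=1e-6)

    def test_and_complex_limited_by_scarcest_subunit(self):
        """AND complex with unequal masses: optimum allocates equal
        concentrations to both subunits, flux = kcat*C/(m1+m2)."""
        model = MetabolicModel(
            [Metabolite("A"), Metabolite("B")],
            [
                Reaction("EX_A", {"A": -1.0}, lb=-10.0, is_exchange=True),
                Reaction("R1", {"A": -1.0, "B": 1.0}, gpr=parse_gpr("g1 and g2")),
                Reaction("BIOMASS", {"B": -1.0}),
            ],
            {"g1", "g2"},
            "BIOMASS",
        )
        params = EnzymeCostParams({"R1": 10.0}, {"g1": 1.0, "g2": 3.0}, C=1.0)
        sol = moment_fba(model, params)
        assert sol.objective_value == pytest.approx(10.0 / 4.0, abs=1e-6)


class TestBudgetInvariance:
    @pytest.mark.parametrize("method", [moment_fba, ccfba])
    def test_epsilon_does_not_depend_on_C(self, method):
        """Growth is linear in C, so knockout/wild-type ratios — and hence
        epistasis — are invariant to the budget's numeric value."""
        model, params = random_toy_model(n_branch_points=3, seed=7, p_reuse=0.4)
        genes = sorted(model.genes)[:4]
        pairs = [(genes[0], genes[1]), (genes[2], genes[3])]

        def eps_table(C):
            sols = crowding_wildtype_and_knockouts(
                model, params.with_budget(C), pairs,
                method="moment" if method is moment_fba else "ccfba",
            )
            wt = sols[frozenset()].objective_value
            out = {}
            for a, b in pairs:
                W = lambda key: (
                    0.0 if sols[key].status != "optimal"
                    else sols[key].objective_value / wt
                )
                out[(a, b)] = W(frozenset({a, b})) - W(frozenset({a})) * W(frozenset({b}))
            return out

        base = eps_table(0.27)
        for C in (0.05, 1.0):
            other = eps_table(C)
            for pair in pairs:
                assert other[pair] == pytest.approx(base[pair], abs=1e-6)


class TestBatchInterface:
    def test_empty_pair_list_gives_wild_type_only(self):
        model, params = build_parallel_isoenzyme_motif()
        sols = crowding_wildtype_and_knockouts(model, params, [])
        assert set(sols) == {frozenset()}

    def test_parallel_motif_double_knockout_fitness(self):
        """Fast-isoform pair: both singles neutral, the double drops to the
        slow backup's share — strong negative epistasis."""
        model, params = build_parallel_isoenzyme_motif(kcats=(10.0, 10.0, 1.0), C=1.0)
        sols = crowding_wildtype_and_knockouts(model, params, [("g1", "g2")], method="ccfba")
        wt = sols[frozenset()].objective_value
        W1 = sols[frozenset({"g1"})].objective_value / wt
        W2 = sols[frozenset({"g2"})].objective_value / wt
        W12 = sols[frozenset({"g1", "g2"})].objective_value / wt
        assert (W1, W2) == pytest.approx((1.0, 1.0), abs=1e-6)
        assert W12 == pytest.approx(0.1, abs=1e-6)
        assert W12 - W1 * W2 == pytest.approx(-0.9, abs=1e-6)

    def test_converging_motif_gives_positive_epistasis(self):
        model, params = build_converging_pathway_motif()
        sols = crowding_wildtype_and_knockouts(model, params, [("gxf", "gyf")])
        wt = sols[frozenset()].objective_value
        W1 = sols[frozenset({"gxf"})].objective_value / wt
        W12 = sols[frozenset({"gxf", "gyf"})].objective_value / wt
        assert W12 - W1 * W1 > 0


def test_params_validation():
    with pytest.raises(ValueError, match="budget"):
        EnzymeCostParams({"R1": 1.0}, {"g1": 1.0}, C=0.0)
    with pytest.raises(ValueError, match="kcat"):
        EnzymeCostParams({"R1": -1.0}, {"g1": 1.0})
    with pytest.raises(ValueError, match="molar mass"):
        EnzymeCostParams({"R1": 1.0}, {"g1": 0.0})
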