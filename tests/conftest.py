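"""Shared toy-network fixtures.

All fixtures are built programmatically and sized so that brute-force
oracles (vertex enumeration, hand LPs) stay exact and fast.
"""

import pytest

from epistanet.gpr import And, Gene, Or
from epistanet.model import MetabolicModel, Metabolite, Reaction


def make_model(mets, reactions, genes, biomass="BIOMASS"):
    return MetabolicModel([Metabolite(m) for m in mets], reactions, set(genes), biomass)


@pytest.fixture
def chain_model():
    """EX_A (uptake 10) -> A -> B -> biomass, unit stoichiometry."""
    return make_model(
        ["A", "B"],
        [
            Reaction("EX_A", {"A": -1.0}, lb=-10.0, is_exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, gpr=Gene("g1")),
            Reaction("BIOMASS", {"B": -1.0}),
        ],
        {"g1"},
    )


@pytest.fixture
def capped_chain_model():
    """Same chain with the internal step capped at 4."""
    return make_model(
        ["A", "B"],
        [
            Reaction("EX_A", {"A": -1.0}, lb=-10.0, is_exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, ub=4.0, gpr=Gene("g1")),
            Reaction("BIOMASS", {"B": -1.0}),
        ],
        {"g1"},
    )


@pytest.fixture
def branched_model():
    """6-reaction branched network with interior caps; uptake 20.

    A splits into B (cap 6) and C (cap 7); C rejoins through a capped step
    (5); optimum 6 + 5 = 11 by hand, checked against vertex enumeration.
    """
    return make_model(
        ["A", "B", "C", "D"],
        [
            Reaction("EX_A", {"A": -1.0}, lb=-20.0, is_exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, ub=6.0),
            Reaction("R2", {"A": -1.0, "C": 1.0}, ub=7.0),
            Reaction("R3", {"B": -1.0, "D": 1.0}),
            Reaction("R4", {"C": -1.0, "D": 1.0}, ub=5.0),
            Reaction("BIOMASS", {"D": -1.0}),
        ],
        set(),
    )


@pytest.fixture
def two_route_model():
    """Two parallel A->B routes: direct (1 reaction, gene gd) and a
    2-reaction detour via C (genes gi1, gi2)."""
    return make_model(
        ["A", "B", "C"],
        [
            Reaction("EX_A", {"A": -1.0}, lb=-10.0, is_exchange=True),
            Reaction("DIRECT", {"A": -1.0, "B": 1.0}, gpr=Gene("gd")),
            Reaction("IND1", {"A": -1.0, "C": 1.0}, gpr=Gene("gi1")),
            Reaction("IND2", {"C": -1.0, "B": 1.0}, gpr=Gene("gi2")),
            Reaction("BIOMASS", {"B": -1.0}),
        ],
        {"gd", "gi1", "gi2"},
    )


@pytest.fixture
def screen_model():
    """5-reaction screening fixture: parallel routes (g1, g2), an essential
    biomass gate (gbio) and a gene gating only a dead-end (gdead)."""
    return make_model(
        ["A", "B", "D"],
        [
            Reaction("EX_A", {"A": -1.0}, lb=-10.0, is_exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, gpr=Gene("g1")),
            Reaction("R2", {"A": -1.0, "B": 1.0}, gpr=Gene("g2")),
            Reaction("RD", {"B": -1.0, "D": 1.0}, gpr=Gene("gdead")),
            Reaction("BIOMASS", {"B": -1.0}, gpr=Gene("gbio")),
        ],
        {"g1", "g2", "gbio", "gdead"},
    )


@pytest.fixture
def serial_multifunctional_model():
    """One gene gating two serial reactions: the fixture separating MOMENT
    (enzyme reused, flux kcat*C/m) from ccFBA (enzyme split, half that)."""
    from epistanet.crowding import EnzymeCostParams

    model = make_model(
        ["A", "B", "C"],
        [
            Reaction("EX_A", {"A": -1.0}, lb=-10.0, is_exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, gpr=Gene("g1")),
            Reaction("R2", {"B": -1.0, "C": 1.0}, gpr=Gene("g1")),
            Reaction("BIOMASS", {"C": -1.0}),
        ],
        {"g1"},
    )
    params = EnzymeCostParams({"R1": 10.0, "R2": 10.0}, {"g1": 1.0}, C=1.0)
    return model, params
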