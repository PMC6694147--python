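"""SBML readers/writers, delegating format handling to cobrapy.

cobrapy copes with both SBML L3 + fbc gene-product associations and the
older L2 notes-field GPR encoding; models are converted to and from this
package's :class:`~epistanet.model.MetabolicModel`.  Only the features
the pipeline needs survive the round trip: stoichiometry, bounds, GPR
rules, exchange flags, and the (single) biomass objective.
"""

from __future__ import annotations

import logging
from typing import Optional

from .gpr import gpr_genes, gpr_to_string, parse_gpr
from .model import MetabolicModel, Metabolite, ModelError, Reaction

logger = logging.getLogger(__name__)

__all__ = ["read_sbml", "write_sbml", "from_cobra", "to_cobra"]


def from_cobra(cmodel) -> MetabolicModel:
    """Convert a cobrapy model (objective must be a single reaction)."""
    from cobra.util.solver import linear_reaction_coefficients

    obj = linear_reaction_coefficients(cmodel)
    if len(obj) != 1:
        raise ModelError(
            f"model {cmodel.id!r}: need exactly one objective reaction, found {len(obj)}"
        )
    biomass_id = next(iter(obj)).id

    metabolites = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c")
        for m in cmodel.metabolites
    ]
    reactions = []
    genes = set()
    for rxn in cmodel.reactions:
        rule = rxn.gene_reaction_rule or None
        try:
            gpr = parse_gpr(rule)
        except Exception as exc:
            raise ModelError(f"reaction {rxn.id}: cannot parse GPR {rule!r}: {exc}") from exc
        genes |= gpr_genes(gpr)
        reactions.append(
            Reaction(
                id=rxn.id,
                stoich={m.id: float(c) for m, c in rxn.metabolites.items()},
                lb=float(rxn.lower_bound),
                ub=float(rxn.upper_bound),
                gpr=gpr,
                is_exchange=bool(rxn.boundary),
                name=rxn.name or "",
            )
        )
    genes |= {g.id for g in cmodel.genes}
    model = MetabolicModel(metabolites, reactions, genes, biomass_id)
    logger.info(
        "converted SBML model %r: %d metabolites, %d reactions, %d genes",
        cmodel.id, len(metabolites), len(reactions), len(genes),
    )
    return model


def to_cobra(model: MetabolicModel, model_id: str = "model"):
    """Convert to a cobrapy model (for SBML export or cross-checking)."""
    import cobra

    cmodel = cobra.Model(model_id)
    cmets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    for r in model.reactions:
        crxn = cobra.Reaction(r.id, name=r.name, lower_bound=r.lb, upper_bound=r.ub)
        cmodel.add_reactions([crxn])
        crxn.add_metabolites({cmets[m]: c for m, c in r.stoich.items()})
        if r.gpr is not None:
            crxn.gene_reaction_rule = gpr_to_string(r.gpr)
    cmodel.objective = model.biomass_reaction_id
    return cmodel


def read_sbml(path) -> MetabolicModel:
    """Read an SBML file (L2 with notes GPRs or L3 + fbc)."""
    import cobra.io

    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise ModelError(f"cannot read SBML file {path}: {exc}") from exc
    return from_cobra(cmodel)


def write_sbml(model: MetabolicModel, path) -> None:
    """Write the model as SBML L3 + fbc."""
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), str(path))
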