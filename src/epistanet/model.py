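"""Stoichiometric network data model and model preparation.

The central object is :class:`MetabolicModel`: metabolites, reactions with
flux bounds and GPR rules, a gene set, and a biomass objective.  Exchange
reactions are written in the ``met ->`` orientation, so uptake is a
*negative* flux; a :class:`Medium` stores uptake magnitudes and
:func:`apply_medium` opens the corresponding lower bounds.

Model preparation follows the usual knockout-simulation workflow:
removing strain-background genes, applying a medium, translating gene
deletions into reaction bounds, and screening for the analysable gene set
(non-essential, non-blocked genes).
"""

from __future__ import annotations

import copy
import json
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np

from .gpr import (
    UNSATISFIABLE,
    GprExpression,
    evaluate_gpr,
    gpr_genes,
    gpr_to_string,
    parse_gpr,
    remove_genes,
)

logger = logging.getLogger(__name__)

#: Conventional "effectively infinite" flux bound (mmol gDW^-1 h^-1).
DEFAULT_BOUND = 1000.0


class ModelError(ValueError):
    """Raised for malformed models or model files."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_external: bool = False


@dataclass
class Reaction:
    id: str
    stoich: Dict[str, float]
    lb: float = 0.0
    ub: float = DEFAULT_BOUND
    gpr: GprExpression = None
    is_exchange: bool = False
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ModelError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")


@dataclass
class MetabolicModel:
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    genes: Set[str]
    biomass_reaction_id: str
    _rxn_index: Dict[str, Reaction] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._rxn_index = {r.id: r for r in self.reactions}
        self.validate()

    # -- lookups ---------------------------------------------------------
    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise ModelError(f"no reaction with id {rxn_id!r}") from None

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def biomass_reaction(self) -> Reaction:
        return self.reaction(self.biomass_reaction_id)

    def genes_to_reactions(self) -> Dict[str, List[str]]:
        """Map each gene to the reactions whose GPR mentions it."""
        out: Dict[str, List[str]] = {g: [] for g in self.genes}
        for r in self.reactions:
            for g in gpr_genes(r.gpr):
                out.setdefault(g, []).append(r.id)
        return out

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            raise ModelError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            raise ModelError("duplicate reaction ids")
        known = set(met_ids)
        external = {m.id for m in self.metabolites if m.is_external}
        for r in self.reactions:
            missing = set(r.stoich) - known
            if missing:
                raise ModelError(f"reaction {r.id} references unknown metabolites {sorted(missing)}")
            if r.is_exchange and len(set(r.stoich) - external) != 1:
                raise ModelError(
                    f"exchange reaction {r.id} must touch exactly one internal metabolite"
                )
            stray = gpr_genes(r.gpr) - self.genes
            if stray:
                raise ModelError(f"reaction {r.id} GPR references unknown genes {sorted(stray)}")
        if self.biomass_reaction_id not in self._rxn_index:
            raise ModelError(f"biomass reaction {self.biomass_reaction_id!r} not in model")

    # -- matrices --------------------------------------------------------
    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        """Dense S over *internal* metabolites (rows) x reactions (columns).

        External (boundary) metabolites are not mass-balanced and are
        excluded from the rows.
        """
        internal = [m.id for m in self.metabolites if not m.is_external]
        met_pos = {m: i for i, m in enumerate(internal)}
        S = np.zeros((len(internal), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoich.items():
                i = met_pos.get(met)
                if i is not None:
                    S[i, j] = coef
        return S, internal, self.reaction_ids

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)


#: Medium: exchange-reaction id -> maximal uptake rate (magnitude, >= 0).
Medium = Dict[str, float]


# ---------------------------------------------------------------------------
# Tabular model dialect (TSV: id, equation, lb, ub, gpr)
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "->")
_COEF_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(side: str, rxn_id: str, sign: float, stoich: Dict[str, float]) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split(" + "):
        term = term.strip()
        m = _COEF_TERM.match(term)
        if m is None:
            raise ModelError(f"reaction {rxn_id}: cannot parse equation term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        stoich[met] = stoich.get(met, 0.0) + sign * coef


def _parse_equation(eq: str, rxn_id: str) -> Tuple[Dict[str, float], bool, bool]:
    """Return (stoich, reversible_arrow, is_exchange)."""
    for arrow in _ARROWS:
        if arrow in eq:
            left, right = eq.split(arrow, 1)
            stoich: Dict[str, float] = {}
            _parse_side(left, rxn_id, -1.0, stoich)
            _parse_side(right, rxn_id, +1.0, stoich)
            if not stoich:
                raise ModelError(f"reaction {rxn_id}: empty equation {eq!r}")
            one_sided = not left.strip() or not right.strip()
            # one-sided equations are boundary sinks/sources; only the
            # conventional EX_ prefix marks a true exchange (a biomass or
            # demand sink is one-sided too but is not part of the medium)
            is_exchange = one_sided and rxn_id.upper().startswith("EX_")
            return stoich, arrow == "<->", is_exchange
    raise ModelError(f"reaction {rxn_id}: equation {eq!r} has no '->' or '<->' arrow")


def read_tabular_model(path) -> MetabolicModel:
    """Read the TSV model dialect: columns ``id  equation  lb  ub  gpr``.

    Equations use `` + ``-separated ``coefficient metabolite`` terms, e.g.
    ``A + 2 B -> C``; a one-sided equation (``A ->``) whose id starts with
    ``EX_`` is an exchange reaction (uptake = negative flux).  The reaction
    whose id contains ``biomass`` (case-insensitive) is the objective.
    Lines starting with ``#`` are comments.
    """
    reactions: List[Reaction] = []
    genes: Set[str] = set()
    mets: Dict[str, Metabolite] = {}
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                expected = ["id", "equation", "lb", "ub", "gpr"]
                if header[: len(expected)] != expected:
                    raise ModelError(
                        f"{path}: line {lineno}: header must be {expected}, got {header}"
                    )
                continue
            if len(fields) < 4:
                raise ModelError(f"{path}: line {lineno}: expected >= 4 tab-separated fields")
            rxn_id = fields[0].strip()
            try:
                stoich, rev_arrow, is_exchange = _parse_equation(fields[1], rxn_id)
                lb, ub = float(fields[2]), float(fields[3])
            except (ModelError, ValueError) as exc:
                raise ModelError(f"{path}: line {lineno}: {exc}") from exc
            # exchanges are written one-sided ("A ->") and may take lb < 0:
            # uptake is a negative flux under the sign convention used here
            if not rev_arrow and lb < 0 and not is_exchange:
                raise ModelError(
                    f"{path}: line {lineno}: reaction {rxn_id} has lb < 0 but an "
                    "irreversible '->' arrow"
                )
            gpr_text = fields[4].strip() if len(fields) > 4 else ""
            gpr = parse_gpr(gpr_text or None)
            genes |= gpr_genes(gpr)
            for met in stoich:
                mets.setdefault(met, Metabolite(id=met))
            reactions.append(
                Reaction(id=rxn_id, stoich=stoich, lb=lb, ub=ub, gpr=gpr, is_exchange=is_exchange)
            )
    biomass = [r.id for r in reactions if "biomass" in r.id.lower()]
    if len(biomass) != 1:
        raise ModelError(
            f"{path}: need exactly one reaction whose id contains 'biomass', found {biomass}"
        )
    model = MetabolicModel(
        metabolites=list(mets.values()),
        reactions=reactions,
        genes=genes,
        biomass_reaction_id=biomass[0],
    )
    logger.info(
        "read %s: %d metabolites, %d reactions, %d genes",
        path, len(model.metabolites), len(model.reactions), len(model.genes),
    )
    return model


def write_tabular_model(model: MetabolicModel, path) -> None:
    """Write the TSV model dialect (inverse of :func:`read_tabular_model`)."""
    def term(met: str, coef: float) -> str:
        coef = abs(coef)
        return met if coef == 1 else f"{coef:g} {met}"

    with open(path, "w") as fh:
        fh.write("id\tequation\tlb\tub\tgpr\n")
        for r in model.reactions:
            left = " + ".join(term(m, c) for m, c in r.stoich.items() if c < 0)
            right = " + ".join(term(m, c) for m, c in r.stoich.items() if c > 0)
            arrow = "<->" if r.reversible and not r.is_exchange else "->"
            eq = f"{left} {arrow} {right}".strip()
            gpr_text = "" if r.gpr is None else gpr_to_string(r.gpr)
            fh.write(f"{r.id}\t{eq}\t{r.lb:g}\t{r.ub:g}\t{gpr_text}\n")


def load_medium(path) -> Medium:
    """Load a medium from a JSON map of exchange-reaction id -> uptake rate."""
    with open(path) as fh:
        medium = json.load(fh)
    return {str(k): float(v) for k, v in medium.items()}


# ---------------------------------------------------------------------------
# Model preparation
# ---------------------------------------------------------------------------

def apply_strain_background(model: MetabolicModel, genes_to_remove: Iterable[str]) -> MetabolicModel:
    """Remove strain-background genes (e.g. auxotrophy markers) from the model.

    GPRs are partially evaluated with the listed genes absent; reactions whose
    rule becomes unsatisfiable are closed (lb = ub = 0).  Genes absent from the
    model trigger a warning, not an error — deletion-collection marker genes
    are not always metabolic.
    """
    genes_to_remove = set(genes_to_remove)
    missing = genes_to_remove - model.genes
    if missing:
        logger.warning("strain-background genes not in model (ignored): %s", sorted(missing))
    present = genes_to_remove & model.genes
    new_reactions = []
    for r in model.reactions:
        gpr = remove_genes(r.gpr, present)
        if gpr is UNSATISFIABLE:
            new_reactions.append(replace(r, stoich=dict(r.stoich), lb=0.0, ub=0.0, gpr=UNSATISFIABLE))
        else:
            new_reactions.append(replace(r, stoich=dict(r.stoich), gpr=gpr))
    return MetabolicModel(
        metabolites=copy.deepcopy(model.metabolites),
        reactions=new_reactions,
        genes=model.genes - present,
        biomass_reaction_id=model.biomass_reaction_id,
    )


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Set exchange bounds from a medium of uptake magnitudes.

    Exchange reactions are oriented ``met ->``, so an uptake limit u becomes
    lb = -u.  Exchange reactions absent from the medium allow excretion only
    (lb = 0).
    """
    new_reactions = []
    exchange_ids = {r.id for r in model.reactions if r.is_exchange}
    bad = set(medium) - exchange_ids
    if bad:
        raise ModelError(f"medium names non-exchange reactions: {sorted(bad)}")
    for r in model.reactions:
        r = replace(r, stoich=dict(r.stoich))
        if r.is_exchange:
            if r.id in medium:
                uptake = float(medium[r.id])
                if uptake < 0:
                    raise ModelError(f"medium uptake for {r.id} must be non-negative")
                r.lb = -uptake
            else:
                r.lb = 0.0
        new_reactions.append(r)
    return MetabolicModel(
        metabolites=copy.deepcopy(model.metabolites),
        reactions=new_reactions,
        genes=set(model.genes),
        biomass_reaction_id=model.biomass_reaction_id,
    )


def gene_deletion_bounds(
    model: MetabolicModel, deleted: Iterable[str]
) -> Dict[str, Tuple[float, float]]:
    """Flux bounds implementing a (multi-)gene knockout.

    Every reaction whose GPR evaluates False with the deleted genes absent is
    forced to zero flux; all other reactions, including spontaneous ones, keep
    their original bounds.
    """
    deleted = set(deleted)
    unknown = deleted - model.genes
    if unknown:
        raise ModelError(f"unknown gene ids in deletion set: {sorted(unknown)}")
    bounds = {}
    for r in model.reactions:
        if r.gpr is not None and not evaluate_gpr(r.gpr, deleted):
            bounds[r.id] = (0.0, 0.0)
        else:
            bounds[r.id] = (r.lb, r.ub)
    return bounds


def screen_nonessential_unblocked_genes(
    model: MetabolicModel,
    essentiality_threshold: float = 1e-3,
    blocked_tol: float = 1e-9,
    settings=None,
) -> Set[str]:
    """The analysable gene set: genes neither essential nor blocked.

    A gene is *essential* if its single-knockout FBA fitness (knockout
    optimum / wild-type optimum) falls below ``essentiality_threshold``.
    A gene is *blocked* if none of the reactions it gates can carry flux
    beyond ``blocked_tol`` anywhere in the wild-type feasible region
    (flux variability with the objective unconstrained).
    """
    from .fba import fba, fva_bounds  # local import to avoid a cycle

    wt = fba(model, settings=settings)
    if wt.status != "optimal" or wt.objective_value <= 0:
        raise ModelError("wild-type FBA must be optimal with positive growth for screening")

    fva_cache: Dict[str, Tuple[float, float]] = {}

    def reaction_blocked(rxn_id: str) -> bool:
        if rxn_id not in fva_cache:
            fva_cache[rxn_id] = fva_bounds(model, rxn_id, settings=settings)
        lo, hi = fva_cache[rxn_id]
        return max(abs(lo), abs(hi)) <= blocked_tol

    keep = set()
    gene_rxns = model.genes_to_reactions()
    for gene in sorted(model.genes):
        ko = fba(model, bounds_override=gene_deletion_bounds(model, {gene}), settings=settings)
        fitness = 0.0 if ko.status != "optimal" else ko.objective_value / wt.objective_value
        if fitness < essentiality_threshold:
            continue
        rxns = gene_rxns.get(gene, [])
        if not rxns or all(reaction_blocked(rid) for rid in rxns):
            continue  # gene gates no flux-carrying reaction -> blocked
        keep.add(gene)
    logger.info("screen: %d of %d genes non-essential and unblocked", len(keep), len(model.genes))
    return keep
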