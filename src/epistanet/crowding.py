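"""FBA with molecular crowding: MOMENT and ccFBA.

Both methods replace the nutrient-uptake limit of classical FBA with a
budget on the total mass of metabolic enzyme per gram dry weight,

    sum_i [E_i] * m_i  <=  C ,

where [E_i] is the molar concentration of the product of gene i
(mmol gDW^-1), m_i its molar mass (g mmol^-1) and C the budget
(g gDW^-1).  Enzyme demand is tied to flux through the effective-rate
approximation [E] = v / kcat, and a reaction's available catalytic
capacity follows its GPR rule: an AND complex is limited by its scarcest
subunit (minimum over members), isoenzyme OR branches add up.

The two methods differ only in how a *multifunctional* gene — one gating
several reactions — is accounted:

* MOMENT lets a gene's full concentration serve every reaction it gates
  simultaneously (the original formulation's relaxation);
* ccFBA splits the gene's concentration across its reactions through
  per-(gene, reaction) usage variables u_ij >= 0 with sum_j u_ij <= g_i,
  so the same enzyme pool cannot be counted twice.

Consequently the ccFBA optimum never exceeds the MOMENT optimum, with
equality whenever no gene is multifunctional.  Because the optimum is
linear in C, C cancels from knockout/wild-type growth ratios, so epistasis
predictions do not depend on its numeric value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fba import FluxDistribution, LpSettings
from .gpr import And, Gene, Or, UNSATISFIABLE, gpr_genes
from .lp import OPTIMAL, SparseBuilder, solve_lp
from .model import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "EnzymeCostParams",
    "CrowdingSolution",
    "CrowdingProblem",
    "impute_kcats",
    "moment_fba",
    "ccfba",
    "crowding_wildtype_and_knockouts",
    "load_kcat_table",
    "load_mw_table",
]

#: default enzyme budget, g enzyme per gDW (yeast parameterisation)
DEFAULT_C = 0.27
#: default turnover-number imputation value, h^-1 (median of known yeast kcats)
DEFAULT_KCAT_MED = 11.5

#: large bound replacing medium uptake limits in crowding mode
_OPEN_UPTAKE = 1e6

Kcat = Union[float, Tuple[float, float]]  # single or (forward, backward)


@dataclass
class EnzymeCostParams:
    """Kinetic/cost parameters: per-reaction kcat (h^-1), per-gene molar
    mass (g mmol^-1), and the total enzyme budget C (g gDW^-1)."""

    kcat: Dict[str, Kcat]
    mw: Dict[str, float]
    C: float = DEFAULT_C
    kcat_med: float = DEFAULT_KCAT_MED

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("enzyme budget C must be positive")
        for rid, k in self.kcat.items():
            vals = k if isinstance(k, tuple) else (k,)
            if any(v <= 0 for v in vals):
                raise ValueError(f"non-positive kcat for reaction {rid}")
        for g, m in self.mw.items():
            if m <= 0:
                raise ValueError(f"non-positive molar mass for gene {g}")

    def kcat_directional(self, rxn_id: str) -> Tuple[float, float]:
        k = self.kcat[rxn_id]
        return k if isinstance(k, tuple) else (k, k)

    def with_budget(self, C: float) -> "EnzymeCostParams":
        return EnzymeCostParams(dict(self.kcat), dict(self.mw), C, self.kcat_med)

    @classmethod
    def from_tables(
        cls,
        model: MetabolicModel,
        kcat_table: Optional[Mapping[str, Kcat]] = None,
        mw_table: Optional[Mapping[str, float]] = None,
        C: float = DEFAULT_C,
        kcat_med: float = DEFAULT_KCAT_MED,
    ) -> "EnzymeCostParams":
        """Build parameters for a model, imputing missing kcats with the
        median value and, if no mass table is given, unit molar masses."""
        kcat = impute_kcats(kcat_table or {}, model, kcat_med)
        if mw_table is None:
            mw = {g: 1.0 for g in model.genes}
        else:
            mw = {g: float(mw_table[g]) for g in model.genes}
        return cls(kcat, mw, C, kcat_med)


@dataclass
class CrowdingSolution(FluxDistribution):
    """Flux distribution plus the enzyme allocation that supports it."""

    enzyme_concentrations: Dict[str, float] = field(default_factory=dict)
    budget_used: Optional[float] = None


def impute_kcats(
    raw_kcat_table: Mapping[str, Kcat],
    model: MetabolicModel,
    kcat_med: float = DEFAULT_KCAT_MED,
) -> Dict[str, Kcat]:
    """Complete a partial kcat table over the model's gated reactions.

    Every gene-gated, non-exchange reaction must carry a turnover number;
    reactions absent from the measured table get the median of the known
    values, ``kcat_med``.  Spontaneous and exchange reactions carry no
    enzyme cost and receive no entry.
    """
    if kcat_med <= 0:
        raise ValueError("kcat_med must be positive")
    for rid, k in raw_kcat_table.items():
        vals = k if isinstance(k, tuple) else (k,)
        if any(v <= 0 for v in vals):
            raise ValueError(f"non-positive kcat in table for reaction {rid}")
    out: Dict[str, Kcat] = {}
    n_known = n_imputed = 0
    for r in model.reactions:
        if r.gpr is None or r.gpr is UNSATISFIABLE or r.is_exchange:
            continue
        if r.id in raw_kcat_table:
            out[r.id] = raw_kcat_table[r.id]
            n_known += 1
        else:
            out[r.id] = kcat_med
            n_imputed += 1
    logger.info("kcat coverage: %d measured, %d imputed at %.3g", n_known, n_imputed, kcat_med)
    return out


def load_kcat_table(path) -> Dict[str, Kcat]:
    """TSV with columns ``reaction_id  kcat`` and optionally ``kcat_backward``."""
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, Kcat] = {}
    for _, row in df.iterrows():
        rid = str(row["reaction_id"])
        if "kcat_backward" in df.columns and not pd.isna(row["kcat_backward"]):
            out[rid] = (float(row["kcat"]), float(row["kcat_backward"]))
        else:
            out[rid] = float(row["kcat"])
    logger.info("loaded %d kcat entries from %s", len(out), path)
    return out


def load_mw_table(path) -> Dict[str, float]:
    """TSV with columns ``gene_id  mw`` (g mmol^-1)."""
    df = pd.read_csv(path, sep="\t")
    out = {str(r["gene_id"]): float(r["mw"]) for _, r in df.iterrows()}
    logger.info("loaded %d molar masses from %s", len(out), path)
    return out


class CrowdingProblem:
    """One crowding LP instance, reusable across knockouts.

    The constraint matrix is assembled once; knockouts only toggle the
    bounds of the deleted genes' concentration variables to zero, which
    closes every reaction their loss disables (capacities collapse through
    the GPR recursion).
    """

    def __init__(
        self,
        model: MetabolicModel,
        params: EnzymeCostParams,
        method: str = "moment",
        settings: Optional[LpSettings] = None,
        open_uptakes: bool = True,
    ):
        method = method.lower()
        if method not in ("moment", "ccfba"):
            raise ValueError(f"unknown crowding method {method!r}")
        self.model = model
        self.params = params
        self.method = method
        self.settings = settings or LpSettings()
        self.open_uptakes = open_uptakes
        self._build()

    # -- variable registry ----------------------------------------------
    def _new_var(self, lo: float, hi: Optional[float]) -> int:
        self._bounds.append((lo, hi))
        return len(self._bounds) - 1

    def _build(self) -> None:
        model, params = self.model, self.params
        S, _, rxn_ids = model.stoichiometric_matrix()
        self.rxn_ids = rxn_ids
        n_rxn = len(rxn_ids)

        self._bounds: List[Tuple[float, Optional[float]]] = []
        # flux variables, with medium uptakes opened (the crowding budget
        # replaces the nutrient-uptake constraint; closed uptakes stay closed)
        self.v_idx: Dict[str, int] = {}
        for r in model.reactions:
            lb, ub = r.lb, r.ub
            if self.open_uptakes and r.is_exchange and lb < 0:
                lb = -_OPEN_UPTAKE
            self.v_idx[r.id] = self._new_var(lb, ub)

        # gene concentration variables [E_i] >= 0
        self.gene_list = sorted(model.genes)
        self.g_idx: Dict[str, int] = {g: self._new_var(0.0, None) for g in self.gene_list}

        eq_rows: List[Tuple[List[Tuple[int, float]], float]] = []
        ub_rows: List[Tuple[List[Tuple[int, float]], float]] = []

        # mass balance S v = 0
        S_sp = sp.coo_matrix(S)
        mass_rows: Dict[int, List[Tuple[int, float]]] = {}
        for i, j, v in zip(S_sp.row, S_sp.col, S_sp.data):
            mass_rows.setdefault(int(i), []).append((self.v_idx[rxn_ids[int(j)]], float(v)))
        for i in range(S.shape[0]):
            eq_rows.append((mass_rows.get(i, []), 0.0))

        # ccFBA usage variables u_(gene, reaction)
        self.u_idx: Dict[Tuple[str, str], int] = {}

        def leaf_var(gene: str, rxn_id: str) -> int:
            if self.method == "moment":
                return self.g_idx[gene]
            key = (gene, rxn_id)
            if key not in self.u_idx:
                self.u_idx[key] = self._new_var(0.0, None)
            return self.u_idx[key]

        def emit(node, rxn_id: str) -> int:
            """Return the variable holding the node's usable concentration."""
            if isinstance(node, Gene):
                return leaf_var(node.name, rxn_id)
            a = self._new_var(0.0, None)
            if isinstance(node, And):
                # complex limited by its scarcest subunit: a <= child for all
                for child in node.children:
                    ub_rows.append(([(a, 1.0), (emit(child, rxn_id), -1.0)], 0.0))
            elif isinstance(node, Or):
                # isoenzymes add: a <= sum of children
                entries = [(a, 1.0)]
                entries += [(emit(child, rxn_id), -1.0) for child in node.children]
                ub_rows.append((entries, 0.0))
            else:
                raise TypeError(f"not a GPR node: {node!r}")
            return a

        # kinetic ceilings per gated reaction
        for r in model.reactions:
            if r.gpr is None or r.is_exchange:
                continue
            if r.gpr is UNSATISFIABLE:
                continue  # bounds are already zero
            if r.id not in params.kcat:
                raise KeyError(
                    f"reaction {r.id} is gene-gated but has no kcat; run impute_kcats first"
                )
            kf, kb = params.kcat_directional(r.id)
            root = emit(r.gpr, r.id)
            vj = self.v_idx[r.id]
            if r.lb < 0:
                # reversible: split directions sharing one enzyme pool
                vf = self._new_var(0.0, None)
                vb = self._new_var(0.0, None)
                eq_rows.append(([(vj, 1.0), (vf, -1.0), (vb, 1.0)], 0.0))
                ub_rows.append(([(vf, 1.0 / kf), (vb, 1.0 / kb), (root, -1.0)], 0.0))
            else:
                ub_rows.append(([(vj, 1.0 / kf), (root, -1.0)], 0.0))

        # ccFBA: a gene's usages across reactions share its concentration
        if self.method == "ccfba":
            per_gene: Dict[str, List[int]] = {}
            for (g, _rid), idx in self.u_idx.items():
                per_gene.setdefault(g, []).append(idx)
            for g, idxs in per_gene.items():
                ub_rows.append(([(i, 1.0) for i in idxs] + [(self.g_idx[g], -1.0)], 0.0))

        # enzyme mass budget
        ub_rows.append(
            ([(self.g_idx[g], params.mw[g]) for g in self.gene_list], params.C)
        )

        n = len(self._bounds)
        eq = SparseBuilder(n)
        for entries, rhs in eq_rows:
            eq.add_row(entries, rhs)
        ub = SparseBuilder(n)
        for entries, rhs in ub_rows:
            ub.add_row(entries, rhs)
        self.A_eq, self.b_eq = eq.matrix()
        self.A_ub, self.b_ub = ub.matrix()
        self.c = np.zeros(n)
        self.c[self.v_idx[model.biomass_reaction_id]] = 1.0

    def solve(self, deleted_genes: Iterable[str] = ()) -> CrowdingSolution:
        deleted = set(deleted_genes)
        unknown = deleted - self.model.genes
        if unknown:
            raise ValueError(f"unknown gene ids in deletion set: {sorted(unknown)}")
        bounds = list(self._bounds)
        for g in deleted:
            bounds[self.g_idx[g]] = (0.0, 0.0)
        res = solve_lp(
            self.c,
            A_eq=self.A_eq,
            b_eq=self.b_eq,
            A_ub=self.A_ub,
            b_ub=self.b_ub,
            bounds=bounds,
            maximize=True,
            feasibility_tol=self.settings.feasibility_tol,
        )
        if res.status != OPTIMAL:
            return CrowdingSolution({}, None, res.status)
        fluxes = {rid: float(res.x[self.v_idx[rid]]) for rid in self.rxn_ids}
        conc = {g: float(res.x[self.g_idx[g]]) for g in self.gene_list}
        budget = float(sum(self.params.mw[g] * conc[g] for g in self.gene_list))
        return CrowdingSolution(
            fluxes,
            float(res.objective),
            OPTIMAL,
            enzyme_concentrations=conc,
            budget_used=budget,
        )


def moment_fba(
    model: MetabolicModel,
    params: EnzymeCostParams,
    deleted_genes: Iterable[str] = (),
    settings: Optional[LpSettings] = None,
    open_uptakes: bool = True,
) -> CrowdingSolution:
    """Growth maximisation under the enzyme budget, MOMENT semantics
    (a multifunctional gene serves all its reactions simultaneously)."""
    return CrowdingProblem(model, params, "moment", settings, open_uptakes).solve(deleted_genes)


def ccfba(
    model: MetabolicModel,
    params: EnzymeCostParams,
    deleted_genes: Iterable[str] = (),
    settings: Optional[LpSettings] = None,
    open_uptakes: bool = True,
) -> CrowdingSolution:
    """Growth maximisation under the enzyme budget, ccFBA semantics
    (a multifunctional gene's concentration is split across its reactions)."""
    return CrowdingProblem(model, params, "ccfba", settings, open_uptakes).solve(deleted_genes)


def crowding_wildtype_and_knockouts(
    model: MetabolicModel,
    params: EnzymeCostParams,
    pairs: Sequence[Tuple[str, str]],
    method: str = "ccfba",
    settings: Optional[LpSettings] = None,
) -> Dict[FrozenSet[str], CrowdingSolution]:
    """Batch-solve wild type, all involved single knockouts and the given
    double knockouts on one reusable problem instance.

    Keys of the returned map: ``frozenset()`` (wild type), ``frozenset({g})``
    and ``frozenset({g1, g2})``.  Per-genotype infeasibility is recorded in
    the solution status, never raised.
    """
    prob = CrowdingProblem(model, params, method, settings)
    out: Dict[FrozenSet[str], CrowdingSolution] = {frozenset(): prob.solve()}
    singles = sorted({g for pair in pairs for g in pair})
    for g in singles:
        out[frozenset({g})] = prob.solve({g})
    for a, b in pairs:
        key = frozenset({a, b})
        if key not in out:
            out[key] = prob.solve(key)
    return out
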