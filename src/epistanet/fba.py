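"""Flux balance analysis (FBA), parsimonious FBA and flux variability.

FBA solves  max v_biomass  s.t.  S v = 0,  lb <= v <= ub:  the maximal
biomass yield compatible with mass balance and the flux bounds.  pFBA
fixes that optimum and then minimises total absolute flux, selecting the
least-redundant of the (generally degenerate) yield-optimal flux
distributions; it is the wild-type reference used by linear MOMA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .lp import INFEASIBLE, OPTIMAL, UNBOUNDED, LpResult, solve_lp
from .model import MetabolicModel

__all__ = ["LpSettings", "FluxDistribution", "FbaProblem", "fba", "pfba", "fva_bounds"]


@dataclass
class LpSettings:
    feasibility_tol: float = 1e-9
    optimality_tol: float = 1e-9
    #: relative slack when fixing the FBA optimum in pFBA stage 2
    pfba_objective_slack: float = 1e-9

    def __post_init__(self) -> None:
        if min(self.feasibility_tol, self.optimality_tol, self.pfba_objective_slack) <= 0:
            raise ValueError("all tolerances must be positive")


@dataclass
class FluxDistribution:
    """A solved flux vector.

    If ``status`` is not ``"optimal"``, ``fluxes`` is empty and
    ``objective_value`` is None.  ``distance`` (lMOMA) and ``total_flux``
    (pFBA) carry the auxiliary objective actually minimised.
    """

    fluxes: Dict[str, float]
    objective_value: Optional[float]
    status: str
    distance: Optional[float] = None
    total_flux: Optional[float] = None

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


class FbaProblem:
    """Reusable FBA problem: S and bounds built once, overrides per solve."""

    def __init__(self, model: MetabolicModel, settings: Optional[LpSettings] = None):
        self.model = model
        self.settings = settings or LpSettings()
        S, _, rxn_ids = model.stoichiometric_matrix()
        self.S = sp.csr_matrix(S)
        self.rxn_ids = rxn_ids
        self.rxn_pos = {rid: j for j, rid in enumerate(rxn_ids)}
        self.base_bounds = [(r.lb, r.ub) for r in model.reactions]
        self.obj_index = self.rxn_pos[model.biomass_reaction_id]

    def bounds_with(self, override: Optional[Mapping[str, Tuple[float, float]]]):
        if not override:
            return list(self.base_bounds)
        bounds = list(self.base_bounds)
        for rid, lu in override.items():
            bounds[self.rxn_pos[rid]] = tuple(lu)
        return bounds

    def _to_distribution(self, res: LpResult) -> FluxDistribution:
        if res.status != OPTIMAL:
            return FluxDistribution({}, None, res.status)
        fluxes = {rid: float(res.x[j]) for j, rid in enumerate(self.rxn_ids)}
        return FluxDistribution(fluxes, float(res.x[self.obj_index]), OPTIMAL)

    def solve(
        self,
        bounds_override: Optional[Mapping[str, Tuple[float, float]]] = None,
        objective_reaction: Optional[str] = None,
        maximize: bool = True,
    ) -> FluxDistribution:
        n = len(self.rxn_ids)
        c = np.zeros(n)
        c[self.rxn_pos[objective_reaction] if objective_reaction else self.obj_index] = 1.0
        res = solve_lp(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=self.bounds_with(bounds_override),
            maximize=maximize,
            feasibility_tol=self.settings.feasibility_tol,
        )
        return self._to_distribution(res)


def fba(
    model: MetabolicModel,
    bounds_override: Optional[Mapping[str, Tuple[float, float]]] = None,
    settings: Optional[LpSettings] = None,
) -> FluxDistribution:
    """Maximise biomass flux; infeasible/unbounded map to the status field."""
    return FbaProblem(model, settings).solve(bounds_override)


def pfba(
    model: MetabolicModel,
    bounds_override: Optional[Mapping[str, Tuple[float, float]]] = None,
    settings: Optional[LpSettings] = None,
) -> FluxDistribution:
    """Parsimonious FBA: minimal total |flux| at (essentially) the FBA optimum.

    Stage 1 is plain FBA; stage 2 fixes the biomass flux into
    ``[z*(1 - slack), z*]`` and minimises sum_i |v_i| via epigraph variables
    t_i >= |v_i|.  The reported ``objective_value`` is the biomass flux, not
    the flux sum (which is stored in ``total_flux``).
    """
    settings = settings or LpSettings()
    prob = FbaProblem(model, settings)
    stage1 = prob.solve(bounds_override)
    if stage1.status != OPTIMAL:
        return stage1
    z = stage1.objective_value

    n = len(prob.rxn_ids)
    bounds = prob.bounds_with(bounds_override)
    slack = settings.pfba_objective_slack * max(abs(z), 1.0)
    bounds[prob.obj_index] = (z - slack, z)
    # variables: [v (n), t (n)], t_i >= |v_i|
    bounds += [(0.0, None)] * n
    A_eq = sp.hstack([prob.S, sp.csr_matrix((prob.S.shape[0], n))]).tocsr()
    eye = sp.identity(n, format="csr")
    A_ub = sp.vstack([sp.hstack([eye, -eye]), sp.hstack([-eye, -eye])]).tocsr()
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = solve_lp(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(prob.S.shape[0]),
        A_ub=A_ub,
        b_ub=np.zeros(2 * n),
        bounds=bounds,
        maximize=False,
        feasibility_tol=settings.feasibility_tol,
    )
    if res.status != OPTIMAL:
        return FluxDistribution({}, None, res.status)
    fluxes = {rid: float(res.x[j]) for j, rid in enumerate(prob.rxn_ids)}
    return FluxDistribution(
        fluxes,
        float(res.x[prob.obj_index]),
        OPTIMAL,
        total_flux=float(res.objective),
    )


def fva_bounds(
    model: MetabolicModel,
    reaction_id: str,
    settings: Optional[LpSettings] = None,
) -> Tuple[float, float]:
    """Min and max of one reaction's flux over the feasible region.

    The biomass objective is left unconstrained — this is the variant used
    for blocked-reaction screening, not production FVA at fixed growth.
    """
    prob = FbaProblem(model, settings)
    lo = prob.solve(objective_reaction=reaction_id, maximize=False)
    hi = prob.solve(objective_reaction=reaction_id, maximize=True)
    if lo.status != OPTIMAL or hi.status != OPTIMAL:
        raise RuntimeError(
            f"FVA for {reaction_id} failed: min {lo.status}, max {hi.status}"
        )
    return lo.fluxes[reaction_id], hi.fluxes[reaction_id]
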