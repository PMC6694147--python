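"""Linear minimisation of metabolic adjustment (lMOMA).

A knockout's flux distribution is predicted as the point of the knockout
feasible space closest — in Manhattan (L1) distance — to a wild-type
reference flux vector.  Because FBA optima are highly degenerate, the
reference should be the parsimonious-FBA wild-type solution, which is
unique in total flux and biologically the least redundant choice.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import scipy.sparse as sp

from .fba import FbaProblem, FluxDistribution, LpSettings
from .lp import OPTIMAL, solve_lp
from .model import MetabolicModel, gene_deletion_bounds

__all__ = ["lmoma_knockout", "manhattan_distance"]


def manhattan_distance(a: FluxDistribution, b: FluxDistribution) -> float:
    """Sum_i |a_i - b_i| over a common reaction set."""
    if set(a.fluxes) != set(b.fluxes):
        raise ValueError("flux distributions cover different reaction sets")
    return float(sum(abs(a.fluxes[r] - b.fluxes[r]) for r in a.fluxes))


def lmoma_knockout(
    model: MetabolicModel,
    reference: FluxDistribution,
    deleted_genes: Iterable[str],
    settings: Optional[LpSettings] = None,
) -> FluxDistribution:
    """Predict knockout fluxes by minimising L1 distance to ``reference``.

    Solves  min sum_i |v_i - v_i_ref|  s.t.  S v = 0 and the knockout
    bounds from :func:`gene_deletion_bounds`.  ``objective_value`` is the
    biomass flux of the solution; the minimised distance is reported in
    ``distance``.  An infeasible knockout space yields status
    ``"infeasible"`` (downstream: fitness 0).
    """
    if reference.status != OPTIMAL:
        raise ValueError("reference flux distribution must be optimal")
    settings = settings or LpSettings()
    prob = FbaProblem(model, settings)
    ref = np.array([reference.fluxes[rid] for rid in prob.rxn_ids])

    ko_bounds = gene_deletion_bounds(model, set(deleted_genes))
    bounds = prob.bounds_with(ko_bounds)

    n = len(prob.rxn_ids)
    # variables: [v (n), t (n)] with t_i >= |v_i - ref_i|
    bounds += [(0.0, None)] * n
    A_eq = sp.hstack([prob.S, sp.csr_matrix((prob.S.shape[0], n))]).tocsr()
    eye = sp.identity(n, format="csr")
    A_ub = sp.vstack([sp.hstack([eye, -eye]), sp.hstack([-eye, -eye])]).tocsr()
    b_ub = np.concatenate([ref, -ref])
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = solve_lp(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(prob.S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
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
        distance=float(res.objective),
    )
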