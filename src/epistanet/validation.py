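"""Brute-force reference solvers for validating the LP-based methods.

The flux polytope {v : S v = 0, lb <= v <= ub} is bounded for the toy
networks used in testing, so its vertices can be enumerated exhaustively:
a vertex activates dim-many linearly independent constraints, of which
rank(S) are the mass balances, leaving n - rank(S) active flux bounds to
choose.  Because an LP optimum is attained at a vertex, maximising the
objective over the enumerated vertex set is an independent check of any
LP solver result.  Exponential in n - rank(S); intended for problems with
at most ~8 degrees of freedom.
"""

from __future__ import annotations

import itertools
from typing import List, Mapping, Optional, Tuple

import numpy as np

from .model import MetabolicModel

__all__ = ["enumerate_polytope_vertices", "fba_by_vertex_enumeration"]


def _independent_rows(A: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """A maximal linearly independent row subset (QR with column pivoting)."""
    if A.size == 0:
        return A
    from scipy.linalg import qr

    _, R, piv = qr(A.T, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * max(diag[0], 1.0))) if diag.size else 0
    return A[piv[:rank]]


def enumerate_polytope_vertices(
    A_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    tol: float = 1e-9,
) -> List[np.ndarray]:
    """All vertices of {x : A_eq x = 0, lb <= x <= ub} (finite bounds only)."""
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = lb.size
    A = _independent_rows(np.asarray(A_eq, dtype=float).reshape(-1, n))
    r = A.shape[0]
    free = n - r
    if free < 0:
        raise ValueError("more independent equalities than variables")
    vertices: List[np.ndarray] = []
    scale = max(1.0, np.abs(ub[np.isfinite(ub)]).max(initial=1.0))
    for combo in itertools.combinations(range(n), free):
        for choice in itertools.product((0, 1), repeat=free):
            vals = [lb[j] if c == 0 else ub[j] for j, c in zip(combo, choice)]
            if any(not np.isfinite(v) for v in vals):
                continue
            M = np.vstack([A] + [np.eye(n)[j] for j in combo]) if free else A
            b = np.concatenate([np.zeros(r), np.asarray(vals)])
            if M.shape[0] != n:
                continue
            try:
                x = np.linalg.solve(M, b)
            except np.linalg.LinAlgError:
                continue
            if np.max(np.abs(A @ x)) > tol * scale:
                continue
            if np.any(x < lb - tol * scale) or np.any(x > ub + tol * scale):
                continue
            vertices.append(x)
    return vertices


def fba_by_vertex_enumeration(
    model: MetabolicModel,
    bounds_override: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> Optional[float]:
    """Maximal biomass flux found by exhaustive vertex enumeration.

    Returns None if the polytope has no vertex (infeasible).  Independent
    of the LP path: builds its own matrices and never calls a solver.
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb = np.array([r.lb for r in model.reactions], dtype=float)
    ub = np.array([r.ub for r in model.reactions], dtype=float)
    if bounds_override:
        pos = {rid: j for j, rid in enumerate(rxn_ids)}
        for rid, (lo, hi) in bounds_override.items():
            lb[pos[rid]], ub[pos[rid]] = lo, hi
    vertices = enumerate_polytope_vertices(S, lb, ub)
    if not vertices:
        return None
    j = rxn_ids.index(model.biomass_reaction_id)
    return max(v[j] for v in vertices)
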