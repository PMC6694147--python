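"""Thin wrapper around scipy's HiGHS linear-programming interface.

All optimisation problems in this package (FBA, pFBA, lMOMA, MOMENT,
ccFBA) are LPs; they are assembled as sparse matrices and handed to
``scipy.optimize.linprog(method="highs")``.  Solver failure modes are
mapped to the three statuses the rest of the package understands:
``optimal``, ``infeasible``, ``unbounded``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    """Raised when the LP solver fails for a reason other than infeasibility/unboundedness."""


@dataclass
class LpResult:
    status: str
    x: Optional[np.ndarray]
    objective: Optional[float]
    message: str = ""


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[sp.spmatrix] = None,
    b_eq: Optional[np.ndarray] = None,
    A_ub: Optional[sp.spmatrix] = None,
    b_ub: Optional[np.ndarray] = None,
    bounds: Optional[List[Tuple[float, float]]] = None,
    maximize: bool = False,
    feasibility_tol: float = 1e-9,
) -> LpResult:
    """Solve min (or max) c'x s.t. A_eq x = b_eq, A_ub x <= b_ub, bounds."""
    c = np.asarray(c, dtype=float)
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": feasibility_tol,
            "dual_feasibility_tolerance": feasibility_tol,
        },
    )
    if res.status == 0:
        return LpResult(OPTIMAL, np.asarray(res.x), float(c @ res.x), res.message)
    if res.status == 2:
        return LpResult(INFEASIBLE, None, None, res.message)
    if res.status == 3:
        return LpResult(UNBOUNDED, None, None, res.message)
    raise SolverError(f"LP solver failed (status {res.status}): {res.message}")


class SparseBuilder:
    """Incremental COO assembly of a sparse constraint block."""

    def __init__(self, n_cols: int):
        self.n_cols = n_cols
        self.rows: List[int] = []
        self.cols: List[int] = []
        self.vals: List[float] = []
        self.rhs: List[float] = []

    def add_row(self, entries: List[Tuple[int, float]], rhs: float) -> int:
        i = len(self.rhs)
        for j, v in entries:
            self.rows.append(i)
            self.cols.append(j)
            self.vals.append(v)
        self.rhs.append(rhs)
        return i

    @property
    def n_rows(self) -> int:
        return len(self.rhs)

    def matrix(self) -> Tuple[Optional[sp.csr_matrix], Optional[np.ndarray]]:
        if not self.rhs:
            return None, None
        A = sp.coo_matrix(
            (self.vals, (self.rows, self.cols)), shape=(self.n_rows, self.n_cols)
        ).tocsr()
        return A, np.asarray(self.rhs, dtype=float)
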