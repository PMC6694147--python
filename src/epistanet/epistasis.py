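"""All-pairs knockout simulation and epistasis scoring.

For a pair of genes the epistasis score is

    eps = W12 - W1 * W2 ,

the deviation of the double-mutant fitness from the product of the
single-mutant fitnesses.  Fitness is the genotype's biomass flux divided
by the wild-type biomass flux of the *same* method: the FBA optimum for
FBA, the pFBA wild-type biomass for lMOMA, and the crowding-limited
maximal growth rate for MOMENT/ccFBA.  Negative eps marks aggravating
(synthetic-sick/lethal) interactions, positive eps alleviating ones.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .crowding import CrowdingProblem, EnzymeCostParams
from .fba import FbaProblem, FluxDistribution, LpSettings, pfba
from .lmoma import lmoma_knockout
from .lp import OPTIMAL
from .model import MetabolicModel, gene_deletion_bounds

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "EpistasisRecord",
    "SyntheticLethalCall",
    "fitness",
    "epistasis",
    "classify_interaction",
    "call_synthetic_lethal",
    "run_all_pairs",
    "records_to_dataframe",
    "write_records",
    "read_records",
]

METHODS = ("FBA", "lMOMA", "MOMENT", "ccFBA")

#: inclusive classification cutoff on |eps|
DEFAULT_EPS_CUTOFF = 1e-4
#: |eps| below this is solver jitter and snaps to zero before classification
DEFAULT_NOISE_FLOOR = 1e-9
#: synthetic-lethality thresholds (strict inequalities)
SL_EPS_CUTOFF = -0.08
SL_FITNESS_CUTOFF = 0.2


@dataclass
class EpistasisRecord:
    gene_a: str
    gene_b: str
    method: str
    W1: float
    W2: float
    W12: float
    epsilon: float
    interaction_class: str  # "negative" | "positive" | "none"

    @property
    def f(self) -> float:
        """Double-mutant fitness (alias of W12)."""
        return self.W12

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class SyntheticLethalCall:
    gene_a: str
    gene_b: str
    epsilon: float
    f: float
    is_SL: bool


def fitness(v_genotype: Optional[float], v_wildtype: float, status: str = OPTIMAL) -> float:
    """Relative fitness W = v / v_WT; an unsolvable genotype has fitness 0."""
    if v_wildtype is None or v_wildtype <= 0:
        raise ValueError("wild type must grow (v_wildtype > 0)")
    if status != OPTIMAL or v_genotype is None:
        return 0.0
    return v_genotype / v_wildtype


def epistasis(W1: float, W2: float, W12: float) -> float:
    """eps = W12 - W1 * W2."""
    return W12 - W1 * W2


def classify_interaction(eps: float, cutoff: float = DEFAULT_EPS_CUTOFF) -> str:
    """Classify an epistasis score; the boundaries +-cutoff are inclusive."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if eps <= -cutoff:
        return "negative"
    if eps >= cutoff:
        return "positive"
    return "none"


def call_synthetic_lethal(
    eps: float,
    f: float,
    eps_cutoff: float = SL_EPS_CUTOFF,
    f_cutoff: float = SL_FITNESS_CUTOFF,
) -> bool:
    """Synthetic lethality: strongly negative epistasis *and* a nearly dead
    double mutant.  Both inequalities are strict."""
    return eps < eps_cutoff and f < f_cutoff


def _fitness_of(sol: FluxDistribution, wt_value: float) -> float:
    return fitness(sol.objective_value, wt_value, sol.status)


def run_all_pairs(
    model: MetabolicModel,
    method: str,
    gene_set: Sequence[str],
    params: Optional[EnzymeCostParams] = None,
    settings: Optional[LpSettings] = None,
    eps_cutoff: float = DEFAULT_EPS_CUTOFF,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
) -> List[EpistasisRecord]:
    """Epistasis for every unordered pair of ``gene_set`` under one method.

    Single-knockout solutions are computed once and reused for all pairs;
    output records are in lexicographic pair order.  Per-genotype solver
    infeasibility becomes fitness 0 (lethal), never an exception.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    genes = list(gene_set)
    if len(genes) != len(set(genes)):
        raise ValueError("gene_set contains duplicates")
    unknown = set(genes) - model.genes
    if unknown:
        raise ValueError(f"gene_set not in model: {sorted(unknown)}")
    genes = sorted(genes)

    settings = settings or LpSettings()
    if method == "FBA":
        prob = FbaProblem(model, settings)
        wt = prob.solve()

        def solve(deleted: FrozenSet[str]) -> FluxDistribution:
            return prob.solve(gene_deletion_bounds(model, deleted))

    elif method == "lMOMA":
        reference = pfba(model, settings=settings)
        wt = reference

        def solve(deleted: FrozenSet[str]) -> FluxDistribution:
            return lmoma_knockout(model, reference, deleted, settings=settings)

    else:  # MOMENT / ccFBA
        if params is None:
            raise ValueError(f"{method} requires EnzymeCostParams")
        cprob = CrowdingProblem(model, params, method.lower(), settings)
        wt = cprob.solve()

        def solve(deleted: FrozenSet[str]) -> FluxDistribution:
            return cprob.solve(deleted)

    if wt.status != OPTIMAL or not wt.objective_value or wt.objective_value <= 0:
        raise RuntimeError(f"wild-type problem not solvable with positive growth ({method})")
    wt_value = wt.objective_value

    single_W = {g: _fitness_of(solve(frozenset({g})), wt_value) for g in genes}
    for g, W in single_W.items():
        if W > 1 + 1e-6:
            logger.warning("single-knockout fitness above 1 for %s: %.6g", g, W)

    records = []
    for a, b in itertools.combinations(genes, 2):
        W1, W2 = single_W[a], single_W[b]
        W12 = _fitness_of(solve(frozenset({a, b})), wt_value)
        eps = epistasis(W1, W2, W12)
        if abs(eps) < noise_floor:
            eps = 0.0
        records.append(
            EpistasisRecord(a, b, method, W1, W2, W12, eps, classify_interaction(eps, eps_cutoff))
        )
    return records


def records_to_dataframe(records: Iterable[EpistasisRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "method": r.method,
                "W1": r.W1,
                "W2": r.W2,
                "W12": r.W12,
                "epsilon": r.epsilon,
                "class": r.interaction_class,
            }
            for r in records
        ]
    )


def write_records(records: Iterable[EpistasisRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_records(path) -> List[EpistasisRecord]:
    df = pd.read_csv(path)
    return [
        EpistasisRecord(
            str(r["gene_a"]), str(r["gene_b"]), str(r["method"]),
            float(r["W1"]), float(r["W2"]), float(r["W12"]),
            float(r["epsilon"]), str(r["class"]),
        )
        for _, r in df.iterrows()
    ]
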