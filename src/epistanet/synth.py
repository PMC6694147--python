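"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* the two illustrative epistasis motifs — parallel isoenzymes (negative
  epistasis under crowding, none under FBA) and converging pathways
  (positive epistasis under crowding);
* random viable toy networks with GPR rules and kinetic parameters,
  small enough for brute-force oracles;
* noisy experimental-style interaction-call tables derived from a known
  truth (Bernoulli dropout of true interactions plus Gaussian score
  jitter), emulating the statistical shape of a high-confidence SGA set:
  mostly-zero scores with sparse signed interactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .crowding import DEFAULT_C, EnzymeCostParams
from .epistasis import DEFAULT_EPS_CUTOFF, EpistasisRecord, classify_interaction
from .evaluation import ExperimentalCall, pair_key
from .gpr import And, Gene, Or
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

__all__ = [
    "build_parallel_isoenzyme_motif",
    "build_converging_pathway_motif",
    "random_toy_model",
    "generate_observed_calls",
    "truth_from_records",
]


def build_parallel_isoenzyme_motif(
    kcats: Sequence[float] = (10.0, 10.0, 1.0),
    mws: Optional[Sequence[float]] = None,
    uptake: float = 10.0,
    C: float = 1.0,
) -> Tuple[MetabolicModel, EnzymeCostParams]:
    """Isoenzyme motif:  A(ext) -> A -> B by one of several isoenzymes -> biomass.

    Every route has the same stoichiometric yield, so FBA sees no fitness
    effect of any knockout combination (eps = 0 throughout).  Under a
    crowding budget the routes differ in protein cost per flux; knocking
    out both *fast* isoenzymes forces flux through the slow backup and
    produces negative epistasis.  Uptake and biomass steps are gene-free
    and cost-free.  Gene for isoenzyme i is ``g{i+1}``.
    """
    if len(kcats) < 2:
        raise ValueError("parallel motif needs at least 2 isoenzyme routes")
    mws = list(mws) if mws is not None else [1.0] * len(kcats)
    if len(mws) != len(kcats):
        raise ValueError("kcats and mws must have equal length")
    mets = [Metabolite("A"), Metabolite("B")]
    reactions = [
        Reaction("EX_A", {"A": -1.0}, lb=-uptake, ub=DEFAULT_BOUND, is_exchange=True)
    ]
    kcat: Dict[str, float] = {}
    mw: Dict[str, float] = {}
    genes = set()
    for i, (k, m) in enumerate(zip(kcats, mws), start=1):
        gene = f"g{i}"
        rid = f"ISO{i}"
        reactions.append(Reaction(rid, {"A": -1.0, "B": 1.0}, lb=0.0, gpr=Gene(gene)))
        kcat[rid] = float(k)
        mw[gene] = float(m)
        genes.add(gene)
    reactions.append(Reaction("BIOMASS", {"B": -1.0}, lb=0.0))
    model = MetabolicModel(mets, reactions, genes, "BIOMASS")
    return model, EnzymeCostParams(kcat, mw, C=C)


def build_converging_pathway_motif(
    kcat_fast: Tuple[float, float] = (10.0, 10.0),
    backup_capacity: Tuple[float, float] = (1.0, 1.0),
    mws: Tuple[float, float] = (1.0, 1.0),
    uptake: float = 10.0,
    C: float = 1.0,
) -> Tuple[MetabolicModel, EnzymeCostParams]:
    """Converging-pathway motif: two precursors, each with a fast enzymatic
    route and a low-capacity backup, joined by a downstream biomass step.

        AX -> X  (fast, gene gxf, kcat)    AX -> X  (backup, capacity-limited)
        AY -> Y  (fast, gene gyf, kcat)    AY -> Y  (backup, capacity-limited)
        X + Y -> biomass                    (gene-free, cost-free)

    The backups are modelled as spontaneous reactions with a small flux
    capacity (enzyme-cost-exempt), the limiting-capacity idealisation of a
    catalytically inefficient bypass.  With this construction the double
    knockout of the two fast genes runs both branches on their backups at
    zero enzyme cost, so W12 = min(W1, W2) holds exactly and the crowding
    methods predict positive epistasis eps = min(W1, W2) - W1*W2.
    """
    if len(kcat_fast) != 2 or len(backup_capacity) != 2:
        raise ValueError("converging motif has exactly 2 input branches")
    if any(b < 0 for b in backup_capacity):
        raise ValueError("backup capacities must be non-negative")
    mets = [Metabolite(m) for m in ("AX", "AY", "X", "Y")]
    bx, by = (float(b) for b in backup_capacity)
    reactions = [
        Reaction("EX_AX", {"AX": -1.0}, lb=-uptake, is_exchange=True),
        Reaction("EX_AY", {"AY": -1.0}, lb=-uptake, is_exchange=True),
        Reaction("FASTX", {"AX": -1.0, "X": 1.0}, gpr=Gene("gxf")),
        Reaction("SLOWX", {"AX": -1.0, "X": 1.0}, ub=bx),
        Reaction("FASTY", {"AY": -1.0, "Y": 1.0}, gpr=Gene("gyf")),
        Reaction("SLOWY", {"AY": -1.0, "Y": 1.0}, ub=by),
        Reaction("BIOMASS", {"X": -1.0, "Y": -1.0}),
    ]
    model = MetabolicModel(mets, reactions, {"gxf", "gyf"}, "BIOMASS")
    params = EnzymeCostParams(
        {"FASTX": float(kcat_fast[0]), "FASTY": float(kcat_fast[1])},
        {"gxf": float(mws[0]), "gyf": float(mws[1])},
        C=C,
    )
    return model, params


def random_toy_model(
    n_branch_points: int = 4,
    n_isoforms_max: int = 3,
    seed: int = 0,
    p_complex: float = 0.25,
    p_reuse: float = 0.3,
    p_dead_end: float = 0.15,
    uptake: float = 10.0,
    C: float = DEFAULT_C,
) -> Tuple[MetabolicModel, EnzymeCostParams]:
    """A random viable toy network for property and oracle tests.

    A linear backbone  S -> M1 -> ... -> Mn -> biomass guarantees a
    biomass route at every step; each step carries 1..n_isoforms_max
    parallel gated reactions (isoenzymes), occasionally a two-gene AND
    complex, and genes are re-used across steps with probability
    ``p_reuse`` (creating the multifunctional enzymes that separate ccFBA
    from MOMENT).  Some steps sprout a gated dead-end reaction that can
    never carry flux (a blocked reaction for screening tests).  kcats are
    log-uniform in [1, 100] h^-1, molar masses uniform in [0.5, 2].
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    mets: List[Metabolite] = [Metabolite("S")]
    reactions: List[Reaction] = [
        Reaction("EX_S", {"S": -1.0}, lb=-uptake, is_exchange=True)
    ]
    genes: List[str] = []
    kcat: Dict[str, float] = {}
    mw: Dict[str, float] = {}

    def new_gene() -> str:
        g = f"g{len(genes) + 1:02d}"
        genes.append(g)
        mw[g] = float(rng.uniform(0.5, 2.0))
        return g

    def pick_gene() -> str:
        if genes and rng.random() < p_reuse:
            return genes[int(rng.integers(len(genes)))]
        return new_gene()

    prev = "S"
    for step in range(n_branch_points):
        cur = f"M{step + 1}"
        mets.append(Metabolite(cur))
        n_iso = int(rng.integers(1, n_isoforms_max + 1))
        for iso in range(n_iso):
            rid = f"R{step + 1}_{iso + 1}"
            if rng.random() < p_complex:
                gpr = And((Gene(pick_gene()), Gene(pick_gene())))
            else:
                gpr = Gene(pick_gene())
            reactions.append(Reaction(rid, {prev: -1.0, cur: 1.0}, gpr=gpr))
            kcat[rid] = float(10 ** rng.uniform(0.0, 2.0))
        if rng.random() < p_dead_end:
            dead = f"D{step + 1}"
            mets.append(Metabolite(dead))
            rid = f"RD{step + 1}"
            reactions.append(Reaction(rid, {cur: -1.0, dead: 1.0}, gpr=Gene(new_gene())))
            kcat[rid] = float(10 ** rng.uniform(0.0, 2.0))
        prev = cur
    reactions.append(Reaction("BIOMASS", {prev: -1.0}))
    model = MetabolicModel(mets, reactions, set(genes), "BIOMASS")
    params = EnzymeCostParams(kcat, mw, C=C)
    return model, params


Truth = Union[
    Sequence[Tuple[str, str, float]],
    Sequence[Tuple[str, str, float, float]],
]


def truth_from_records(records: Iterable[EpistasisRecord]) -> List[Tuple[str, str, float, float]]:
    """Turn pipeline records into a (gene_a, gene_b, eps, f) truth table."""
    return [(r.gene_a, r.gene_b, r.epsilon, r.W12) for r in records]


def generate_observed_calls(
    truth: Truth,
    fn_rate: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    interaction_cutoff: float = DEFAULT_EPS_CUTOFF,
) -> List[ExperimentalCall]:
    """Noisy experimental-style calls from a per-pair epistasis truth table.

    True interactions (|eps| >= cutoff) are dropped — their observed score
    set to 0 — with probability ``fn_rate``; all retained scores get
    additive zero-mean Gaussian jitter of sd ``jitter_sd``; classes are
    re-derived from the perturbed score with the same cutoff.  The output
    is byte-reproducible for a given seed.
    """
    if not 0 <= fn_rate < 1:
        raise ValueError("fn_rate must be in [0, 1)")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    calls = []
    for row in truth:
        a, b, eps = row[0], row[1], float(row[2])
        f_obs = float(row[3]) if len(row) > 3 else None
        a, b = pair_key(a, b)
        interacting = abs(eps) >= interaction_cutoff
        if interacting and rng.random() < fn_rate:
            eps_obs = 0.0
        else:
            eps_obs = eps + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
        calls.append(
            ExperimentalCall(a, b, eps_obs, classify_interaction(eps_obs, interaction_cutoff), f_obs)
        )
    return calls
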