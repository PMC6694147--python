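"""Evaluation of predicted genetic interactions against experimental calls.

Predictions and observations are compared as sets of unordered gene
pairs: precision (fraction of predictions confirmed), recall (fraction of
observed interactions recovered), and two false-positive-rate variants —
the textbook FP / (universe negatives) and the "fraction of predictions
not confirmed" reading (1 - precision) that appears in some interaction
studies.  Both are always computed and labelled so the ambiguity never
silently picks a side.  Cutoff sweeps trace precision/recall and ROC
curves over |eps| thresholds; four-way method overlaps are tabulated as
the full 15-region Venn partition; synthetic-lethal recall counts how
many observed SL pairs a method also calls SL.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .epistasis import (
    EpistasisRecord,
    SL_EPS_CUTOFF,
    SL_FITNESS_CUTOFF,
    call_synthetic_lethal,
)

__all__ = [
    "ExperimentalCall",
    "MetricCurve",
    "OverlapTable",
    "pair_key",
    "confusion_metrics",
    "sweep_cutoffs",
    "venn_overlap",
    "sl_recall",
    "read_experimental_calls",
    "write_experimental_calls",
]

Pair = Tuple[str, str]


def pair_key(a: str, b: str) -> Pair:
    """Canonical unordered-pair key (lexicographic)."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ExperimentalCall:
    gene_a: str
    gene_b: str
    epsilon_obs: float
    class_obs: str  # "negative" | "positive" | "none", taken as given
    f_obs: Optional[float] = None

    @property
    def pair(self) -> Pair:
        return pair_key(self.gene_a, self.gene_b)


@dataclass
class ConfusionMetrics:
    precision: float  # NaN when no predictions were made
    recall: float
    fpr_standard: float  # FP / (universe - observed)
    fpr_paper: float  # FP / predictions = 1 - precision


@dataclass
class MetricCurve:
    """Precision/recall/FPR as a function of the |eps| cutoff, one sign."""

    sign: str
    rows: pd.DataFrame  # columns: cutoff, precision, recall, fpr_standard, fpr_paper


@dataclass
class OverlapTable:
    """Counts of the 2^k - 1 exclusive Venn regions for k prediction sets."""

    region_counts: Dict[FrozenSet[str], int]
    unique_counts: Dict[str, int]
    pairwise_shares: pd.DataFrame  # share[i, j] = |S_i & S_j| / |S_i|

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())


def confusion_metrics(
    predicted: Set[Pair], observed: Set[Pair], universe_size: int
) -> ConfusionMetrics:
    """Precision, recall and both FPR variants for one prediction set."""
    union = predicted | observed
    if universe_size < len(union):
        raise ValueError(
            f"universe_size {universe_size} smaller than |predicted ∪ observed| = {len(union)}"
        )
    tp = len(predicted & observed)
    fp = len(predicted - observed)
    precision = tp / len(predicted) if predicted else math.nan
    recall = tp / len(observed) if observed else math.nan
    negatives = universe_size - len(observed)
    fpr_standard = fp / negatives if negatives else math.nan
    fpr_paper = fp / len(predicted) if predicted else math.nan
    return ConfusionMetrics(precision, recall, fpr_standard, fpr_paper)


def _predicted_at(records: Iterable[EpistasisRecord], cutoff: float, sign: str) -> Set[Pair]:
    if sign == "negative":
        return {pair_key(r.gene_a, r.gene_b) for r in records if r.epsilon <= -cutoff}
    if sign == "positive":
        return {pair_key(r.gene_a, r.gene_b) for r in records if r.epsilon >= cutoff}
    raise ValueError(f"sign must be 'negative' or 'positive', got {sign!r}")


def observed_pairs(calls: Iterable[ExperimentalCall], sign: str) -> Set[Pair]:
    return {c.pair for c in calls if c.class_obs == sign}


def sweep_cutoffs(
    records: Sequence[EpistasisRecord],
    observed_calls: Sequence[ExperimentalCall],
    cutoff_grid: Sequence[float],
    sign: str,
    universe_size: int,
) -> MetricCurve:
    """Metrics at each |eps| cutoff of a sorted positive grid, one sign.

    At cutoff t the predictions are {pairs with eps <= -t} (negative sweep)
    or {pairs with eps >= +t} (positive sweep), with inclusive boundaries,
    so a single cutoff reproduces the default classifier's sets.
    """
    grid = list(cutoff_grid)
    if not grid:
        raise ValueError("cutoff grid is empty")
    if any(t <= 0 for t in grid) or sorted(grid) != grid:
        raise ValueError("cutoff grid must be positive and sorted ascending")
    observed = observed_pairs(observed_calls, sign)
    rows = []
    for t in grid:
        m = confusion_metrics(_predicted_at(records, t, sign), observed, universe_size)
        rows.append(
            {
                "cutoff": t,
                "precision": m.precision,
                "recall": m.recall,
                "fpr_standard": m.fpr_standard,
                "fpr_paper": m.fpr_paper,
            }
        )
    return MetricCurve(sign, pd.DataFrame(rows))


def default_cutoff_grid(n: int = 25) -> List[float]:
    """Logarithmic grid from 1e-6 to 1e-1."""
    return [10 ** (-6 + 5 * i / (n - 1)) for i in range(n)]


def venn_overlap(prediction_sets: Mapping[str, Set[Pair]]) -> OverlapTable:
    """Exclusive Venn-region counts for named prediction sets.

    Each non-empty subset R of method names indexes the region of pairs
    predicted by exactly the methods in R; counts therefore sum to the size
    of the union.  Also reports per-method unique counts and the pairwise
    intersection shares |S_i & S_j| / |S_i|.
    """
    names = list(prediction_sets)
    sets = {m: set(s) for m, s in prediction_sets.items()}
    universe = set().union(*sets.values()) if sets else set()
    region_counts: Dict[FrozenSet[str], int] = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set(universe)
            for m in combo:
                inside &= sets[m]
            for m in names:
                if m not in combo:
                    inside -= sets[m]
            region_counts[frozenset(combo)] = len(inside)
    unique_counts = {m: region_counts.get(frozenset({m}), 0) for m in names}
    share = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            share.loc[a, b] = (len(sets[a] & sets[b]) / len(sets[a])) if sets[a] else math.nan
    return OverlapTable(region_counts, unique_counts, share)


def sl_recall(
    records_by_method: Mapping[str, Sequence[EpistasisRecord]],
    observed_sl: Set[Pair],
    eps_cutoff: float = SL_EPS_CUTOFF,
    f_cutoff: float = SL_FITNESS_CUTOFF,
) -> Dict[str, int]:
    """Per method: how many observed synthetic-lethal pairs it also calls SL.

    Supports relaxed fitness cutoffs (e.g. probing f < 0.55 while keeping
    negative epistasis) by passing different ``eps_cutoff``/``f_cutoff``.
    """
    out = {}
    for method, records in records_by_method.items():
        predicted = {
            pair_key(r.gene_a, r.gene_b)
            for r in records
            if call_synthetic_lethal(r.epsilon, r.f, eps_cutoff, f_cutoff)
        }
        out[method] = len(predicted & observed_sl)
    return out


def read_experimental_calls(path) -> List[ExperimentalCall]:
    """TSV with columns gene_a, gene_b, epsilon_obs, class_obs[, f_obs]."""
    df = pd.read_csv(path, sep="\t")
    calls = []
    for _, r in df.iterrows():
        f_obs = float(r["f_obs"]) if "f_obs" in df.columns and not pd.isna(r["f_obs"]) else None
        calls.append(
            ExperimentalCall(
                str(r["gene_a"]), str(r["gene_b"]),
                float(r["epsilon_obs"]), str(r["class_obs"]), f_obs,
            )
        )
    return calls


def write_experimental_calls(calls: Iterable[ExperimentalCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tepsilon_obs\tclass_obs\tf_obs\n")
        for c in calls:
            f_obs = "" if c.f_obs is None else f"{c.f_obs:.10g}"
            fh.write(f"{c.gene_a}\t{c.gene_b}\t{c.epsilon_obs:.10g}\t{c.class_obs}\t{f_obs}\n")
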