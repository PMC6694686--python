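"""Cohort coverage optimization: choose at most k guide-pair sites covering
the maximum number of individuals.

The problem is the classical maximum-coverage variant of set cover, posed
on the bipartite graph of guide pairs and the individuals in which each pair
is usable (both variants heterozygous with the targeted alleles in cis).
It is solved exactly as a binary integer linear program:

    maximize   sum_s y_s
    subject to sum_p x_p <= k
               y_s <= sum_{p in N(s)} x_p        for every sample s
               x_p, y_s in {0, 1}

solved with the HiGHS MILP engine (``scipy.optimize.milp``); any ILP solver
satisfying the model is interchangeable — the model, not the engine, is the
contract. A naive top-k baseline (rank pairs by how many individuals share
them) and an exhaustive subset-enumeration oracle are provided for
comparison and testing; a greedy heuristic rounds out the classical
(1 − 1/e)-approximation reference point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import lil_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoverGraph",
    "CoverageSolution",
    "build_cover_graph",
    "solve_max_coverage_ilp",
    "top_k_baseline",
    "greedy_max_coverage",
    "exhaustive_oracle",
    "coverage_report",
]

EXHAUSTIVE_GUARD = 20


@dataclass
class CoverGraph:
    """Bipartite incidence of guide-pair sites and cohort individuals.

    ``samples`` is the full cohort (covered or not); edges reference
    declared ids only and duplicates are collapsed.
    """

    pairs: list[str]
    samples: list[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        pset, sset = set(self.pairs), set(self.samples)
        if len(pset) != len(self.pairs) or len(sset) != len(self.samples):
            raise ValueError("duplicate pair or sample ids in cover graph")
        bad = [e for e in self.edges if e[0] not in pset or e[1] not in sset]
        if bad:
            raise ValueError(f"edges reference undeclared ids: {bad[:5]}")

    def neighborhood(self, pair: str) -> frozenset[str]:
        return frozenset(s for p, s in self.edges if p == pair)

    def neighborhoods(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {p: set() for p in self.pairs}
        for p, s in self.edges:
            out[p].add(s)
        return {p: frozenset(v) for p, v in out.items()}


@dataclass
class CoverageSolution:
    method: str  # 'ilp' | 'top_k' | 'greedy' | 'exhaustive'
    k: int
    chosen: list[str]
    covered: frozenset[str]
    n_cohort: int
    group_coverage: dict[str, float] | None = None

    @property
    def coverage(self) -> float:
        return len(self.covered) / self.n_cohort if self.n_cohort else 0.0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "k": self.k,
            "chosen_pairs": sorted(self.chosen),
            "covered_samples": sorted(self.covered),
            "coverage": self.coverage,
            "group_coverage": self.group_coverage,
        }


def build_cover_graph(
    pair_sample_edges: pd.DataFrame | list[tuple[str, str]],
    cohort: list[str],
) -> CoverGraph:
    """Assemble a cover graph from (pair_id, sample_id) usability edges.

    ``cohort`` declares every individual (the denominator of coverage);
    pairs covering no cohort sample are dropped with a logged count.
    """
    if isinstance(pair_sample_edges, pd.DataFrame):
        edges = {
            (str(r.pair_id), str(r.sample_id))
            for r in pair_sample_edges.itertuples(index=False)
        }
    else:
        edges = {(str(p), str(s)) for p, s in pair_sample_edges}
    cohort_set = set(cohort)
    declared_pairs = {p for p, _ in edges}
    edges = {(p, s) for p, s in edges if s in cohort_set}
    pairs = sorted({p for p, _ in edges})
    n_dropped = len(declared_pairs - set(pairs))
    if n_dropped:
        logger.info("dropped %d pairs covering no cohort sample", n_dropped)
    return CoverGraph(pairs=pairs, samples=list(cohort), edges=edges)


def _solution_from_chosen(
    graph: CoverGraph, method: str, k: int, chosen: list[str]
) -> CoverageSolution:
    nbhd = graph.neighborhoods()
    covered: set[str] = set()
    for p in chosen:
        covered |= nbhd[p]
    return CoverageSolution(
        method=method,
        k=k,
        chosen=list(chosen),
        covered=frozenset(covered),
        n_cohort=len(graph.samples),
    )


def solve_max_coverage_ilp(graph: CoverGraph, k: int) -> CoverageSolution:
    """Exact maximum coverage by binary ILP (see module docstring)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    P, S = len(graph.pairs), len(graph.samples)
    if P == 0 or not graph.edges:
        return _solution_from_chosen(graph, "ilp", k, [])
    pair_idx = {p: i for i, p in enumerate(graph.pairs)}
    sample_idx = {s: j for j, s in enumerate(graph.samples)}

    # variables: x_0..x_{P-1}, y_0..y_{S-1}; maximize sum(y) == minimize -sum(y)
    c = np.concatenate([np.zeros(P), -np.ones(S)])
    A = lil_matrix((1 + S, P + S))
    A[0, :P] = 1.0  # sum x_p <= k
    for (p, s) in graph.edges:
        A[1 + sample_idx[s], pair_idx[p]] = -1.0
    for j in range(S):
        A[1 + j, P + j] = 1.0  # y_s - sum_{p in N(s)} x_p <= 0
    ub = np.concatenate([[k], np.zeros(S)])
    lb = -np.inf * np.ones(1 + S)
    res = milp(
        c=c,
        constraints=LinearConstraint(A.tocsr(), lb, ub),
        integrality=np.ones(P + S),
        bounds=Bounds(0, 1),
    )
    if not res.success:
        raise RuntimeError(f"ILP solver failed: {res.message}")
    x = res.x[:P]
    chosen = [graph.pairs[i] for i in range(P) if x[i] > 0.5]
    # coverage recomputed from the chosen set (robust to solver slack in y)
    return _solution_from_chosen(graph, "ilp", k, chosen)


def top_k_baseline(graph: CoverGraph, k: int) -> CoverageSolution:
    """Naive baseline: the k most highly shared pairs (ties lexicographic)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    nbhd = graph.neighborhoods()
    ranked = sorted(graph.pairs, key=lambda p: (-len(nbhd[p]), p))
    return _solution_from_chosen(graph, "top_k", k, ranked[:k])


def greedy_max_coverage(graph: CoverGraph, k: int) -> CoverageSolution:
    """Greedy heuristic: repeatedly add the pair covering the most
    not-yet-covered samples ((1 − 1/e)-approximate)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    nbhd = graph.neighborhoods()
    covered: set[str] = set()
    chosen: list[str] = []
    remaining = set(graph.pairs)
    for _ in range(min(k, len(graph.pairs))):
        best = max(
            sorted(remaining), key=lambda p: len(nbhd[p] - covered), default=None
        )
        if best is None or not (nbhd[best] - covered):
            break
        chosen.append(best)
        covered |= nbhd[best]
        remaining.discard(best)
    return _solution_from_chosen(graph, "greedy", k, chosen)


def exhaustive_oracle(graph: CoverGraph, k: int) -> CoverageSolution:
    """Evaluate every <=k-subset of pairs; exact but exponential.

    Guarded to at most ``EXHAUSTIVE_GUARD`` pairs. Among maximum-coverage
    subsets, returns the lexicographically smallest chosen-pair set (the
    canonical optimum used to make tests deterministic).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(graph.pairs) > EXHAUSTIVE_GUARD:
        raise ValueError(
            f"exhaustive oracle refused: {len(graph.pairs)} pairs exceeds "
            f"guard bound {EXHAUSTIVE_GUARD}"
        )
    nbhd = graph.neighborhoods()
    best: tuple[int, tuple[str, ...]] | None = None
    m = min(k, len(graph.pairs))
    for subset in combinations(sorted(graph.pairs), m) if m else [()]:
        covered: set[str] = set()
        for p in subset:
            covered |= nbhd[p]
        key = (-len(covered), subset)
        if best is None or key < best:
            best = key
    chosen = list(best[1]) if best else []
    return _solution_from_chosen(graph, "exhaustive", k, chosen)


def coverage_report(
    solution: CoverageSolution,
    groups: dict[str, str] | pd.DataFrame | None,
    cohort: list[str],
) -> dict[str, float]:
    """Per-group covered fractions, plus 'overall'.

    ``groups`` maps sample -> group label (DataFrame columns: sample,
    group); every covered sample must be labeled.
    """
    report = {"overall": len(solution.covered) / len(cohort) if cohort else 0.0}
    if groups is None:
        return report
    if isinstance(groups, pd.DataFrame):
        groups = {
            str(r.sample): str(r.group) for r in groups.itertuples(index=False)
        }
    unlabeled = sorted(set(solution.covered) - groups.keys())
    if unlabeled:
        raise ValueError(f"covered samples without a group label: {unlabeled[:5]}")
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for s in cohort:
        g = groups.get(s)
        if g is None:
            continue
        totals[g] = totals.get(g, 0) + 1
        if s in solution.covered:
            hits[g] = hits.get(g, 0) + 1
    for g, total in sorted(totals.items()):
        report[g] = hits.get(g, 0) / total if total else 0.0
    return report
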