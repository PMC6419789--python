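"""Greedy steepest-descent optimisation of electron assignments.

A cheap, always-converging heuristic: build an initial assignment by placing
one unit (pair, by default) at a time on the position that currently yields
the lowest total score, then repeatedly move a unit from one position to
another whenever that lowers the score, stopping at a local minimum.  The
result is not guaranteed to be the global optimum; the exact solvers in
:mod:`lewisopt.opt_astar` and :mod:`lewisopt.opt_fpt` are.

All tie-breaks are deterministic: candidate positions are examined in the
multiset's canonical order (vertices by index, then edges lexicographically),
and the first position achieving the best score wins.
"""

from __future__ import annotations

import time
from typing import Dict, List, Optional, Tuple

from .exceptions import InfeasibleMolecule
from .molgraph import MolecularGraph, PositionMultiset
from .scoring import (
    INF,
    AssignmentResult,
    ElectronAssignment,
    ScoreTable,
    assignment_score,
    result_from_assignment,
)

Counts = Tuple[int, ...]


def _score(g: MolecularGraph, p: PositionMultiset, counts: Counts,
           table: ScoreTable, fixed: Optional[Dict]) -> float:
    return assignment_score(g, ElectronAssignment(p, counts, fixed), table)


def initial_assignment(g: MolecularGraph, p: PositionMultiset,
                       table: ScoreTable,
                       fixed: Optional[Dict] = None) -> ElectronAssignment:
    """Greedy construction: add one unit at a time at the cheapest position."""
    counts = [0] * len(p)
    caps = [p.mult(pos) for pos in p.order]
    for _ in range(p.e_t):
        best = None
        best_score = None
        for i in range(len(counts)):
            if counts[i] >= caps[i]:
                continue
            counts[i] += 1
            s = _score(g, p, tuple(counts), table, fixed)
            counts[i] -= 1
            if best_score is None or s < best_score:
                best, best_score = i, s
        if best is None:
            raise InfeasibleMolecule("no capacity left before e_T was placed")
        counts[best] += 1
    return ElectronAssignment(p, tuple(counts), fixed)


def neighbours(assignment: ElectronAssignment,
               p: PositionMultiset) -> List[ElectronAssignment]:
    """All assignments reachable by moving one unit between two positions."""
    counts = assignment.counts
    caps = [p.mult(pos) for pos in p.order]
    out = []
    seen = set()
    for src in range(len(counts)):
        if counts[src] == 0:
            continue
        for dst in range(len(counts)):
            if dst == src or counts[dst] >= caps[dst]:
                continue
            moved = list(counts)
            moved[src] -= 1
            moved[dst] += 1
            key = tuple(moved)
            if key not in seen:
                seen.add(key)
                out.append(ElectronAssignment(p, key, assignment.fixed))
    return out


def minimise_local(g: MolecularGraph, p: PositionMultiset, table: ScoreTable,
                   timeout_s: float = 5.0, follow_ties: bool = False,
                   fixed: Optional[Dict] = None) -> AssignmentResult:
    """Steepest descent to a local minimum of the assignment score.

    With ``follow_ties`` every equal-lowest neighbour is kept and expanded
    (breadth-wise), which can escape plateaus at extra cost.  A wall-clock
    ``timeout_s`` guard returns the best assignment found so far with the
    ``timed_out`` flag set.
    """
    deadline = time.monotonic() + timeout_s
    current = initial_assignment(g, p, table, fixed)
    current_score = assignment_score(g, current, table)
    frontier = [current]
    visited = {current.counts}
    timed_out = False

    while True:
        best_score = None
        best: List[ElectronAssignment] = []
        for asg in frontier:
            for nb in neighbours(asg, p):
                if time.monotonic() > deadline:
                    timed_out = True
                    break
                s = assignment_score(g, nb, table)
                if best_score is None or s < best_score:
                    best_score, best = s, [nb]
                elif follow_ties and s == best_score and nb.counts not in visited:
                    best.append(nb)
            if timed_out:
                break
        if timed_out or best_score is None or not best_score < current_score:
            # At infinite plateaus, allow sideways steps through unvisited
            # assignments so descent can eventually reach finite territory.
            if (not timed_out and best_score == INF and current_score == INF):
                fresh = [a for a in best if a.counts not in visited]
                if fresh:
                    frontier = fresh if follow_ties else fresh[:1]
                    for a in frontier:
                        visited.add(a.counts)
                    continue
            break
        current = best[0]
        current_score = best_score
        frontier = best if follow_ties else [best[0]]
        for a in frontier:
            visited.add(a.counts)

    result = result_from_assignment(g, current, table, algorithm="local",
                                    timed_out=timed_out)
    return result
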