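"""Exact A* search over the tree of partial electron assignments.

The unique positions are laid out in a fixed order (a breadth-first traversal
that keeps each atom next to its incident bonds); level ``k`` of the search
tree decides the electron count of position ``k``.  A node's priority is
``f = g + h``:

* ``g`` — the summed scores of all *calculable* members (atoms whose own
  count and all incident bond counts are decided; bonds whose endpoints are
  calculable), +inf when the budget is exceeded;
* ``h`` — for every not-yet-calculable member, the minimum score over the
  electron counts (bonds) or formal charges (atoms) it can still reach,
  which never exceeds the true completion cost (admissible), so the first
  complete assignment popped is optimal.

Children whose ``f`` exceeds the greedy local-optimisation score plus one
are pruned, and a configurable memory cap on the priority queue aborts the
search on pathological molecules rather than thrashing.
"""

from __future__ import annotations

import heapq
import itertools
from typing import Dict, List, Optional, Tuple

from .exceptions import MemoryLimitExceeded
from .molgraph import MolecularGraph, PositionMultiset
from .opt_local import minimise_local
from .scoring import (
    INF,
    AssignmentResult,
    ElectronAssignment,
    ScoreTable,
    edge_score,
    formal_charge,
    invalid_result,
    result_from_assignment,
    valence,
    vertex_score,
)

#: documented per-node accounting constant for the queue memory estimate
NODE_BASE_BYTES = 96
NODE_PER_LEVEL_BYTES = 8


def order_positions(g: MolecularGraph, p: PositionMultiset) -> List:
    """Deterministic level order: BFS from atom 0, each bond emitted as soon
    as both endpoints have been visited, so members become calculable early.
    """
    in_p = set()
    for pos in p.order:
        in_p.add(pos)
    ordered: List = []
    visited = set()
    queue = [g.atoms[0].index] if g.atoms else []
    visited.update(queue)
    while queue:
        v = queue.pop(0)
        for e in g.incident_edges(v):
            u = e[0] if e[1] == v else e[1]
            if u in visited and e in in_p and e not in ordered:
                ordered.append(e)
        if v in in_p:
            ordered.append(v)
        for u in g.neighbors(v):
            if u not in visited:
                visited.add(u)
                queue.append(u)
    return ordered


def calculable_levels(g: MolecularGraph, p: PositionMultiset,
                      order: List) -> List[List]:
    """For each level 0..|P|, the set Q of calculable members.

    Calculability depends only on which positions are decided, i.e. on the
    level, so it is precomputed once.  Returned as, per level, the list of
    members newly calculable at that level (so g can be updated
    incrementally); level lists are cumulative via ``itertools.accumulate``
    by the caller if needed.
    """
    undecided_at: Dict = {pos: lvl for lvl, pos in enumerate(order)}
    n_levels = len(order)
    newly: List[List] = [[] for _ in range(n_levels + 1)]

    def decided_level(member) -> int:
        """First level at which `member` counts as decided-or-never."""
        lvl = undecided_at.get(member)
        return 0 if lvl is None else lvl + 1

    vertex_level: Dict[int, int] = {}
    for a in g.atoms:
        lvl = decided_level(a.index)
        for e in g.incident_edges(a.index):
            lvl = max(lvl, decided_level(e))
        vertex_level[a.index] = lvl
    for v, lvl in vertex_level.items():
        newly[lvl].append(v)
    for e in g.bonds:
        lvl = max(decided_level(e), vertex_level[e[0]], vertex_level[e[1]])
        newly[lvl].append(e)
    return newly


def calculable_set(g: MolecularGraph, p: PositionMultiset, order: List,
                   level: int) -> set:
    """Q at a given level (reference form of :func:`calculable_levels`)."""
    newly = calculable_levels(g, p, order)
    out = set()
    for lvl in range(level + 1):
        out.update(newly[lvl])
    return out


def _member_score(g, asg, table, member) -> float:
    if isinstance(member, tuple):
        return edge_score(g, asg, table, member)
    return vertex_score(g, asg, table, member)


def g_cost(g: MolecularGraph, p: PositionMultiset, order: List,
           counts: Tuple[int, ...], table: ScoreTable,
           fixed: Optional[Dict] = None) -> float:
    """Exact cost of the calculable members under a partial assignment."""
    level = len(counts)
    if sum(counts) > p.e_t:
        return INF
    asg = _partial_assignment(p, order, counts, fixed)
    total = 0.0
    for member in calculable_set(g, p, order, level):
        s = _member_score(g, asg, table, member)
        if s == INF:
            return INF
        total += s
    return total


def _partial_assignment(p, order, counts, fixed) -> ElectronAssignment:
    by_pos = dict(zip(order, counts))
    full = tuple(by_pos.get(pos, 0) for pos in p.order)
    return ElectronAssignment(p, full, fixed)


def h_cost(g: MolecularGraph, p: PositionMultiset, order: List,
           counts: Tuple[int, ...], table: ScoreTable,
           fixed: Optional[Dict] = None) -> float:
    """Admissible completion estimate: per-member minimum over its options."""
    level = len(counts)
    asg = _partial_assignment(p, order, counts, fixed)
    newly = calculable_levels(g, p, order)
    calculable = set()
    for lvl in range(level + 1):
        calculable.update(newly[lvl])
    total = 0.0
    for a in g.atoms:
        v = a.index
        if v in calculable:
            continue
        s = _vertex_h(g, asg, table, v)
        if s == INF:
            return INF
        total += s
    for e in g.bonds:
        if e in calculable:
            continue
        s = _edge_h(g, p, asg, table, e)
        if s == INF:
            return INF
        total += s
    return total


def _vertex_h(g, asg, table, v) -> float:
    atom = g.atom(v)
    val = valence(g, asg, v)
    room = atom.target_valency - val
    if room < 0:
        return INF
    fc_now = formal_charge(g, asg, v)
    best = INF
    base = int(fc_now) if fc_now == int(fc_now) else None
    if base is None:
        return INF
    for drop in range(room + 1):
        s = table.atom_score(atom.atomic_number, base - drop)
        if s < best:
            best = s
    return best


def _edge_h(g, p, asg, table, e) -> float:
    y, z = e
    unit = p.unit
    cap = p.mult(e) - asg.units_on(e)  # remaining units on the bond
    val_y = valence(g, asg, y)
    val_z = valence(g, asg, z)
    tau_y = g.atom(y).target_valency
    tau_z = g.atom(z).target_valency
    base_total = asg.edge_total(e)
    best = INF
    for b in range(cap + 1):
        add = b * unit
        if val_y + add > tau_y or val_z + add > tau_z:
            break
        s = table.bond_score(g.atom(y).atomic_number, g.atom(z).atomic_number,
                             base_total + add)
        if s < best:
            best = s
    return best


def astar_search(g: MolecularGraph, p: PositionMultiset, table: ScoreTable,
                 memory_limit_mb: float = 1024,
                 fixed: Optional[Dict] = None,
                 local_timeout_s: float = 5.0) -> AssignmentResult:
    """Optimal electron assignment by best-first search.

    Raises :class:`MemoryLimitExceeded` (returning no partial answer) when
    the queue's estimated footprint passes ``memory_limit_mb``.
    """
    order = order_positions(g, p)
    n_levels = len(order)
    caps = [p.mult(pos) for pos in order]
    node_bytes = NODE_BASE_BYTES + NODE_PER_LEVEL_BYTES * max(1, n_levels)
    limit_bytes = memory_limit_mb * (1 << 20)
    if node_bytes > limit_bytes:
        raise MemoryLimitExceeded(
            f"memory limit {memory_limit_mb} MB cannot hold a single node")

    upper = minimise_local(g, p, table, timeout_s=local_timeout_s,
                           fixed=fixed).score + 1

    suffix_cap = [0] * (n_levels + 1)
    for i in range(n_levels - 1, -1, -1):
        suffix_cap[i] = suffix_cap[i + 1] + caps[i]

    newly = calculable_levels(g, p, order)

    counter = itertools.count()
    root_counts: Tuple[int, ...] = ()
    root_g = g_cost(g, p, order, root_counts, table, fixed)
    root_h = h_cost(g, p, order, root_counts, table, fixed)
    heap: List = []
    heapq.heappush(heap, (root_g + root_h, 0, next(counter), root_counts, root_g))

    while heap:
        if len(heap) * node_bytes > limit_bytes:
            raise MemoryLimitExceeded(
                f"A* queue estimate exceeded {memory_limit_mb} MB")
        f, neg_level, _, counts, node_g = heapq.heappop(heap)
        if f == INF:
            # admissibility: every completion through every remaining node
            # is infinitely scored, so the optimum is +inf
            return invalid_result("astar")
        level = len(counts)
        if level == n_levels:
            asg = _partial_assignment(p, order, counts, fixed)
            return result_from_assignment(g, asg, table, algorithm="astar")
        remaining = p.e_t - sum(counts)
        for n in range(caps[level] + 1):
            if n > remaining:
                break
            if remaining - n > suffix_cap[level + 1]:
                continue  # not enough capacity left to finish
            child = counts + (n,)
            asg = _partial_assignment(p, order, child, fixed)
            child_g = node_g
            for member in newly[level + 1]:
                s = _member_score(g, asg, table, member)
                child_g = child_g + s if s != INF else INF
                if child_g == INF:
                    break
            child_h = 0.0 if child_g == INF else \
                h_cost(g, p, order, child, table, fixed)
            child_f = child_g + child_h
            if child_f > upper:
                continue
            heapq.heappush(
                heap, (child_f, -(level + 1), next(counter), child, child_g))

    return invalid_result("astar")
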