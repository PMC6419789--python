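"""Exact fixed-parameter-tractable optimisation via tree decompositions.

Molecular graphs are sparse and tree-like, so the electron-assignment
problem is solved by dynamic programming over a *nice* tree decomposition:
a rooted tree of bags refined into leaf / introduce / forget / join nodes,
each bag changing by exactly one member.  Because both atoms and bonds must
be scored, bonds are promoted to bag members: a bond belongs to every bag
containing at least one of its endpoints, which keeps the bags-containing-it
subtree connected, guarantees that an atom's incident bonds are on hand in
the bag where the atom is forgotten (its formal charge and valence are
evaluated there), and lets the bond itself be forgotten — and scored — right
after its second endpoint.

Per node ``t`` the DP table ``S_t[l, k]`` holds the minimum total score of
all members already forgotten below ``t``, given that ``l`` electron units
were placed on them and that the current bag members carry the counts ``k``.
Budgets outside the feasible window (what the forgotten positions can hold
vs. what the remaining positions can still absorb) are pruned.  The root has
an empty bag, so the answer is ``S_root[e_T, ()]``, and all minimum-score
resonance structures are recovered by backtracking every arg-min choice,
capped (default 32) against combinatorial explosion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .exceptions import MalformedInput, NoValidAssignment
from .molgraph import MolecularGraph, PositionMultiset
from .scoring import (
    INF,
    AssignmentResult,
    ElectronAssignment,
    ScoreTable,
    invalid_result,
    result_from_assignment,
)

Member = object  # int (vertex) or Tuple[int, int] (edge)


def _member_key(m) -> Tuple:
    if isinstance(m, tuple):
        return (1, m[0], m[1])
    return (0, m, -1)


# ---------------------------------------------------------------------------
# tree decomposition (GreedyFillIn)
# ---------------------------------------------------------------------------

@dataclass
class TreeDecomposition:
    """Tree of vertex bags covering a graph with running intersection."""

    bags: Dict[int, frozenset]
    tree_edges: List[Tuple[int, int]]

    @property
    def width(self) -> int:
        return max(len(b) for b in self.bags.values()) - 1

    def neighbors(self, node: int) -> List[int]:
        out = []
        for (a, b) in self.tree_edges:
            if a == node:
                out.append(b)
            elif b == node:
                out.append(a)
        return sorted(out)

    def validate(self, g: MolecularGraph) -> None:
        covered = set()
        for b in self.bags.values():
            covered |= b
        if covered != {a.index for a in g.atoms}:
            raise MalformedInput("tree decomposition does not cover all vertices")
        for (u, v) in g.bonds:
            if not any(u in b and v in b for b in self.bags.values()):
                raise MalformedInput(f"edge ({u},{v}) not covered by any bag")
        # running intersection: nodes whose bag contains v form a subtree
        for v in covered:
            nodes = [t for t, b in self.bags.items() if v in b]
            seen = {nodes[0]}
            stack = [nodes[0]]
            node_set = set(nodes)
            while stack:
                for nb in self.neighbors(stack.pop()):
                    if nb in node_set and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if seen != node_set:
                raise MalformedInput(f"bags containing {v} are disconnected")


def greedy_fill_in(g: MolecularGraph) -> TreeDecomposition:
    """Width upper bound via the greedy minimum-fill-in elimination heuristic.

    Repeatedly eliminates the vertex whose neighbourhood needs the fewest
    fill edges to become a clique (ties: smallest current degree, then
    smallest index), recording ``{v} union N(v)`` as its bag.
    """
    adj: Dict[int, Set[int]] = {a.index: set(g.neighbors(a.index)) for a in g.atoms}
    order: List[int] = []
    bags: Dict[int, frozenset] = {}
    bag_of: Dict[int, int] = {}  # eliminated vertex -> bag node id
    remaining = set(adj)

    while remaining:
        best = None
        for v in sorted(remaining):
            nbrs = adj[v]
            fill = 0
            nl = sorted(nbrs)
            for i in range(len(nl)):
                for j in range(i + 1, len(nl)):
                    if nl[j] not in adj[nl[i]]:
                        fill += 1
            cand = (fill, len(nbrs), v)
            if best is None or cand < best:
                best = cand
        v = best[2]
        nbrs = sorted(adj[v])
        node = len(order)
        bags[node] = frozenset([v] + nbrs)
        bag_of[v] = node
        order.append(v)
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                adj[nbrs[i]].add(nbrs[j])
                adj[nbrs[j]].add(nbrs[i])
        for u in nbrs:
            adj[u].discard(v)
        del adj[v]
        remaining.discard(v)

    # connect each bag to the bag of the earliest-eliminated later vertex
    elim_rank = {v: i for i, v in enumerate(order)}
    tree_edges: List[Tuple[int, int]] = []
    for node, v in enumerate(order):
        later = [u for u in bags[node] if u != v]
        if later:
            parent_vertex = min(later, key=lambda u: elim_rank[u])
            tree_edges.append((node, bag_of[parent_vertex]))
    return TreeDecomposition(bags, tree_edges)


# ---------------------------------------------------------------------------
# nice tree decomposition over members (vertices + edges)
# ---------------------------------------------------------------------------

@dataclass
class NTDNode:
    kind: str  # leaf | introduce | forget | join | root
    members: Tuple  # sorted member tuple (the bag)
    children: List["NTDNode"] = field(default_factory=list)
    changed: Optional[Member] = None  # introduced/forgotten member
    vertex_bag: frozenset = frozenset()


@dataclass
class NiceTreeDecomposition:
    root: NTDNode
    graph: MolecularGraph

    def nodes(self) -> List[NTDNode]:
        out: List[NTDNode] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    @property
    def width(self) -> int:
        return max(len(n.members) for n in self.nodes()) - 1

    def validate(self) -> None:
        g = self.graph
        all_members = {a.index for a in g.atoms} | set(g.bonds)
        forgotten: List[Member] = []
        covered: Set = set()
        for n in self.nodes():
            covered.update(n.members)
            if n.kind in ("leaf",) and n.members:
                raise MalformedInput("leaf bag not empty")
            if n.kind == "root" and n.members:
                raise MalformedInput("root bag not empty")
            if len(n.children) > 2:
                raise MalformedInput("node with more than two children")
            if n.kind == "join":
                c, d = n.children
                if not (n.members == c.members == d.members):
                    raise MalformedInput("join bags differ")
            if n.kind == "introduce":
                (c,) = n.children
                if set(n.members) != set(c.members) | {n.changed} or \
                        len(n.members) != len(c.members) + 1:
                    raise MalformedInput("introduce does not add exactly one member")
            if n.kind in ("forget", "root"):
                (c,) = n.children
                if set(c.members) != set(n.members) | {n.changed} or \
                        len(c.members) != len(n.members) + 1:
                    raise MalformedInput("forget does not drop exactly one member")
                forgotten.append(n.changed)
        if covered != all_members:
            raise MalformedInput("nice decomposition does not cover all members")
        if len(forgotten) != len(set(forgotten)) or set(forgotten) != all_members:
            raise MalformedInput("each member must be forgotten exactly once")
        # running intersection over members
        parent: Dict[int, Optional[NTDNode]] = {id(self.root): None}
        order = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            order.append(n)
            for c in n.children:
                parent[id(c)] = n
                stack.append(c)
        for m in all_members:
            holders = [n for n in order if m in n.members]
            if not holders:
                continue
            hset = {id(n) for n in holders}
            roots = 0
            for n in holders:
                par = parent[id(n)]
                if par is None or id(par) not in hset:
                    roots += 1
            if roots != 1:
                raise MalformedInput(f"bags containing member {m} are disconnected")


def _rooted(td: TreeDecomposition) -> Tuple[int, Dict[int, List[int]]]:
    root = min(td.bags)
    children: Dict[int, List[int]] = {t: [] for t in td.bags}
    seen = {root}
    stack = [root]
    while stack:
        t = stack.pop()
        for nb in td.neighbors(t):
            if nb not in seen:
                seen.add(nb)
                children[t].append(nb)
                stack.append(nb)
    return root, children


def make_nice(td: TreeDecomposition, g: MolecularGraph) -> NiceTreeDecomposition:
    """Refine a tree decomposition into a nice one over vertices and edges."""
    td.validate(g)
    root_id, child_map = _rooted(td)
    incident = {a.index: list(g.incident_edges(a.index)) for a in g.atoms}

    def intro_chain(base: Optional[NTDNode], have_v: Set[int],
                    want_v: frozenset) -> Tuple[NTDNode, Set[int], Set]:
        """Introduce vertices of want_v \\ have_v (and their bonds) above base."""
        node = base
        members: Set = set(base.members) if base else set()
        vs = set(have_v)
        for v in sorted(want_v - have_v):
            members.add(v)
            node = NTDNode("introduce", tuple(sorted(members, key=_member_key)),
                           [node] if node else [], v, frozenset(vs | {v}))
            vs.add(v)
            for e in incident[v]:
                if e not in members:
                    members.add(e)
                    node = NTDNode("introduce",
                                   tuple(sorted(members, key=_member_key)),
                                   [node], e, frozenset(vs))
        return node, vs, members

    def forget_chain(base: NTDNode, have_v: Set[int],
                     keep_v: frozenset) -> Tuple[NTDNode, Set[int], Set]:
        node = base
        members: Set = set(base.members)
        vs = set(have_v)
        for v in sorted(have_v - keep_v):
            vs.discard(v)
            members.discard(v)
            node = NTDNode("forget", tuple(sorted(members, key=_member_key)),
                           [node], v, frozenset(vs))
            for e in incident[v]:
                other = e[0] if e[1] == v else e[1]
                if e in members and other not in vs:
                    members.discard(e)
                    node = NTDNode("forget",
                                   tuple(sorted(members, key=_member_key)),
                                   [node], e, frozenset(vs))
        return node, vs, members

    def build(t: int) -> NTDNode:
        bag = td.bags[t]
        kids = sorted(child_map[t])
        if not kids:
            leaf = NTDNode("leaf", (), [], None, frozenset())
            top, _, _ = intro_chain(leaf, set(), bag)
            return top if top is not None else leaf
        tops: List[NTDNode] = []
        for c in kids:
            sub = build(c)
            node, vs, _ = forget_chain(sub, set(td.bags[c]), bag)
            node, vs, _ = intro_chain(node, vs, bag)
            tops.append(node if node is not None else sub)
        combined = tops[0]
        for other in tops[1:]:
            combined = NTDNode("join", combined.members, [combined, other],
                               None, bag)
        return combined

    top = build(root_id)
    final, vs, members = forget_chain(top, set(td.bags[root_id]), frozenset())
    # the last forget leaves an empty bag: relabel it as the formal root
    if final.members:
        raise MalformedInput("root bag not empty after final forget chain")
    final.kind = "root"
    return NiceTreeDecomposition(final, g)


def decompose(g: MolecularGraph) -> NiceTreeDecomposition:
    """GreedyFillIn decomposition refined to a nice one."""
    return make_nice(greedy_fill_in(g), g)


# ---------------------------------------------------------------------------
# dynamic programme
# ---------------------------------------------------------------------------

class _DP:
    def __init__(self, g: MolecularGraph, p: PositionMultiset,
                 table: ScoreTable, ntd: NiceTreeDecomposition,
                 fixed: Optional[Dict] = None):
        self.g = g
        self.p = p
        self.table = table
        self.ntd = ntd
        self.fixed = fixed or {}
        self.e_t = p.e_t
        self.capacity = p.capacity
        self.tables: Dict[int, Dict] = {}
        self.forgotten_cap: Dict[int, int] = {}

    # -- member scoring ----------------------------------------------------
    def member_score(self, member, bag_counts: Dict, n: int) -> float:
        """Score of ``member`` carrying ``n`` units, in the context of the
        bag counts ``bag_counts`` (covers all its incident bonds)."""
        g, p, unit = self.g, self.p, self.p.unit
        if isinstance(member, tuple):
            total = 2 + (n + self.fixed.get(member, 0)) * unit
            return self.table.bond_score(g.atom(member[0]).atomic_number,
                                         g.atom(member[1]).atomic_number,
                                         total)
        atom = g.atom(member)
        own = (n + self.fixed.get(member, 0)) * unit
        val = own
        half = 0.0
        for e in g.incident_edges(member):
            etotal = 2 + (bag_counts[e] + self.fixed.get(e, 0)) * unit
            val += etotal
            half += etotal / 2
        if val > atom.target_valency:
            return INF
        fc = atom.valence_electrons - own - half
        if fc != int(fc):
            return INF
        return self.table.atom_score(atom.atomic_number, int(fc))

    def _l_bounds(self, forgotten_cap: int) -> Tuple[int, int]:
        n_min = max(0, self.e_t - (self.capacity - forgotten_cap))
        n_max = min(self.e_t, forgotten_cap)
        return n_min, n_max

    # -- node evaluation ---------------------------------------------------
    def solve(self) -> float:
        self._eval(self.ntd.root)
        root_table = self.tables[id(self.ntd.root)]
        return root_table.get((self.e_t, ()), INF)

    def _eval(self, node: NTDNode) -> None:
        # iterative post-order to avoid recursion limits on long chains
        stack: List[Tuple[NTDNode, bool]] = [(node, False)]
        while stack:
            n, ready = stack.pop()
            if ready:
                self._eval_one(n)
            else:
                stack.append((n, True))
                for c in n.children:
                    stack.append((c, False))

    def _eval_one(self, n: NTDNode) -> None:
        mult = self.p.mult
        if n.kind == "leaf":
            self.tables[id(n)] = {(0, ()): 0.0}
            self.forgotten_cap[id(n)] = 0
            return
        if n.kind == "join":
            c, d = n.children
            tc, td_ = self.tables[id(c)], self.tables[id(d)]
            fcap = self.forgotten_cap[id(c)] + self.forgotten_cap[id(d)]
            n_min, n_max = self._l_bounds(fcap)
            by_k_d: Dict[Tuple, List[Tuple[int, float]]] = {}
            for (q, k), s in td_.items():
                by_k_d.setdefault(k, []).append((q, s))
            out: Dict = {}
            for (pl, k), s1 in tc.items():
                for q, s2 in by_k_d.get(k, ()):
                    l = pl + q
                    if l < n_min or l > n_max:
                        continue
                    v = s1 + s2
                    cur = out.get((l, k))
                    if cur is None or v < cur:
                        out[(l, k)] = v
            self.tables[id(n)] = out
            self.forgotten_cap[id(n)] = fcap
            self._drop_children(n)
            return
        (c,) = n.children
        tc = self.tables[id(c)]
        if n.kind == "introduce":
            x = n.changed
            pos = n.members.index(x)
            cap = mult(x)
            fcap = self.forgotten_cap[id(c)]
            out = {}
            for (l, k), s in tc.items():
                base = list(k)
                for cnt in range(cap + 1):
                    if l + sum(base) + cnt > self.e_t:
                        break
                    key = tuple(base[:pos] + [cnt] + base[pos:])
                    out[(l, key)] = s
            self.tables[id(n)] = out
            self.forgotten_cap[id(n)] = fcap
            self._drop_children(n)
            return
        if n.kind in ("forget", "root"):
            x = n.changed
            cpos = c.members.index(x)
            fcap = self.forgotten_cap[id(c)] + mult(x)
            n_min, n_max = self._l_bounds(fcap)
            child_index = {m: i for i, m in enumerate(c.members)}
            out = {}
            for (pl, kc), s in tc.items():
                ncnt = kc[cpos]
                l = pl + ncnt
                if l < n_min or l > n_max:
                    continue
                bag_counts = {m: kc[i] for m, i in child_index.items()}
                e = self.member_score(x, bag_counts, ncnt)
                if e == INF:
                    continue
                v = s + e
                key = (l, kc[:cpos] + kc[cpos + 1:])
                cur = out.get(key)
                if cur is None or v < cur:
                    out[key] = v
            self.tables[id(n)] = out
            self.forgotten_cap[id(n)] = fcap
            self._drop_children(n)
            return
        raise MalformedInput(f"unknown node kind {n.kind}")

    def _drop_children(self, n: NTDNode) -> None:
        if not self.keep_tables:
            for c in n.children:
                self.tables.pop(id(c), None)

    keep_tables = False

    # -- backtracking ------------------------------------------------------
    def enumerate(self, cap: int):
        """Yield up to ``cap``+1 arg-min assignments (dicts member -> units)."""
        s_min = self.tables[id(self.ntd.root)].get((self.e_t, ()), INF)
        if s_min == INF:
            return
        yield from self._bt(self.ntd.root, self.e_t, ())

    def _bt(self, n: NTDNode, l: int, k: Tuple):
        target = self.tables[id(n)].get((l, k))
        if target is None:
            return
        if n.kind == "leaf":
            yield {}
            return
        if n.kind == "join":
            c, d = n.children
            tc, td_ = self.tables[id(c)], self.tables[id(d)]
            for (pl, kk), s1 in tc.items():
                if kk != k:
                    continue
                s2 = td_.get((l - pl, k))
                if s2 is None or s1 + s2 != target:
                    continue
                for left in self._bt(c, pl, k):
                    for right in self._bt(d, l - pl, k):
                        merged = dict(left)
                        merged.update(right)
                        yield merged
            return
        (c,) = n.children
        if n.kind == "introduce":
            x = n.changed
            pos = n.members.index(x)
            kc = k[:pos] + k[pos + 1:]
            yield from self._bt(c, l, kc)
            return
        # forget / root
        x = n.changed
        cpos = c.members.index(x)
        child_index = {m: i for i, m in enumerate(c.members)}
        tc = self.tables[id(c)]
        for ncnt in range(self.p.mult(x) + 1):
            pl = l - ncnt
            kc = k[:cpos] + (ncnt,) + k[cpos:]
            s = tc.get((pl, kc))
            if s is None:
                continue
            bag_counts = {m: kc[i] for m, i in child_index.items()}
            e = self.member_score(x, bag_counts, ncnt)
            if e == INF or s + e != target:
                continue
            for sub in self._bt(c, pl, kc):
                out = dict(sub)
                out[x] = ncnt
                yield out


def dp_solve(g: MolecularGraph, p: PositionMultiset, table: ScoreTable,
             ntd: Optional[NiceTreeDecomposition] = None,
             fixed: Optional[Dict] = None) -> float:
    """Minimum assignment score via the tree-decomposition DP."""
    if ntd is None:
        ntd = decompose(g)
    dp = _DP(g, p, table, ntd, fixed)
    return dp.solve()


@dataclass
class ResonanceSet:
    """All (up to a cap) distinct minimum-score assignments of a molecule."""

    structures: List[AssignmentResult]
    truncated: bool
    score: float

    def __len__(self) -> int:
        return len(self.structures)


def _counts_from_member_dict(p: PositionMultiset, by_member: Dict) -> Tuple[int, ...]:
    return tuple(by_member.get(pos, 0) for pos in p.order)


def fpt_search(g: MolecularGraph, p: PositionMultiset, table: ScoreTable,
               ntd: Optional[NiceTreeDecomposition] = None,
               fixed: Optional[Dict] = None) -> AssignmentResult:
    """Optimal assignment (one arg-min structure) via the DP."""
    if ntd is None:
        ntd = decompose(g)
    dp = _DP(g, p, table, ntd, fixed)
    dp.keep_tables = True
    s_min = dp.solve()
    if not math.isfinite(s_min):
        return invalid_result("fpt")
    first = next(dp.enumerate(cap=1))
    asg = ElectronAssignment(p, _counts_from_member_dict(p, first), fixed)
    return result_from_assignment(g, asg, table, algorithm="fpt")


def enumerate_minima(g: MolecularGraph, p: PositionMultiset, table: ScoreTable,
                     ntd: Optional[NiceTreeDecomposition] = None, cap: int = 32,
                     fixed: Optional[Dict] = None) -> ResonanceSet:
    """Up to ``cap`` distinct minimum-score resonance structures."""
    if ntd is None:
        ntd = decompose(g)
    dp = _DP(g, p, table, ntd, fixed)
    dp.keep_tables = True
    s_min = dp.solve()
    if not math.isfinite(s_min):
        raise NoValidAssignment("minimum score is infinite")
    seen: Set[Tuple[int, ...]] = set()
    results: List[AssignmentResult] = []
    truncated = False
    for by_member in dp.enumerate(cap):
        counts = _counts_from_member_dict(p, by_member)
        if counts in seen:
            continue
        seen.add(counts)
        if len(results) >= cap:
            truncated = True
            break
        asg = ElectronAssignment(p, counts, fixed)
        results.append(result_from_assignment(g, asg, table, algorithm="fpt"))
    return ResonanceSet(results, truncated, s_min)
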