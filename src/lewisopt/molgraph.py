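"""Molecular-graph data model and the electron-placement problem setup.

A molecule is represented purely by element types, connectivity and total
charge; coordinates play no role.  Each atom carries a *target valency*
``tau`` — the maximum number of electrons (shared or lone) allowed around it:
2 for hydrogen, 10 for phosphorus and 12 for sulfur when they are involved in
at least three bonds (hypervalent phosphate/sulfate style groups), and the
octet of 8 otherwise.

From the graph we derive the number of electrons whose position must be
optimised,

    e_T = -q_T - 2 * N_B + sum_i nu_i,

where ``q_T`` is the total molecular charge, ``N_B`` the bond count (every
bond keeps a baseline pair, hence the ``-2 N_B``), and ``nu_i`` the valence
electron count of atom *i*.  The legal positions form a multiset over
vertices and edges with multiplicities

    m_v = tau_v - 2 * deg(v),      m_e = min over endpoints of that slack.

Both are always even, so placing electron *pairs* instead of single electrons
(``pair_mode``, the default) is lossless and halves the search depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from .exceptions import (
    InfeasibleMolecule,
    MalformedInput,
    OverSaturatedAtom,
    RadicalNotSupported,
    UnsupportedElement,
)

#: symbol -> (atomic number, valence electron count)
ELEMENTS: Dict[str, Tuple[int, int]] = {
    "H": (1, 1),
    "C": (6, 4),
    "N": (7, 5),
    "O": (8, 6),
    "F": (9, 7),
    "P": (15, 5),
    "S": (16, 6),
    "Cl": (17, 7),
    "Br": (35, 7),
}

SUPPORTED_ELEMENTS = frozenset(ELEMENTS)

Edge = Tuple[int, int]


def canonical_edge(u: int, v: int) -> Edge:
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    atomic_number: int
    valence_electrons: int
    target_valency: int


@dataclass
class MolecularGraph:
    atoms: List[Atom]
    bonds: List[Edge]
    total_charge: int
    _adj: Dict[int, List[int]] = field(default_factory=dict, repr=False)
    _incident: Dict[int, List[Edge]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._adj = {a.index: [] for a in self.atoms}
        self._incident = {a.index: [] for a in self.atoms}
        for (u, v) in self.bonds:
            self._adj[u].append(v)
            self._adj[v].append(u)
            self._incident[u].append((u, v))
            self._incident[v].append((u, v))
        for idx in self._adj:
            self._adj[idx].sort()
            self._incident[idx].sort()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def neighbors(self, v: int) -> List[int]:
        return self._adj[v]

    def incident_edges(self, v: int) -> List[Edge]:
        return self._incident[v]

    def atom(self, v: int) -> Atom:
        return self.atoms[v]

    def is_connected(self) -> bool:
        if not self.atoms:
            return True
        seen = {self.atoms[0].index}
        stack = [self.atoms[0].index]
        while stack:
            for u in self._adj[stack.pop()]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        return len(seen) == self.n_atoms


def _target_valency(element: str, degree: int) -> int:
    if element == "H":
        return 2
    if element == "P" and degree >= 3:
        return 10
    if element == "S" and degree >= 3:
        return 12
    return 8


def build_graph(
    elements: Sequence[str],
    bonds: Iterable[Tuple[int, int]],
    total_charge: int = 0,
) -> MolecularGraph:
    """Validate and assemble a :class:`MolecularGraph`.

    ``elements`` is a sequence of element symbols (index = atom id); ``bonds``
    an iterable of atom-index pairs.  Explicit hydrogens are expected.
    Target valencies are assigned from element and degree (hypervalency rule
    for P/S with three or more bonds).
    """
    n = len(elements)
    seen = set()
    canon: List[Edge] = []
    for (u, v) in bonds:
        if u == v:
            raise MalformedInput(f"self-bond on atom {u}")
        if not (0 <= u < n and 0 <= v < n):
            raise MalformedInput(f"bond ({u},{v}) references a missing atom")
        e = canonical_edge(u, v)
        if e in seen:
            raise MalformedInput(f"duplicate bond {e}")
        seen.add(e)
        canon.append(e)
    canon.sort()

    degree = [0] * n
    for (u, v) in canon:
        degree[u] += 1
        degree[v] += 1

    atoms = []
    for i, sym in enumerate(elements):
        if sym not in ELEMENTS:
            raise UnsupportedElement(f"element {sym!r} (atom {i}) is not supported")
        z, nu = ELEMENTS[sym]
        atoms.append(Atom(i, sym, z, nu, _target_valency(sym, degree[i])))
    return MolecularGraph(atoms, canon, total_charge)


def electron_budget(g: MolecularGraph) -> int:
    """Number of electrons to place: ``e_T = -q_T - 2 N_B + sum(nu_i)``."""
    e_t = -g.total_charge - 2 * g.n_bonds + sum(a.valence_electrons for a in g.atoms)
    if e_t < 0:
        raise InfeasibleMolecule(f"negative electron budget e_T={e_t}")
    if e_t % 2:
        raise RadicalNotSupported(f"odd electron budget e_T={e_t}")
    return e_t


@dataclass
class PositionMultiset:
    """The multiset of occupiable positions and the electron budget.

    ``unit`` is 2 in pair mode (all counts are in electron pairs) and 1
    otherwise.  ``order`` is the deterministic list of distinct positions
    (vertices sorted by index, then edges lexicographically); ``mult`` maps
    each of them to its multiplicity in units.  Positions with multiplicity
    zero are omitted.
    """

    vertex_mult: Dict[int, int]
    edge_mult: Dict[Edge, int]
    e_t: int  # in units
    unit: int  # 1 (electrons) or 2 (pairs)
    order: List = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.order:
            self.order = sorted(self.vertex_mult) + sorted(self.edge_mult)

    def mult(self, pos) -> int:
        if isinstance(pos, tuple):
            return self.edge_mult.get(pos, 0)
        return self.vertex_mult.get(pos, 0)

    @property
    def capacity(self) -> int:
        return sum(self.vertex_mult.values()) + sum(self.edge_mult.values())

    def __len__(self) -> int:
        return len(self.order)


def positions(g: MolecularGraph, pair_mode: bool = True) -> PositionMultiset:
    """Build the position multiset (and budget) for ``g``.

    Raises :class:`OverSaturatedAtom` if any atom's sigma framework already
    exceeds its target valency, and :class:`InfeasibleMolecule` if the total
    capacity cannot accommodate the electron budget.
    """
    e_t = electron_budget(g)
    unit = 2 if pair_mode else 1
    vmult: Dict[int, int] = {}
    for a in g.atoms:
        m = a.target_valency - 2 * g.degree(a.index)
        if m < 0:
            raise OverSaturatedAtom(
                f"atom {a.index} ({a.element}): degree {g.degree(a.index)} "
                f"exceeds target valency {a.target_valency}"
            )
        if m > 0:
            vmult[a.index] = m // unit
    emult: Dict[Edge, int] = {}
    for (u, v) in g.bonds:
        slack_u = g.atom(u).target_valency - 2 * g.degree(u)
        slack_v = g.atom(v).target_valency - 2 * g.degree(v)
        m = min(slack_u, slack_v)
        if m > 0:
            emult[(u, v)] = m // unit
    p = PositionMultiset(vmult, emult, e_t // unit, unit)
    if p.capacity < p.e_t:
        raise InfeasibleMolecule(
            f"capacity {p.capacity} units cannot hold e_T={p.e_t} units"
        )
    return p


#: pre-placement rules: element -> (required degree, pairs to place)
_PREPLACE_PAIRS = {"F": 3, "Cl": 3, "Br": 3, "O": 2, "S": 2}


def preplace(g: MolecularGraph, p: PositionMultiset):
    """Pre-place chemically certain lone pairs, shrinking the search space.

    Terminal halogens receive three lone pairs; terminal O/S under the octet
    rule receive two.  Returns ``(fixed, reduced, warned)`` where ``fixed``
    maps positions to pre-placed units, ``reduced`` is the equivalent reduced
    problem and ``warned`` signals a fallback to no pre-placement (when the
    rules would overrun the budget).  Any optimum of the reduced problem plus
    ``fixed`` is an optimum of the full problem restricted to assignments
    honouring the pre-placement.
    """
    fixed: Dict[int, int] = {}
    for a in g.atoms:
        if g.degree(a.index) != 1:
            continue
        pairs = _PREPLACE_PAIRS.get(a.element)
        if pairs is None:
            continue
        if a.element in ("O", "S") and a.target_valency != 8:
            continue
        units = pairs * 2 // p.unit
        if p.mult(a.index) >= units:
            fixed[a.index] = units
    total = sum(fixed.values())
    if total > p.e_t:
        return {}, p, True
    vmult = dict(p.vertex_mult)
    for v, units in fixed.items():
        vmult[v] -= units
        if vmult[v] == 0:
            del vmult[v]
    reduced = PositionMultiset(vmult, dict(p.edge_mult), p.e_t - total, p.unit)
    return fixed, reduced, False
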