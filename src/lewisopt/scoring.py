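"""Electron-assignment scoring: 32-bit keys, score tables, charges and orders.

The score of an assignment is a sum over all graph members (atoms and bonds)
of values looked up in a table keyed by a 32-bit unsigned integer:

* atom key — bits 1-7 (LSB-first) hold the atomic number, bits 8-11 the
  magnitude of the formal charge, bit 12 is set for a negative charge;
* bond key — bits 1-7 and 8-14 hold the two atomic numbers (ascending, so
  the key is symmetric), bits 15-18 the total electron count on the bond.

A missing key scores +inf, and an atom whose valence exceeds its target
valency scores +inf regardless of the table.  Bond electron counts are
*baseline-inclusive*: every bond owns two electrons before any surplus is
placed, so a bond carrying a surplus of 2 is a double bond (order =
total/2).  Formal charges follow

    F(v) = nu_v - c_p[v] - sum over incident bonds of total/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator, Optional, Tuple

from .exceptions import InvalidBondState, KeyOverflow, ParseError, UnsupportedElement
from .molgraph import ELEMENTS, Edge, MolecularGraph, PositionMultiset

INF = math.inf

_Z_TO_SYMBOL = {z: sym for sym, (z, _) in ELEMENTS.items()}


# ---------------------------------------------------------------------------
# keys
# ---------------------------------------------------------------------------

def vertex_key(atomic_number: int, formal_charge: int) -> int:
    """32-bit key for an atom in a given formal-charge state."""
    if not 1 <= atomic_number < 128:
        raise KeyOverflow(f"atomic number {atomic_number} outside 7-bit range")
    mag = abs(formal_charge)
    if mag >= 16:
        raise KeyOverflow(f"|formal charge| {mag} >= 16")
    key = atomic_number | (mag << 7)
    if formal_charge < 0:
        key |= 1 << 11
    return key


def edge_key(z_a: int, z_b: int, total_electrons: int) -> int:
    """32-bit key for a bond; element order is canonicalized (ascending Z)."""
    if not (1 <= z_a < 128 and 1 <= z_b < 128):
        raise KeyOverflow("atomic number outside 7-bit range")
    if total_electrons < 2:
        raise InvalidBondState(f"bond with {total_electrons} electrons")
    if total_electrons % 2 or total_electrons >= 16:
        raise InvalidBondState(f"unrepresentable bond electron count {total_electrons}")
    lo, hi = (z_a, z_b) if z_a <= z_b else (z_b, z_a)
    return lo | (hi << 7) | (total_electrons << 14)


# ---------------------------------------------------------------------------
# score table
# ---------------------------------------------------------------------------

@dataclass
class ScoreTable:
    """Lookup table from 32-bit keys to scores; missing keys score +inf."""

    entries: Dict[int, float] = field(default_factory=dict)
    provenance: str = "unspecified"
    swap_c0_cminus: bool = False

    def get(self, key: int) -> float:
        return self.entries.get(key, INF)

    def __len__(self) -> int:
        return len(self.entries)

    def atom_score(self, z: int, fc: int) -> float:
        try:
            return self.get(vertex_key(z, fc))
        except KeyOverflow:
            return INF

    def bond_score(self, z_a: int, z_b: int, total_electrons: int) -> float:
        try:
            return self.get(edge_key(z_a, z_b, total_electrons))
        except (KeyOverflow, InvalidBondState):
            return INF


def _apply_swap(entries: Dict[int, float]) -> None:
    """Exchange the scores of the C(0) and C(-1) atom keys in place."""
    k0 = vertex_key(6, 0)
    km = vertex_key(6, -1)
    if k0 in entries and km in entries:
        entries[k0], entries[km] = entries[km], entries[k0]


def load_score_table(path, swap_c0_cminus: bool = True) -> ScoreTable:
    """Read a score table from the documented text format.

    Lines are ``ATOM <symbol> <charge> <score>`` or
    ``BOND <symbol> <symbol> <electrons> <score>``; ``#`` starts a comment.
    With ``swap_c0_cminus`` the neutral-carbon and anionic-carbon scores are
    exchanged at load time (makes neutral carbon strictly preferable).
    """
    entries: Dict[int, float] = {}
    provenance = str(path)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            try:
                if parts[0] == "ATOM" and len(parts) == 4:
                    sym, charge, score = parts[1], int(parts[2]), float(parts[3])
                    if sym not in ELEMENTS:
                        raise UnsupportedElement(sym)
                    key = vertex_key(ELEMENTS[sym][0], charge)
                elif parts[0] == "BOND" and len(parts) == 5:
                    sa, sb = parts[1], parts[2]
                    electrons, score = int(parts[3]), float(parts[4])
                    if sa not in ELEMENTS or sb not in ELEMENTS:
                        raise UnsupportedElement(f"{sa}/{sb}")
                    key = edge_key(ELEMENTS[sa][0], ELEMENTS[sb][0], electrons)
                else:
                    raise ValueError(f"unrecognised record {parts[0]!r}")
            except (ValueError, IndexError, UnsupportedElement, KeyOverflow,
                    InvalidBondState) as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if not math.isfinite(score):
                raise ParseError("stored scores must be finite", line=lineno)
            entries[key] = score
    if swap_c0_cminus:
        _apply_swap(entries)
    return ScoreTable(entries, provenance, swap_c0_cminus)


def write_score_table(table: ScoreTable, path) -> None:
    """Write ``table`` in the text format read by :func:`load_score_table`.

    The swap is undone on write so that a write -> load round trip (with the
    same swap setting) reproduces the in-memory entries.
    """
    entries = dict(table.entries)
    if table.swap_c0_cminus:
        _apply_swap(entries)  # swap is an involution
    atom_lines = []
    bond_lines = []
    for key, score in entries.items():
        if key < (1 << 14):
            z = key & 0x7F
            mag = (key >> 7) & 0xF
            fc = -mag if key & (1 << 11) else mag
            atom_lines.append((z, fc, score))
        else:
            lo = key & 0x7F
            hi = (key >> 7) & 0x7F
            ne = (key >> 14) & 0xF
            bond_lines.append((lo, hi, ne, score))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# lewisopt score table ({table.provenance})\n")
        for z, fc, score in sorted(atom_lines):
            fh.write(f"ATOM {_Z_TO_SYMBOL[z]} {fc} {score!r}\n")
        for lo, hi, ne, score in sorted(bond_lines):
            fh.write(f"BOND {_Z_TO_SYMBOL[lo]} {_Z_TO_SYMBOL[hi]} {ne} {score!r}\n")


def default_table(swap_c0_cminus: bool = True) -> ScoreTable:
    """The packaged surrogate score table (approximate energies, eV)."""
    ref = resources.files("lewisopt.data").joinpath("default_scores.tab")
    with resources.as_file(ref) as path:
        table = load_score_table(path, swap_c0_cminus=swap_c0_cminus)
    table.provenance = "packaged surrogate (synthetic, eV)"
    return table


# ---------------------------------------------------------------------------
# electron assignments
# ---------------------------------------------------------------------------

class ElectronAssignment:
    """Counts of surplus electrons placed on positions, in multiset units.

    ``counts`` is aligned with ``multiset.order``; ``fixed`` holds pre-placed
    units merged into every query.  ``electrons_on`` reports electron units;
    ``edge_total`` additionally includes a bond's baseline pair.
    """

    __slots__ = ("multiset", "counts", "fixed", "_placed")

    def __init__(self, multiset: PositionMultiset, counts: Tuple[int, ...],
                 fixed: Optional[Dict] = None):
        self.multiset = multiset
        self.counts = tuple(counts)
        self.fixed = fixed or {}
        placed: Dict = dict(self.fixed)
        for pos, n in zip(multiset.order, self.counts):
            if n:
                placed[pos] = placed.get(pos, 0) + n
        self._placed = placed

    def units_on(self, pos) -> int:
        return self._placed.get(pos, 0)

    def electrons_on(self, pos) -> int:
        return self._placed.get(pos, 0) * self.multiset.unit

    def edge_total(self, e: Edge) -> int:
        """Baseline-inclusive electron count of a bond."""
        return 2 + self.electrons_on(e)

    @property
    def total_units(self) -> int:
        return sum(self._placed.values())

    @property
    def complete(self) -> bool:
        return sum(self.counts) == self.multiset.e_t

    def positions(self) -> Iterator:
        return iter(self._placed)

    def __eq__(self, other) -> bool:
        return (isinstance(other, ElectronAssignment)
                and self.counts == other.counts
                and self.fixed == other.fixed)

    def __hash__(self) -> int:
        return hash(self.counts)

    def __repr__(self) -> str:
        placed = {p: n for p, n in self._placed.items() if n}
        return f"ElectronAssignment({placed}, unit={self.multiset.unit})"


def formal_charge(g: MolecularGraph, assignment: ElectronAssignment, v: int) -> float:
    """F(v) = nu_v - electrons on v - half the electrons of incident bonds."""
    atom = g.atom(v)
    half_bonds = sum(assignment.edge_total(e) for e in g.incident_edges(v)) / 2
    return atom.valence_electrons - assignment.electrons_on(v) - half_bonds


def valence(g: MolecularGraph, assignment: ElectronAssignment, v: int) -> int:
    """Total electron count around ``v`` (lone + baseline-inclusive bonds)."""
    return assignment.electrons_on(v) + sum(
        assignment.edge_total(e) for e in g.incident_edges(v)
    )


def bond_order(assignment: ElectronAssignment, e: Edge) -> int:
    """O(e) = total electrons on the bond / 2; always >= 1."""
    return assignment.edge_total(e) // 2


def vertex_score(g: MolecularGraph, assignment: ElectronAssignment,
                 table: ScoreTable, v: int) -> float:
    """Score of one atom: +inf when over-valent or charge state unknown."""
    atom = g.atom(v)
    if valence(g, assignment, v) > atom.target_valency:
        return INF
    fc = formal_charge(g, assignment, v)
    if fc != int(fc):
        return INF  # half-integer charge (odd bond electrons): not tabulated
    return table.atom_score(atom.atomic_number, int(fc))


def edge_score(g: MolecularGraph, assignment: ElectronAssignment,
               table: ScoreTable, e: Edge) -> float:
    total = assignment.edge_total(e)
    return table.bond_score(g.atom(e[0]).atomic_number,
                            g.atom(e[1]).atomic_number, total)


def assignment_score(g: MolecularGraph, assignment: ElectronAssignment,
                     table: ScoreTable) -> float:
    """Total score: sum of atom and bond scores (+inf absorbs everything)."""
    total = 0.0
    for a in g.atoms:
        s = vertex_score(g, assignment, table, a.index)
        if s == INF:
            return INF
        total += s
    for e in g.bonds:
        s = edge_score(g, assignment, table, e)
        if s == INF:
            return INF
        total += s
    return total


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    """Kekulized bond orders, atomic formal charges and the achieved score."""

    formal_charges: Dict[int, int]
    bond_orders: Dict[Edge, int]
    score: float
    algorithm: str = ""
    assignment: Optional[ElectronAssignment] = None
    timed_out: bool = False

    @property
    def valid(self) -> bool:
        return math.isfinite(self.score)


def result_from_assignment(g: MolecularGraph, assignment: ElectronAssignment,
                           table: ScoreTable, algorithm: str = "",
                           timed_out: bool = False) -> AssignmentResult:
    score = assignment_score(g, assignment, table)
    charges = {a.index: int(formal_charge(g, assignment, a.index))
               for a in g.atoms} if math.isfinite(score) else {}
    orders = {e: bond_order(assignment, e) for e in g.bonds} \
        if math.isfinite(score) else {}
    return AssignmentResult(charges, orders, score, algorithm, assignment,
                            timed_out)


def invalid_result(algorithm: str = "") -> AssignmentResult:
    return AssignmentResult({}, {}, INF, algorithm, None)
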