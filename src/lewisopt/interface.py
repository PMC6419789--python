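"""Structure-file I/O, dataset filtering, synthetic molecules, run config.

Reading goes through RDKit: SDF/MOL, MOL2, SMILES (hydrogens expanded) and
PDB-with-CONECT are accepted.  Only element types, connectivity and charges
are extracted — input bond orders are deliberately discarded, since the whole
point of the optimiser is to reconstruct them from connectivity and total
charge alone (input orders/charges remain available for validation).
Disconnected records are split into one problem per component, with each
component's charge taken from the per-atom formal charges of the record.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import yaml

from .exceptions import LewisoptError, MalformedInput
from .molgraph import (
    ELEMENTS,
    SUPPORTED_ELEMENTS,
    MolecularGraph,
    build_graph,
    positions,
)
from .opt_fpt import ResonanceSet
from .scoring import AssignmentResult

logger = logging.getLogger("lewisopt")

_rdkit_logged = False


def _rdkit():
    from rdkit import Chem, RDLogger

    global _rdkit_logged
    if not _rdkit_logged:
        RDLogger.DisableLog("rdApp.*")
        _rdkit_logged = True
    return Chem


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Algorithm selection and the operational limits of a run."""

    algorithm: str = "fpt"  # local | astar | fpt
    pair_mode: bool = True
    preplace: bool = False
    local_timeout_s: float = 5.0
    astar_memory_mb: float = 1024.0
    max_resonance: int = 32
    swap_c0_cminus: bool = True
    score_table_path: Optional[str] = None
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("local", "astar", "fpt"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.local_timeout_s <= 0 or self.max_resonance <= 0:
            raise ValueError("limits must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

@dataclass
class ParsedMolecule:
    """A raw record component before graph validation."""

    elements: List[str]
    bonds: List[Tuple[int, int]]
    total_charge: int
    provenance: str
    #: reference data carried along for validation only (never optimised on)
    ref_bond_orders: Dict[Tuple[int, int], int] = field(default_factory=dict)
    ref_formal_charges: Dict[int, int] = field(default_factory=dict)

    def heavy_atom_count(self) -> int:
        return sum(1 for e in self.elements if e != "H")

    def to_graph(self) -> MolecularGraph:
        return build_graph(self.elements, self.bonds, self.total_charge)


def _from_rdkit(mol, provenance: str) -> List[ParsedMolecule]:
    """Split an RDKit mol into connected components, one problem each."""
    Chem = _rdkit()
    frags = Chem.GetMolFrags(mol)
    out = []
    for frag_idx, atom_ids in enumerate(frags):
        remap = {a: i for i, a in enumerate(atom_ids)}
        elements = []
        charges = {}
        for a in atom_ids:
            atom = mol.GetAtomWithIdx(a)
            elements.append(atom.GetSymbol() if atom.GetAtomicNum() else "*")
            charges[remap[a]] = atom.GetFormalCharge()
        bonds = []
        orders = {}
        for b in mol.GetBonds():
            u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if u in remap and v in remap:
                e = tuple(sorted((remap[u], remap[v])))
                bonds.append(e)
                orders[e] = max(1, int(b.GetBondTypeAsDouble()))
        name = provenance if len(frags) == 1 else f"{provenance}#frag{frag_idx}"
        out.append(ParsedMolecule(elements, bonds, sum(charges.values()),
                                  name, orders, charges))
    return out


def read_molecules(path, fmt: Optional[str] = None) -> List[ParsedMolecule]:
    """Read molecules from SDF/MOL, MOL2, SMILES or PDB into parsed records.

    Explicit hydrogens are ensured (SMILES are expanded via standard valence
    rules); unparseable records are skipped with a logged reason; a record
    without charge information defaults to total charge 0.
    """
    Chem = _rdkit()
    path = Path(path)
    if fmt is None:
        fmt = {".sdf": "sdf", ".mol": "sdf", ".mol2": "mol2",
               ".smi": "smiles", ".smiles": "smiles", ".pdb": "pdb"}.get(
                   path.suffix.lower())
        if fmt is None:
            raise MalformedInput(f"cannot infer format of {path}")
    out: List[ParsedMolecule] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("%s record %d: unparseable, skipped", path, i)
                continue
            out.extend(_from_rdkit(mol, f"{path.name}:{i}"))
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
        if mol is None:
            logger.warning("%s: unparseable MOL2, skipped", path)
        else:
            out.extend(_from_rdkit(mol, path.name))
    elif fmt == "smiles":
        with open(path) as fh:
            for i, line in enumerate(fh):
                smi = line.strip().split()[0] if line.strip() else ""
                if not smi:
                    continue
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    logger.warning("%s line %d: bad SMILES %r", path, i + 1, smi)
                    continue
                mol = Chem.AddHs(mol)
                out.extend(_from_rdkit(mol, f"{path.name}:{i}"))
    elif fmt == "pdb":
        mol = Chem.MolFromPDBFile(str(path), sanitize=False, removeHs=False)
        if mol is None:
            logger.warning("%s: unparseable PDB, skipped", path)
        else:
            out.extend(_from_rdkit(mol, path.name))
    else:
        raise MalformedInput(f"unsupported format {fmt!r}")
    return out


def parse_smiles(smiles: str, provenance: str = "smiles") -> ParsedMolecule:
    """Convenience: one SMILES string -> one parsed record (must be connected)."""
    Chem = _rdkit()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MalformedInput(f"bad SMILES {smiles!r}")
    parts = _from_rdkit(Chem.AddHs(mol), provenance)
    if len(parts) != 1:
        raise MalformedInput("SMILES describes a disconnected species")
    return parts[0]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

DISPOSITIONS = ("kept", "dangling_bonds", "too_small", "unsupported_element",
                "odd_electrons", "duplicate")


@dataclass
class FilterReport:
    dispositions: List[str]
    kept: List[MolecularGraph]
    counts: Dict[str, int]


def _connectivity_graph(elements: Sequence[str],
                        bonds: Iterable[Tuple[int, int]]) -> nx.Graph:
    gx = nx.Graph()
    for i, e in enumerate(elements):
        gx.add_node(i, element=e)
    gx.add_edges_from(bonds)
    return gx


def _canonical_hash(elements, bonds) -> str:
    gx = _connectivity_graph(elements, bonds)
    return nx.weisfeiler_lehman_graph_hash(gx, node_attr="element", iterations=4)


def filter_dataset(molecules: Sequence[ParsedMolecule]) -> FilterReport:
    """Apply the reference-dataset screening rules, in order.

    Discards molecules with dangling bonds (dummy attachment atoms), with
    three or fewer heavy atoms, with unsupported elements, with an odd
    number of valence electrons, or identical (element-labelled
    connectivity) to an earlier kept molecule.
    """
    dispositions: List[str] = []
    kept: List[MolecularGraph] = []
    seen: Dict[str, List[Tuple[nx.Graph, Sequence[str]]]] = {}
    for pm in molecules:
        if any(e == "*" or not e for e in pm.elements):
            dispositions.append("dangling_bonds")
            continue
        if pm.heavy_atom_count() <= 3:
            dispositions.append("too_small")
            continue
        if any(e not in SUPPORTED_ELEMENTS for e in pm.elements):
            dispositions.append("unsupported_element")
            continue
        n_val = sum(ELEMENTS[e][1] for e in pm.elements) - pm.total_charge
        if n_val % 2:
            dispositions.append("odd_electrons")
            continue
        h = _canonical_hash(pm.elements, pm.bonds)
        gx = _connectivity_graph(pm.elements, pm.bonds)
        dup = False
        for other, _ in seen.get(h, ()):
            if nx.is_isomorphic(gx, other,
                                node_match=lambda a, b: a["element"] == b["element"]):
                dup = True
                break
        if dup:
            dispositions.append("duplicate")
            continue
        seen.setdefault(h, []).append((gx, pm.elements))
        kept.append(pm.to_graph())
        dispositions.append("kept")
    counts = {d: dispositions.count(d) for d in DISPOSITIONS}
    return FilterReport(dispositions, kept, counts)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _to_rdkit(g: MolecularGraph, result: AssignmentResult):
    Chem = _rdkit()
    bond_types = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                  3: Chem.BondType.TRIPLE}
    rw = Chem.RWMol()
    for a in g.atoms:
        atom = Chem.Atom(a.atomic_number)
        atom.SetFormalCharge(int(result.formal_charges.get(a.index, 0)))
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for e in g.bonds:
        rw.AddBond(e[0], e[1], bond_types.get(result.bond_orders.get(e, 1),
                                              Chem.BondType.SINGLE))
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    return mol


def result_report(g: MolecularGraph, result) -> Dict:
    """JSON-serialisable report for a result or resonance set."""
    if isinstance(result, ResonanceSet):
        structures = result.structures
        extra = {"resonance_count": len(result), "truncated": result.truncated}
        score = result.score
        algorithm = structures[0].algorithm if structures else "fpt"
    else:
        structures = [result]
        extra = {"resonance_count": 1, "truncated": False}
        score = result.score
        algorithm = result.algorithm
    if not structures or score == float("inf"):
        return {"status": "no_valid_assignment", "algorithm": algorithm}
    rep = {
        "status": "ok",
        "algorithm": algorithm,
        "score": score,
        "total_charge": g.total_charge,
        "formal_charges": [structures[0].formal_charges[a.index]
                           for a in g.atoms],
        "bond_orders": {f"{e[0]}-{e[1]}": structures[0].bond_orders[e]
                        for e in g.bonds},
    }
    rep.update(extra)
    return rep


def write_result(g: MolecularGraph, result, path, fmt: str = "sdf") -> None:
    """Write an assignment (or resonance set) as SDF or a JSON report."""
    Chem = _rdkit()
    structures = result.structures if isinstance(result, ResonanceSet) \
        else [result]
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(result_report(g, result), fh, indent=2)
        return
    if fmt != "sdf":
        raise MalformedInput(f"unsupported output format {fmt!r}")
    finite = [r for r in structures if r.valid]
    if not finite:
        raise MalformedInput("no valid assignment to write (score is infinite)")
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for r in finite:
        writer.write(_to_rdkit(g, r))
    writer.close()


# ---------------------------------------------------------------------------
# synthetic molecules
# ---------------------------------------------------------------------------

#: conventional single-bond connection capacity used by the generator
_CONNECTIVITY_CAP = {"C": 4, "N": 3, "O": 2, "S": 3, "P": 3,
                     "F": 1, "Cl": 1, "Br": 1}
_DEFAULT_WEIGHTS = {"C": 0.50, "N": 0.14, "O": 0.16, "S": 0.06, "P": 0.03,
                    "F": 0.05, "Cl": 0.04, "Br": 0.02}


def generate_synthetic(n_molecules: int, max_heavy_atoms: int = 10,
                       element_weights: Optional[Dict[str, float]] = None,
                       seed: int = 0,
                       max_pair_slots: Optional[int] = None,
                       ring_probability: float = 0.3
                       ) -> List[MolecularGraph]:
    """Seeded, reproducible random molecules for testing and benchmarks.

    Molecules are random connected heavy-atom trees with occasional
    ring-closing edges, degrees capped by conventional valences, hydrogens
    filled to a plausible (possibly unsaturated) count, and charge drawn
    from {-1, 0, +1} so the placeable-electron count is even.  Every output
    is guaranteed to pass :func:`filter_dataset`; ``max_pair_slots`` limits
    the multiset capacity (in pairs) for exhaustive-oracle suites.
    """
    if max_heavy_atoms < 4:
        raise ValueError("need at least 4 heavy atoms to pass the size filter")
    weights = element_weights or _DEFAULT_WEIGHTS
    symbols = sorted(weights)
    wvals = [weights[s] for s in symbols]
    rng = random.Random(seed)
    out: List[MolecularGraph] = []
    hashes: set = set()
    attempts = 0
    while len(out) < n_molecules:
        attempts += 1
        if attempts > 200 * n_molecules + 1000:
            raise LewisoptError("synthetic generator failed to converge")
        n_heavy = rng.randint(4, max_heavy_atoms)
        elements = rng.choices(symbols, weights=wvals, k=n_heavy)
        caps = [_CONNECTIVITY_CAP[e] for e in elements]
        deg = [0] * n_heavy
        bonds = []
        ok = True
        for i in range(1, n_heavy):
            anchors = [j for j in range(i) if deg[j] < caps[j]]
            if not anchors:
                ok = False
                break
            j = rng.choice(anchors)
            bonds.append((j, i))
            deg[j] += 1
            deg[i] += 1
        if not ok:
            continue
        if n_heavy >= 4 and rng.random() < ring_probability:
            existing = {tuple(sorted(b)) for b in bonds}
            cands = [(a, b) for a in range(n_heavy) for b in range(a + 1, n_heavy)
                     if deg[a] < caps[a] and deg[b] < caps[b]
                     and (a, b) not in existing]
            if cands:
                a, b = rng.choice(cands)
                bonds.append((a, b))
                deg[a] += 1
                deg[b] += 1
        # hydrogen filling with occasional unsaturation
        all_elements = list(elements)
        for i in range(n_heavy):
            free = caps[i] - deg[i]
            if free > 0:
                unsat = rng.choices([0, 1, 2], weights=[0.55, 0.30, 0.15])[0]
                n_h = max(0, free - unsat)
                for _ in range(n_h):
                    h = len(all_elements)
                    all_elements.append("H")
                    bonds.append((i, h))
                    deg[i] += 1
        n_val = sum(ELEMENTS[e][1] for e in all_elements)
        charge = 0 if n_val % 2 == 0 else rng.choice([-1, 1])
        try:
            g = build_graph(all_elements, bonds, charge)
            p = positions(g, pair_mode=True)
        except LewisoptError:
            continue
        if max_pair_slots is not None and p.capacity > max_pair_slots:
            continue
        h = _canonical_hash(all_elements, g.bonds)
        if h in hashes:
            continue
        hashes.add(h)
        out.append(g)
    return out
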