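# lewisopt

Simultaneous assignment of **bond orders** and **formal charges** from
nothing but element types, connectivity and the total molecular charge.

Many cheminformatics and molecular-simulation pipelines start from structure
files that carry no reliable bond orders or atomic charges (2D databases,
PDB ligands, machine-generated topologies). `lewisopt` treats the problem as
electron placement on the molecular graph: the combination of connectivity
and total charge fixes the protonation state, and an optimal arrangement of
the remaining valence electrons *is* a Lewis structure, from which kekulized
bond orders and integer formal charges are read off directly. No 3D
coordinates are used.

## The model

For a molecular graph G = (V, E) with total charge q_T, the number of
electrons to place is

    e_T = -q_T - 2·N_B + Σᵢ νᵢ

(νᵢ = valence electrons of atom i; each of the N_B bonds keeps a baseline
pair). Electrons may sit on atom v or bond e = (u, v) up to the
multiplicities

    m_v = τ_v - 2·deg(v),    m_e = min(τ_u - 2·deg(u), τ_v - 2·deg(v)),

where τ is the target valency: 2 for H, 10/12 for P/S with ≥ 3 bonds
(hypervalent phosphate/sulfate representations), 8 otherwise. An electron
assignment c_p : V ∪ E → ℤ₊ is scored as

    S = Σ_{x ∈ V∪E} Γ[k_x],

with Γ a lookup table keyed by 32-bit integers encoding (element, formal
charge) for atoms and (element pair, electron count) for bonds; missing keys
and over-valent atoms score +∞. Formal charge and bond order follow from the
optimal assignment:

    F(v) = ν_v - c_p[v] - Σ_u c_p[(u,v)]/2,    O(e) = c_p[e]/2.

Three optimizers minimise S:

* **`local`** — greedy steepest descent over single-electron(-pair) moves;
  very fast, not guaranteed optimal; 5 s wall-clock guard.
* **`astar`** — exact A* over the assignment tree with an admissible
  per-member lower-bound heuristic and a 1024 MB queue memory cap.
* **`fpt`** (default) — exact dynamic programming over a *nice tree
  decomposition* of the molecular graph (GreedyFillIn elimination), fixed-
  parameter tractable in the treewidth; also enumerates **all minimum-score
  resonance structures** (capped at 32).

Scores ship as a packaged *surrogate* table (approximate ionization /
electron-affinity and bond-dissociation energies, eV); any user table in the
documented text format can be substituted. By default the neutral-carbon and
anionic-carbon scores are swapped so neutral carbon is always preferred.

## Worked example

```python
from lewisopt import build_graph, default_table, assign, resonance_structures

table = default_table()
acetate = build_graph(["C", "C", "O", "O", "H", "H", "H"],
                      [(0, 1), (1, 2), (1, 3), (0, 4), (0, 5), (0, 6)], -1)
rs = resonance_structures(acetate, table)
print(len(rs), rs.score)
for r in rs.structures:
    print(r.bond_orders[(1, 2)], r.bond_orders[(1, 3)], r.formal_charges)
```

prints

```
2 11.984375
1 2 {0: 0, 1: 0, 2: -1, 3: 0, 4: 0, 5: 0, 6: 0}
2 1 {0: 0, 1: 0, 2: 0, 3: -1, 4: 0, 5: 0, 6: 0}
```

— the two mirror-image carboxylate structures: one C–O double bond and one
single bond to an O⁻, tied at the minimum score 11.98 (eV, surrogate table).
Likewise `assign(...)` on ethyne yields a C≡C triple bond, benzene yields
its two kekulé ring patterns, and sulfate yields a neutral hypervalent
sulfur (τ = 12) with two S=O double bonds and two O⁻.

More narrative scripts live in `examples/` (basic assignment, resonance
enumeration, optimizer consistency, dataset filtering); the `lewisopt` CLI
exposes the same operations (`assign`, `consistency`, `filter`, `synth`).

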