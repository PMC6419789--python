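"""Enumerate all minimum-score resonance structures of delocalised ions.

Acetate's two C-O bonds are equivalent, so two mirror-image assignments tie
at the minimum; benzene has its two kekule ring patterns; sulfate (with
hypervalent sulfur, target valency 12) has six ways to pick the two S=O
double bonds.
"""

from lewisopt import build_graph, default_table, resonance_structures

table = default_table()

acetate = build_graph(["C", "C", "O", "O", "H", "H", "H"],
                      [(0, 1), (1, 2), (1, 3), (0, 4), (0, 5), (0, 6)], -1)
benzene = build_graph(["C"] * 6 + ["H"] * 6,
                      [(i, (i + 1) % 6) for i in range(6)]
                      + [(i, 6 + i) for i in range(6)], 0)
sulfate = build_graph(["S", "O", "O", "O", "O"],
                      [(0, 1), (0, 2), (0, 3), (0, 4)], -2)

for name, g in [("acetate", acetate), ("benzene", benzene),
                ("sulfate", sulfate)]:
    rs = resonance_structures(g, table)  # capped at 32 structures
    print(f"{name}: {len(rs)} resonance structure(s) at score "
          f"{rs.score:.4f}{' (truncated)' if rs.truncated else ''}")
    for r in rs.structures[:6]:
        charged = {i: c for i, c in r.formal_charges.items() if c}
        print(f"   orders={list(r.bond_orders.values())} charges={charged}")

print()
print("Every structure shown scores exactly the minimum; they differ only")
print("in where the double bonds / charged atoms sit (the delocalisation).")
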