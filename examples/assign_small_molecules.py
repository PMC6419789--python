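"""Assign bond orders and formal charges to a few textbook molecules.

Each molecule is given only as elements + connectivity + total charge; the
optimizer places the remaining valence electrons and reads the Lewis
structure off the optimum.
"""

from lewisopt import assign, build_graph, default_table

table = default_table()

molecules = {
    "water": build_graph(["O", "H", "H"], [(0, 1), (0, 2)], 0),
    "ethene": build_graph(["C", "C", "H", "H", "H", "H"],
                          [(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)], 0),
    "ethyne": build_graph(["C", "C", "H", "H"], [(0, 1), (0, 2), (1, 3)], 0),
    "hydroxide": build_graph(["O", "H"], [(0, 1)], -1),
}

for name, g in molecules.items():
    r = assign(g, table)  # exact tree-decomposition solver by default
    charged = {i: c for i, c in r.formal_charges.items() if c}
    print(f"{name:10s} score={r.score:8.4f}  "
          f"orders={sorted(r.bond_orders.values())}  charges={charged or 'none'}")

print()
print("The score is the summed table energy (eV) of the optimal electron")
print("placement; 'orders' lists each bond's kekulized order (2 = double,")
print("3 = triple) and 'charges' any nonzero atomic formal charges --")
print("e.g. hydroxide carries its -1 on the oxygen.")
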