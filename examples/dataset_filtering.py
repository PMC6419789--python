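"""Screen a small mixed dataset with the reference filtering rules.

Molecules are discarded when they carry dangling bonds, have three or fewer
heavy atoms, contain elements outside the score tables, have an odd number
of valence electrons, or duplicate an earlier entry.
"""

from lewisopt import filter_dataset, parse_smiles
from lewisopt.interface import ParsedMolecule

dataset = [
    parse_smiles("CCCO", "1-propanol"),
    parse_smiles("OCCC", "1-propanol again"),     # duplicate
    parse_smiles("CCO", "ethanol"),               # only 3 heavy atoms
    parse_smiles("CCC[O]", "propoxy radical"),    # odd electron count
    ParsedMolecule(["*", "C", "C", "C", "C"],
                   [(0, 1), (1, 2), (2, 3), (3, 4)], 0, "monomer unit"),
    parse_smiles("c1ccccc1C(=O)[O-]", "benzoate"),
]

report = filter_dataset(dataset)
for pm, disposition in zip(dataset, report.dispositions):
    print(f"{pm.provenance:18s} -> {disposition}")
print()
print("counts:", {k: v for k, v in report.counts.items() if v})
print(f"{len(report.kept)} molecule(s) kept and converted to molecular graphs")
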