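import json
import math

import pytest
from click.testing import CliRunner

from lewisopt import (
    assign,
    build_graph,
    filter_dataset,
    generate_synthetic,
    parse_smiles,
    positions,
    read_molecules,
    resonance_structures,
    write_result,
)
from lewisopt.cli import main
from lewisopt.interface import ParsedMolecule, RunConfig, result_report
from lewisopt.scoring import AssignmentResult


class TestReading:
    def test_smiles_water(self):
        pm = parse_smiles("O")
        assert sorted(pm.elements) == ["H", "H", "O"]
        assert pm.total_charge == 0 and len(pm.bonds) == 2

    def test_smiles_charge(self):
        pm = parse_smiles("[O-]C(=O)C")  # acetate
        assert pm.total_charge == -1
        assert pm.heavy_atom_count() == 4

    def test_sdf_round_trip(self, acetate, table, tmp_path):
        r = assign(acetate, table)
        path = tmp_path / "acetate.sdf"
        write_result(acetate, r, path, fmt="sdf")
        back = read_molecules(path)
        assert len(back) == 1
        pm = back[0]
        assert pm.total_charge == -1
        assert sorted(pm.elements) == sorted(a.element for a in acetate.atoms)
        # reference orders/charges survive the round trip
        assert sorted(pm.ref_bond_orders.values()) == \
            sorted(r.bond_orders.values())
        assert sorted(pm.ref_formal_charges.values()) == \
            sorted(r.formal_charges.values())

    def test_resonance_multi_record_sdf(self, acetate, table, tmp_path):
        rs = resonance_structures(acetate, table)
        path = tmp_path / "res.sdf"
        write_result(acetate, rs, path, fmt="sdf")
        assert len(read_molecules(path)) == len(rs)

    def test_disconnected_record_split(self, tmp_path):
        from rdkit import Chem

        mol = Chem.AddHs(Chem.MolFromSmiles("CCO.CC[O-]"))
        w = Chem.SDWriter(str(tmp_path / "two.sdf"))
        w.write(mol)
        w.close()
        parts = read_molecules(tmp_path / "two.sdf")
        assert len(parts) == 2
        assert sorted(pm.total_charge for pm in parts) == [-1, 0]


class TestFiltering:
    def _pm(self, smiles):
        return parse_smiles(smiles, provenance=smiles)

    def test_rules_in_order(self):
        mols = [
            self._pm("CCO"),   # 3 heavy atoms -> too_small
            self._pm("CCCO"),  # kept
            self._pm("OCCC"),  # duplicate of the above
        ]
        # dangling bond: dummy atom
        mols.append(ParsedMolecule(["*", "C", "C", "C", "C"],
                                   [(0, 1), (1, 2), (2, 3), (3, 4)], 0, "dang"))
        # odd valence electrons (nitric-oxide-like fragment, 4 heavy atoms)
        odd = self._pm("CCC[O]")  # neutral alkoxy radical: odd electron count
        mols.append(odd)
        report = filter_dataset(mols)
        assert report.counts["too_small"] == 1
        assert report.counts["kept"] == 1
        assert report.counts["duplicate"] == 1
        assert report.counts["dangling_bonds"] == 1
        assert report.counts["odd_electrons"] == 1

    def test_unsupported_element(self):
        pm = ParsedMolecule(["C", "C", "C", "C", "B"],
                            [(0, 1), (1, 2), (2, 3), (3, 4)], 0, "boron")
        report = filter_dataset([pm])
        assert report.counts["unsupported_element"] == 1

    def test_idempotent(self):
        mols = [self._pm("CCCO"), self._pm("CCCO"), self._pm("CCCC")]
        r1 = filter_dataset(mols)
        r2 = filter_dataset(mols)
        assert r1.dispositions == r2.dispositions
        assert r1.counts == r2.counts


class TestReports:
    def test_infinite_score_reports_no_valid_assignment(self, water):
        rep = result_report(water, AssignmentResult({}, {}, math.inf, "fpt"))
        assert rep["status"] == "no_valid_assignment"

    def test_json_report(self, water, table, tmp_path):
        r = assign(water, table)
        path = tmp_path / "w.json"
        write_result(water, r, path, fmt="json")
        rep = json.loads(path.read_text())
        assert rep["status"] == "ok"
        assert rep["formal_charges"] == [0, 0, 0]
        assert set(rep["bond_orders"].values()) == {1}


class TestSyntheticGenerator:
    def test_deterministic(self):
        a = generate_synthetic(10, seed=1)
        b = generate_synthetic(10, seed=1)
        assert [(tuple(x.element for x in g.atoms), tuple(g.bonds),
                 g.total_charge) for g in a] == \
               [(tuple(x.element for x in g.atoms), tuple(g.bonds),
                 g.total_charge) for g in b]

    def test_all_pass_filters(self):
        graphs = generate_synthetic(30, seed=5)
        for g in graphs:
            assert g.is_connected()
            assert sum(1 for a in g.atoms if a.element != "H") >= 4
            n_val = sum(a.valence_electrons for a in g.atoms) - g.total_charge
            assert n_val % 2 == 0
            p = positions(g)  # no OverSaturatedAtom, capacity feasible
            assert p.capacity >= p.e_t
        pms = [ParsedMolecule([a.element for a in g.atoms], list(g.bonds),
                              g.total_charge, str(i))
               for i, g in enumerate(graphs)]
        assert filter_dataset(pms).counts["kept"] == len(graphs)

    def test_pair_slot_cap(self):
        for g in generate_synthetic(10, max_heavy_atoms=6, seed=2,
                                    max_pair_slots=8):
            assert positions(g).capacity <= 8


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(algorithm="astar", max_resonance=8)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert RunConfig.from_yaml(path) == cfg

    def test_invalid_algorithm(self):
        with pytest.raises(ValueError):
            RunConfig(algorithm="anneal")


class TestCLI:
    def test_assign_happy_path(self, acetate, table, tmp_path):
        sdf = tmp_path / "in.sdf"
        write_result(acetate, assign(acetate, table), sdf, fmt="sdf")
        runner = CliRunner()
        out_json = tmp_path / "out.json"
        res = runner.invoke(main, ["assign", str(sdf), "--algorithm", "fpt",
                                   "--out-json", str(out_json)])
        assert res.exit_code == 0, res.output
        reports = json.loads(out_json.read_text())
        assert reports[0]["status"] == "ok"

    def test_consistency_synthetic(self):
        runner = CliRunner()
        res = runner.invoke(main, ["consistency", "--algorithms", "astar,fpt",
                                   "--synthetic", "8", "--seed", "7",
                                   "--max-heavy", "6"])
        assert res.exit_code == 0, res.output
        assert "= 1.0000" in res.output

    def test_unknown_algorithm_exits_2(self, tmp_path):
        sdf = tmp_path / "x.sdf"
        sdf.write_text("")
        runner = CliRunner()
        res = runner.invoke(main, ["assign", str(sdf), "--algorithm", "magic"])
        assert res.exit_code == 2

    def test_synth_and_filter(self, tmp_path):
        runner = CliRunner()
        sdf = tmp_path / "synth.sdf"
        res = runner.invoke(main, ["synth", str(sdf), "-n", "5", "--seed", "3"])
        assert res.exit_code == 0, res.output
        res = runner.invoke(main, ["filter", str(sdf)])
        assert res.exit_code == 0, res.output
        counts = json.loads(res.output)
        assert counts["kept"] == 5
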