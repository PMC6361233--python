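"""PDB cleaning, interface detection, SASA and burial classification."""

import numpy as np
import pytest

from oracles import brute_force_interface
from skempi2.structure import (BURIAL_THRESHOLD, chain_sequences,
                               classify_locations, clean_structure,
                               interface_residues, load_structure,
                               location_label, relative_sasa)
from skempi2.synthetic import generate_toy_complex


def two_atom_pdb(distance):
    """Two single-carbon 'residues' on different chains, a given distance
    apart (hand-written PDB records)."""
    lines = [
        f"ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
        f"  1.00  0.00           C",
        f"ATOM      2  CA  ALA B   1       0.000   0.000{distance:>8.3f}"
        f"  1.00  0.00           C",
        "END",
    ]
    return "\n".join(lines) + "\n"


MESSY_PDB = "\n".join([
    # chain A starts at residue -2 and contains an insertion code
    "ATOM      1  CA  GLY A  -2       0.000   0.000   0.000  1.00  0.00           C",
    "ATOM      2  CA  GLY A  -1       3.800   0.000   0.000  1.00  0.00           C",
    "ATOM      3  CA  GLY A  -1A      7.600   0.000   0.000  1.00  0.00           C",
    "ATOM      4  CA  GLY B   5       0.000   4.000   0.000  1.00  0.00           C",
    # altloc conformers, B has the higher occupancy
    "ATOM      5  CB AGLY B   5       0.000   5.000   0.000  0.30  0.00           C",
    "ATOM      6  CB BGLY B   5       0.000   6.000   0.000  0.70  0.00           C",
    # irrelevant chain C with a water near A and one far away
    "HETATM    7  O   HOH C   1       0.000   0.000   3.000  1.00  0.00           O",
    "HETATM    8  O   HOH C   2      50.000  50.000  50.000  1.00  0.00           O",
    "END",
]) + "\n"


class TestCleaning:
    def test_renumbering_map_round_trips(self):
        cleaned = clean_structure(MESSY_PDB, ["A"], ["B"])
        assert cleaned.forward_map[("A", -2, "")] == ("A", 1)
        assert cleaned.forward_map[("A", -1, "")] == ("A", 2)
        assert cleaned.forward_map[("A", -1, "A")] == ("A", 3)
        for orig, new in cleaned.forward_map.items():
            assert cleaned.backward_map[new] == orig
        assert len(cleaned.forward_map) == len(cleaned.backward_map)
        # no insertion codes or negative numbers remain
        for chain in next(iter(cleaned.structure)):
            for res in chain:
                assert res.id[1] > 0 and res.id[2] == " "

    def test_water_retention_radius(self):
        cleaned = clean_structure(MESSY_PDB, ["A"], ["B"])
        waters = [res for chain in next(iter(cleaned.structure))
                  for res in chain if res.resname == "HOH"]
        assert len(waters) == 1  # the 3 Å water kept, the 50 Å water dropped

    def test_altloc_highest_occupancy_kept(self):
        cleaned = clean_structure(MESSY_PDB, ["A"], ["B"])
        (chain_b,) = [c for c in next(iter(cleaned.structure)) if c.id == "B"]
        (res,) = [r for r in chain_b if r.resname == "GLY"]
        cb = res["CB"]
        assert not cb.is_disordered()
        assert cb.coord[1] == pytest.approx(6.0)  # the 0.70-occupancy copy

    def test_idempotent(self, toy_complex):
        pdb_text, _ = toy_complex
        c1 = clean_structure(pdb_text, ["A"], ["B"])
        c2 = clean_structure(c1.pdb_text, ["A"], ["B"])
        assert c1.pdb_text == c2.pdb_text

    def test_missing_chain_fatal(self):
        with pytest.raises(ValueError, match="missing"):
            clean_structure(MESSY_PDB, ["A"], ["Z"])

    def test_toy_waters(self, toy_complex):
        pdb_text, truth = toy_complex
        cleaned = clean_structure(pdb_text, ["A"], ["B"])
        waters = [res for chain in next(iter(cleaned.structure))
                  for res in chain if res.resname == "HOH"]
        assert len(waters) == 1


class TestInterface:
    def test_cutoff_boundary(self):
        inside = interface_residues(load_structure(two_atom_pdb(9.9)),
                                    ["A"], ["B"])
        outside = interface_residues(load_structure(two_atom_pdb(10.1)),
                                     ["A"], ["B"])
        assert all(len(s) == 1 for s in inside)
        assert all(len(s) == 0 for s in outside)

    def test_far_slabs_have_no_interface(self):
        pdb_text, _ = generate_toy_complex(gap=25.0)
        i1, i2 = interface_residues(load_structure(pdb_text), ["A"], ["B"])
        assert i1 == set() and i2 == set()

    def test_matches_all_pairs_oracle(self):
        for gap in (3.0, 6.0, 9.5, 12.0):
            pdb_text, _ = generate_toy_complex(gap=gap)
            s = load_structure(pdb_text)
            got = interface_residues(s, ["A"], ["B"])
            assert got == brute_force_interface(s, ["A"], ["B"])


class TestSasa:
    def test_isolated_glycine_matches_dense_integration(self):
        pdb = "\n".join([
            "ATOM      1  N   GLY A   1       0.000   1.430   0.000  1.00  0.00           N",
            "ATOM      2  CA  GLY A   1       1.370   0.900   0.000  1.00  0.00           C",
            "ATOM      3  C   GLY A   1       2.400   1.900   0.500  1.00  0.00           C",
            "ATOM      4  O   GLY A   1       2.200   3.100   0.600  1.00  0.00           O",
            "END"]) + "\n"
        s = load_structure(pdb)
        coarse = relative_sasa(s, ["A"], n_points=960)
        dense = relative_sasa(s, ["A"], n_points=5000)
        (sasa960, _, _), (sasa5k, _, _) = (coarse[("A", 1, "")],
                                           dense[("A", 1, "")])
        assert sasa960 == pytest.approx(sasa5k, rel=0.01)
        assert sasa960 > 150.0  # a lone residue is almost fully exposed

    def test_fully_occluded_residue_near_zero(self, toy_complex):
        pdb_text, truth = toy_complex
        s = load_structure(pdb_text)
        rasa = relative_sasa(s, ["A"])
        interior = [rid for rid, lab in truth["labels"].items()
                    if lab == "INT"]
        for rid in interior:
            assert rasa[rid][1] < 0.05

    def test_burial_monotonic_under_binding(self, toy_complex):
        pdb_text, _ = toy_complex
        s = load_structure(pdb_text)
        mono = relative_sasa(s, ["A"])
        both = relative_sasa(s, ["A", "B"])
        for rid, (_, r_mono, _) in mono.items():
            assert both[rid][1] <= r_mono + 1e-9

    def test_rotation_invariance(self, toy_complex):
        pdb_text, _ = toy_complex
        s1 = load_structure(pdb_text)
        s2 = load_structure(pdb_text)
        rng = np.random.default_rng(2)
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(rng=rng).as_matrix()
        for atom in s2.get_atoms():
            atom.coord = rot @ atom.coord + np.array([5.0, -3.0, 11.0])
        r1 = relative_sasa(s1, ["A", "B"])
        r2 = relative_sasa(s2, ["A", "B"])
        total1 = sum(v[0] for v in r1.values())
        total2 = sum(v[0] for v in r2.values())
        assert abs(total1 - total2) / total1 < 0.01
        devs = [abs(r1[rid][1] - r2[rid][1]) for rid in r1]
        # per-residue deviations are bounded by the 960-point quantization
        # of the sphere sampling (see docs on numerical choices)
        assert np.mean(devs) < 0.01
        assert max(devs) < 0.03


class TestClassification:
    @pytest.mark.parametrize("mono,comp,label", [
        (0.05, 0.05, "INT"),
        (0.60, 0.60, "SUR"),
        (0.10, 0.02, "SUP"),
        (0.60, 0.10, "COR"),
        (0.60, 0.40, "RIM"),
    ])
    def test_rule_table(self, mono, comp, label):
        assert location_label(mono, comp) == label

    def test_rule_table_oracle_over_grid(self):
        thr = BURIAL_THRESHOLD
        for mono in np.linspace(0.0, 1.1, 23):
            for comp in np.linspace(0.0, 1.1, 23):
                if comp > mono:
                    continue
                got = location_label(mono, comp)
                if comp >= mono - 1e-6:
                    want = "INT" if mono < thr else "SUR"
                elif mono < thr:
                    want = "SUP"
                elif comp < thr:
                    want = "COR"
                else:
                    want = "RIM"
                assert got == want

    def test_every_residue_gets_exactly_one_label(self, toy_complex):
        pdb_text, _ = toy_complex
        locs = classify_locations(pdb_text, ["A"], ["B"])
        assert all(l.label in {"INT", "SUR", "SUP", "COR", "RIM"}
                   for l in locs)
        n_polymer = sum(
            1 for c in next(iter(load_structure(pdb_text)))
            if c.id in "AB" for r in c if r.id[0] == " ")
        assert len(locs) == n_polymer

    def test_geometry_forced_labels_recovered(self, toy_complex):
        pdb_text, truth = toy_complex
        by = {l.residue: l.label
              for l in classify_locations(pdb_text, ["A"], ["B"])}
        assert truth["labels"]
        assert {"INT", "SUR", "SUP", "COR", "RIM"} == set(
            truth["labels"].values())
        for rid, want in truth["labels"].items():
            assert by[rid] == want, rid

    def test_interface_labels_require_buried_area(self, toy_complex):
        pdb_text, _ = toy_complex
        locs = classify_locations(pdb_text, ["A"], ["B"])
        for l in locs:
            if l.label in {"SUP", "COR", "RIM"}:
                assert l.rasa_monomer - l.rasa_complex > 0
            else:
                assert l.rasa_monomer - l.rasa_complex <= 1e-6


class TestAnnotate:
    def test_planted_core_mutation_labelled(self, tmp_path, toy_complex):
        from oracles import make_entry
        from skempi2.io import parse_mutation_string
        from skempi2.structure import annotate_entries
        pdb_text, truth = toy_complex
        (tmp_path / "1TOY.pdb").write_text(pdb_text)
        core_res = next(r for r, l in truth["labels"].items() if l == "COR")
        m = parse_mutation_string(f"AA{core_res[1]}G")[0]
        entry = make_entry("1TOY", [m], 1.0)
        annotated, issues, summary = annotate_entries([entry], tmp_path)
        assert annotated[0].location_labels == ("COR",)
        assert summary["single_mutation_locations"] == {"COR": 1}
        assert not issues

    def test_missing_residue_reported(self, tmp_path, toy_complex):
        from oracles import make_entry
        from skempi2.io import parse_mutation_string
        from skempi2.structure import annotate_entries
        pdb_text, _ = toy_complex
        (tmp_path / "1TOY.pdb").write_text(pdb_text)
        m = parse_mutation_string("AA999G")[0]
        entry = make_entry("1TOY", [m], 1.0)
        annotated, issues, _ = annotate_entries([entry], tmp_path)
        assert annotated[0].location_labels is None
        assert any(i.code == "residue_not_in_structure" for i in issues)

    def test_empty_directory_skips_all(self, tmp_path, default_table):
        from skempi2.structure import annotate_entries
        entries, _ = default_table
        annotated, issues, summary = annotate_entries(entries[:5], tmp_path)
        assert summary["n_labelled"] == 0 and summary["n_skipped"] == 5
        assert len(issues) == 5


def test_chain_sequences(toy_complex):
    pdb_text, _ = toy_complex
    seqs = chain_sequences(load_structure(pdb_text))
    assert set(seqs) == {"A", "B"}
    assert set(seqs["A"]) == {"A"} and len(seqs["B"]) == 18
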