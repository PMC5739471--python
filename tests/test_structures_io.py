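"""Structure/ensemble I/O: parsing, residue bookkeeping, tables, round trips."""

import numpy as np
import pytest

import ensembleflex as ef
from ensembleflex.io import PDBFormatError
from ensembleflex.structures import EnsembleConsistencyError

from conftest import make_structure

FOUR_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.749   7.097  -4.943  1.00  0.00           C
ATOM      4  O   ALA A   1      13.165   7.798  -5.869  1.00  0.00           O
END
"""

INSERTION_CODE_PDB = """\
ATOM      1  CA  GLY A  52       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A  52A      3.800   0.000   0.000  1.00  0.00           C
END
"""


def test_reads_hand_written_pdb(tmp_path):
    p = tmp_path / "four.pdb"
    p.write_text(FOUR_ATOM_PDB)
    s = ef.read_structure(p)
    assert s.n_atoms == 4
    assert s.n_residues == 1
    assert list(s.name) == ["N", "CA", "C", "O"]
    np.testing.assert_allclose(s.coords[0], [11.104, 6.134, -6.504])


def test_first_model_policy_on_multimodel_file(tmp_path, weak_patch_case):
    ens = weak_patch_case["ensemble"]
    sub = ef.ConformationalEnsemble(ens.topology, ens.frames[:3])
    p = tmp_path / "three.pdb"
    ef.write_ensemble_pdb(sub, p)
    s = ef.read_structure(p, model="first")
    assert s.n_atoms == ens.topology.n_atoms
    np.testing.assert_allclose(s.coords, ens.frames[0], atol=1e-2)


def test_insertion_codes_make_distinct_residues(tmp_path):
    p = tmp_path / "icode.pdb"
    p.write_text(INSERTION_CODE_PDB)
    s = ef.read_structure(p)
    assert s.n_residues == 2
    assert set(s.residue_index) == {("A", 52, ""), ("A", 52, "A")}
    # independent parser agreement on the same fixture
    from Bio.PDB import PDBParser

    bio = PDBParser(QUIET=True).get_structure("x", str(p))
    bio_residues = list(bio.get_residues())
    assert len(bio_residues) == s.n_residues
    bio_ids = {(r.get_parent().id, r.id[1], r.id[2].strip()) for r in bio_residues}
    assert bio_ids == set(s.residue_index)


def test_unparseable_file_raises_format_error(tmp_path):
    p = tmp_path / "bad.pdb"
    p.write_bytes(b"\x00\x01\x02 not a pdb \xff")
    with pytest.raises((PDBFormatError, ValueError)):
        ef.read_structure(p)


def test_ensemble_from_identical_models_has_zero_rmsd(tmp_path):
    s = make_structure([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
    ens = ef.ConformationalEnsemble(s, np.stack([s.coords, s.coords]))
    p = tmp_path / "two.pdb"
    ef.write_ensemble_pdb(ens, p)
    loaded = ef.read_ensemble(p)
    assert loaded.n_frames == 2
    assert ef.rmsd(loaded.frames[0], loaded.frames[1]) < 1e-6


def test_ensemble_from_directory_sorted_by_filename(tmp_path):
    s = make_structure([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]])
    d = tmp_path / "frames"
    d.mkdir()
    for k in range(5):
        ef.write_structure(s.with_coords(s.coords + k), d / f"frame{k}.pdb")
    ens = ef.read_ensemble(d)
    assert ens.n_frames == 5
    assert ens.frame_ids == [f"frame{k}.pdb" for k in range(5)]
    np.testing.assert_allclose(ens.frames[3], s.coords + 3, atol=1e-2)


def test_inconsistent_model_names_offending_frame(tmp_path):
    lines = FOUR_ATOM_PDB.replace("END\n", "")
    models = []
    for m in (1, 2, 3):
        body = lines if m != 3 else "\n".join(lines.splitlines()[:-1]) + "\n"
        models.append(f"MODEL     {m}\n{body}ENDMDL\n")
    p = tmp_path / "broken.pdb"
    p.write_text("".join(models) + "END\n")
    with pytest.raises((EnsembleConsistencyError, PDBFormatError)) as err:
        ef.read_ensemble(p)
    assert "3" in str(err.value)


def test_residue_table_has_rows_in_chain_order(tmp_path):
    s = make_structure(
        [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], resnums=[5, 6, 7]
    )
    out = tmp_path / "t.tsv"
    ef.write_residue_table({("A", 5, ""): 1.5, ("A", 6, ""): 2.5, ("A", 7, ""): 3.5},
                           out, s)
    lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
    assert lines[0].split("\t")[:2] == ["chain", "resnum"]
    assert [l.split("\t")[1] for l in lines[1:]] == ["5", "6", "7"]
    with pytest.raises(KeyError):
        ef.write_residue_table({("B", 1, ""): 0.0}, out, s)


def test_bfactor_pdb_round_trips_values(tmp_path, weak_patch_case):
    s = weak_patch_case["structure"]
    values = np.ones(s.n_residues)
    p = tmp_path / "bf.pdb"
    ef.write_bfactor_pdb(s, values, p)
    loaded = ef.read_structure(p)
    np.testing.assert_allclose(loaded.b_factor, 1.0, atol=1e-6)
    # arbitrary values round-trip to PDB precision (2 decimals)
    vals = np.linspace(0.1, 40.0, s.n_residues)
    ef.write_bfactor_pdb(s, vals, p)
    loaded = ef.read_structure(p)
    per_res = np.array([loaded.b_factor[loaded.residue_starts[r]]
                        for r in range(loaded.n_residues)])
    np.testing.assert_allclose(per_res, vals, atol=5e-3)


def test_domain_annotation_lookup_and_overlap_guard():
    ann = ef.DomainAnnotation({"A": {"NTD": (1, 215), "MD": (216, 552),
                                     "CTD": (553, 690)}})
    assert ann.domain_of("A", 1) == "NTD"
    assert ann.domain_of("A", 400) == "MD"
    assert ann.domain_of("A", 700) is None
    assert ann.domain_of("B", 10) is None
    with pytest.raises(ValueError):
        ef.DomainAnnotation({"A": {"x": (1, 100), "y": (50, 200)}})


def test_write_read_idempotent_on_coordinates(tmp_path, weak_patch_case):
    s = weak_patch_case["structure"]
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    ef.write_structure(s, p1)
    s1 = ef.read_structure(p1)
    ef.write_structure(s1, p2)
    s2 = ef.read_structure(p2)
    np.testing.assert_allclose(s1.coords, s2.coords, atol=1e-3)
    np.testing.assert_allclose(s.coords, s1.coords, atol=1e-3)
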