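"""Constraint rules: tether cutoffs, Mayo hydrogen bonds, network assembly."""

import numpy as np
import pytest

import ensembleflex as ef
from ensembleflex.rigidity import (
    MissingHydrogensError,
    build_constraint_network,
    covalent_bonds,
    detect_hydrogen_bonds,
    detect_hydrophobic_tethers,
    mayo_energy,
)

from conftest import make_structure


def _carbon_pair(distance, elements=("C", "C")):
    return make_structure(
        [[0, 0, 0], [distance, 0, 0]],
        names=["CB", "CB"], elements=list(elements), resnums=[1, 5],
    )


@pytest.mark.parametrize(
    "distance, elements, expected",
    [
        (3.60, ("C", "C"), True),    # < 1.7 + 1.7 + 0.25 = 3.65
        (3.70, ("C", "C"), False),
        (3.70, ("C", "S"), True),    # < 1.7 + 1.8 + 0.25 = 3.75
        (3.80, ("C", "S"), False),
        (3.80, ("S", "S"), True),    # < 1.8 + 1.8 + 0.25 = 3.85
    ],
)
def test_hydrophobic_tether_cutoff_arithmetic(distance, elements, expected):
    tethers = detect_hydrophobic_tethers(_carbon_pair(distance, elements))
    assert (len(tethers) == 1) == expected
    if tethers:
        assert tethers[0].bars == 2


def test_tethers_exclude_short_bonded_paths():
    # four carbons in a covalent chain, all within tether distance
    s = make_structure(
        [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0]],
        names=["C1", "C2", "C3", "C4"], elements=["C"] * 4,
        resnums=[1, 1, 1, 1],
    )
    bonds = covalent_bonds(s)
    assert len(bonds) == 3  # distance-fallback chain
    assert detect_hydrophobic_tethers(s, bonds=bonds) == []


def _hb_structure(h_pos, o_pos):
    return make_structure(
        [[0, 0, 0], h_pos, o_pos],
        names=["N", "H", "O"], elements=["N", "H", "O"], resnums=[1, 1, 3],
    )


def test_ideal_linear_hydrogen_bond_is_strong():
    assert mayo_energy(2.8, 180.0) == pytest.approx(-8.0)
    s = _hb_structure([0, 0, 1.0], [0, 0, 2.8])
    hb = detect_hydrogen_bonds(s, include_salt_bridges=False)
    assert len(hb) == 1
    assert hb[0].energy <= -4.0


def test_no_bond_outside_distance_gate():
    s = _hb_structure([0, 0, 1.0], [0, 0, 5.0])
    assert detect_hydrogen_bonds(s, include_salt_bridges=False) == []


def test_no_bond_outside_angle_gate():
    s = _hb_structure([0, 0, 1.0], [1.5, 0, 1.0])  # D-H-A angle = 90 deg
    assert detect_hydrogen_bonds(s, include_salt_bridges=False) == []


def test_missing_hydrogens_raise_actionable_error():
    s = make_structure([[0, 0, 0], [0, 0, 2.8]], names=["N", "O"],
                       elements=["N", "O"], resnums=[1, 3])
    with pytest.raises(MissingHydrogensError):
        detect_hydrogen_bonds(s)


def test_salt_bridge_tagged_with_fixed_energy():
    s = make_structure(
        [[0, 0, 0], [3.5, 0, 0]],
        names=["NZ", "OD1"], elements=["N", "O"],
        resnums=[1, 5], resnames=["LYS", "ASP"],
    )
    hb = detect_hydrogen_bonds(s, require_hydrogens=False)
    assert len(hb) == 1
    assert hb[0].kind == "salt-bridge"
    assert hb[0].energy == -10.0


def test_network_cutoff_filters_weak_bonds(weak_patch_case):
    s = weak_patch_case["structure"]
    hbonds = weak_patch_case["constraint_source"](s)
    strong = [c for c in hbonds if c.energy < -1.0]
    net = build_constraint_network(s, e_cut=-1.0, hbonds=hbonds)
    kinds = [c for c in net.constraints if c.kind == "hydrogen-bond"]
    assert len(kinds) == len(strong)
    # E_cut -> -inf removes every hydrogen bond
    net_inf = build_constraint_network(s, e_cut=-1e9, hbonds=hbonds)
    assert all(c.kind != "hydrogen-bond" for c in net_inf.constraints)


def test_lowering_cutoff_never_adds_constraints(weak_patch_case):
    s = weak_patch_case["structure"]
    hbonds = weak_patch_case["constraint_source"](s)
    previous = None
    for e_cut in (-0.5, -2.5, -5.0, -11.0, -13.0):
        pairs = {(c.i, c.j) for c in
                 build_constraint_network(s, e_cut=e_cut, hbonds=hbonds).constraints}
        if previous is not None:
            assert pairs <= previous
        previous = pairs


def test_backbone_template_bond_classes(weak_patch_case):
    s = weak_patch_case["structure"]
    bonds = covalent_bonds(s)
    name = np.char.strip(s.name.astype("U6"))
    res_of = s.atom_residue_index
    kinds = {}
    for c in bonds:
        key = tuple(sorted((name[c.i], name[c.j])))
        inter = res_of[c.i] != res_of[c.j]
        kinds[(key, inter)] = c.kind
    assert kinds[(("C", "N"), True)] == "covalent-locked"       # peptide
    assert kinds[(("C", "O"), False)] == "covalent-locked"      # carbonyl
    assert kinds[(("CA", "N"), False)] == "covalent-rotatable"  # phi
    assert kinds[(("C", "CA"), False)] == "covalent-rotatable"  # psi
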