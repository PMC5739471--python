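"""Constraint detection for FIRST-style rigidity networks.

Atoms become rigid bodies; covalent bonds, hydrogen bonds, salt bridges and
hydrophobic tethers become bar constraints between them:

* rotatable covalent bond — 5 bars (one free dihedral left);
* locked covalent bond (peptide link, double bonds) — 6 bars;
* hydrogen bond / salt bridge — 5 bars, carrying an energy in kcal/mol;
* hydrophobic tether — 2 bars.

Hydrogen-bond energies use the Mayo-form well
``E = V0 (5 (d0/d)^12 - 6 (d0/d)^10) cos^2(theta)`` with V0 = 8 kcal/mol and
d0 = 2.8 Å over the donor-acceptor distance d and the donor-H-acceptor angle
theta, gated at d <= 3.6 Å and theta > 100 deg.  Hydrophobic tethers join
carbon/sulfur pairs closer than the sum of their van der Waals radii
(1.7 Å C, 1.8 Å S) plus a 0.25 Å pad, excluding short bonded paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from ..structures import Structure

__all__ = [
    "Constraint",
    "ConstraintNetwork",
    "MissingHydrogensError",
    "covalent_bonds",
    "detect_hydrogen_bonds",
    "detect_hydrophobic_tethers",
    "build_constraint_network",
]

HB_V0 = 8.0            # kcal/mol, Mayo well depth
HB_D0 = 2.8            # Å, ideal donor-acceptor distance
HB_DIST_CUTOFF = 3.6   # Å, donor-acceptor gate
HB_ANGLE_CUTOFF = 100.0  # degrees, D-H-A gate
D_CUTHP = 0.25         # Å, hydrophobic-tether pad
SALT_BRIDGE_ENERGY = -10.0  # kcal/mol, fixed (persists deep into the sweep)
SALT_BRIDGE_CUTOFF = 4.0    # Å, N...O distance gate

VDW_C = 1.7
VDW_S = 1.8

BARS_ROTATABLE = 5
BARS_LOCKED = 6
BARS_HBOND = 5
BARS_TETHER = 2

_COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07}

# charged side-chain atoms for salt-bridge tagging
_SB_DONORS = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
              ("HIS", "ND1"), ("HIS", "NE2")}
_SB_ACCEPTORS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


class MissingHydrogensError(ValueError):
    """Hydrogen-bond detection needs donor hydrogens; add hydrogens first."""


@dataclass(frozen=True)
class Constraint:
    """A bar constraint between two atoms (body indices into the structure)."""

    kind: str              # covalent-rotatable | covalent-locked | hydrogen-bond |
                           # salt-bridge | hydrophobic-tether
    i: int
    j: int
    bars: int
    energy: float | None = None   # kcal/mol; hydrogen bonds / salt bridges only

    def __post_init__(self) -> None:
        if self.bars not in (2, 5, 6):
            raise ValueError(f"bars must be 2, 5 or 6, got {self.bars}")
        if self.kind in ("hydrogen-bond", "salt-bridge"):
            if self.energy is None or self.energy >= 0:
                raise ValueError(f"{self.kind} constraint needs energy < 0")


def covalent_bonds(structure: Structure) -> list[Constraint]:
    """Covalent constraints from backbone/side-chain templates + distance fallback.

    Intra-residue bonds among the standard backbone names (N-CA, CA-C, C-O,
    C-OXT, CA-CB, N-H) and the inter-residue peptide link C(i)-N(i+1) are
    assigned by name; remaining atoms (side chains past CB, ligands) are
    bonded by a covalent-radius distance criterion.  Peptide links and C=O
    are locked (6 bars); other covalent bonds are rotatable (5 bars).
    """
    name = np.char.strip(structure.name.astype("U8"))
    elem = np.char.upper(np.char.strip(structure.element.astype("U2")))
    res_of = structure.atom_residue_index
    n_res = structure.n_residues
    chain_of_res = [rid[0] for rid in structure.residue_ids()]

    by_res_name: list[dict[str, int]] = [dict() for _ in range(n_res)]
    for a in range(structure.n_atoms):
        by_res_name[res_of[a]].setdefault(name[a], a)

    out: list[Constraint] = []
    seen: set[tuple[int, int]] = set()

    def add(i: int, j: int, locked: bool) -> None:
        key = (min(i, j), max(i, j))
        if key in seen or i == j:
            return
        seen.add(key)
        out.append(Constraint(
            kind="covalent-locked" if locked else "covalent-rotatable",
            i=key[0], j=key[1],
            bars=BARS_LOCKED if locked else BARS_ROTATABLE,
        ))

    templated = np.zeros(structure.n_atoms, dtype=bool)
    template = [("N", "CA", False), ("CA", "C", False), ("C", "O", True),
                ("C", "OXT", True), ("CA", "CB", False), ("N", "H", False)]
    for r in range(n_res):
        atoms = by_res_name[r]
        for a_name, b_name, locked in template:
            if a_name in atoms and b_name in atoms:
                add(atoms[a_name], atoms[b_name], locked)
                templated[atoms[a_name]] = templated[atoms[b_name]] = True
        # peptide link to the next residue in the same chain
        if r + 1 < n_res and chain_of_res[r] == chain_of_res[r + 1]:
            if "C" in atoms and "N" in by_res_name[r + 1]:
                add(atoms["C"], by_res_name[r + 1]["N"], True)

    # distance fallback for anything the template left unbonded
    untempl = np.flatnonzero(~templated)
    if len(untempl):
        tree = cKDTree(structure.coords)
        radii = np.array([_COVALENT_RADII.get(e, 0.77) for e in elem])
        max_cut = 2 * radii.max() + 0.45
        for a in untempl:
            for b in tree.query_ball_point(structure.coords[a], max_cut):
                if b == a:
                    continue
                d = np.linalg.norm(structure.coords[a] - structure.coords[b])
                if d <= radii[a] + radii[b] + 0.45:
                    add(a, b, False)
    return out


def mayo_energy(d_da: float, theta_deg: float) -> float:
    """Mayo-form hydrogen-bond energy (kcal/mol) at D-A distance and D-H-A angle."""
    x = HB_D0 / d_da
    radial = HB_V0 * (5.0 * x ** 12 - 6.0 * x ** 10)
    return radial * np.cos(np.radians(theta_deg)) ** 2


def detect_hydrogen_bonds(
    structure: Structure,
    bonds: list[Constraint] | None = None,
    include_salt_bridges: bool = True,
    require_hydrogens: bool = True,
) -> list[Constraint]:
    """Detect hydrogen bonds (and salt bridges) with Mayo-form energies.

    Donors are N/O atoms with a covalently attached hydrogen; acceptors are
    any other N/O.  A pair qualifies at donor-acceptor distance <= 3.6 Å,
    D-H-A angle > 100 deg and negative energy.  Charged-group N/O pairs
    within 4 Å are tagged as salt bridges with a fixed -10 kcal/mol energy.
    Raises :class:`MissingHydrogensError` when no hydrogens are present.
    """
    elem = np.char.upper(np.char.strip(structure.element.astype("U2")))
    name = np.char.strip(structure.name.astype("U8"))
    resname = np.char.strip(structure.resname.astype("U5"))
    res_of = structure.atom_residue_index
    coords = structure.coords

    if bonds is None:
        bonds = covalent_bonds(structure)
    attached_h: dict[int, list[int]] = {}
    for c in bonds:
        for heavy, h in ((c.i, c.j), (c.j, c.i)):
            if elem[h] == "H" and elem[heavy] in ("N", "O"):
                attached_h.setdefault(heavy, []).append(h)

    polar = np.flatnonzero((elem == "N") | (elem == "O"))
    if require_hydrogens and not np.any(elem == "H"):
        raise MissingHydrogensError(
            "structure has no hydrogens; add (or infer) polar hydrogens "
            "before hydrogen-bond detection, or pass require_hydrogens=False "
            "for salt-bridge-only detection"
        )

    bonded_pairs = {(min(c.i, c.j), max(c.i, c.j)) for c in bonds}
    tree = cKDTree(coords[polar])
    out: list[Constraint] = []
    seen: set[tuple[int, int]] = set()
    for ii, jj in tree.query_pairs(max(HB_DIST_CUTOFF, SALT_BRIDGE_CUTOFF)):
        a, b = int(polar[ii]), int(polar[jj])
        if res_of[a] == res_of[b]:
            continue
        if (min(a, b), max(a, b)) in bonded_pairs:
            continue
        d = float(np.linalg.norm(coords[a] - coords[b]))
        # salt bridge?
        if include_salt_bridges and d <= SALT_BRIDGE_CUTOFF:
            pa, pb = (resname[a], name[a]), (resname[b], name[b])
            if ((pa in _SB_DONORS and pb in _SB_ACCEPTORS)
                    or (pb in _SB_DONORS and pa in _SB_ACCEPTORS)):
                key = (min(a, b), max(a, b))
                if key not in seen:
                    seen.add(key)
                    out.append(Constraint("salt-bridge", key[0], key[1],
                                          BARS_HBOND, SALT_BRIDGE_ENERGY))
                continue
        if d > HB_DIST_CUTOFF:
            continue
        for donor, acceptor in ((a, b), (b, a)):
            best = None
            for h in attached_h.get(donor, ()):
                theta = _angle_deg(coords[donor], coords[h], coords[acceptor])
                if theta <= HB_ANGLE_CUTOFF:
                    continue
                e = mayo_energy(d, theta)
                if e < 0 and (best is None or e < best):
                    best = e
            if best is not None:
                key = (min(donor, acceptor), max(donor, acceptor))
                if key not in seen:
                    seen.add(key)
                    out.append(Constraint("hydrogen-bond", key[0], key[1],
                                          BARS_HBOND, float(best)))
    out.sort(key=lambda c: (c.i, c.j))
    return out


def _angle_deg(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1 = d - h
    v2 = a - h
    cosang = v1.dot(v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hydrophobic_tethers(
    structure: Structure, bonds: list[Constraint] | None = None
) -> list[Constraint]:
    """Hydrophobic tethers: C/S pairs inside the padded van-der-Waals contact.

    The cutoff is r_vdw(i) + r_vdw(j) + 0.25 Å (3.65 Å for C-C, 3.75 Å for
    C-S, 3.85 Å for S-S).  Pairs connected by a covalent path of <= 3 bonds
    are excluded.
    """
    elem = np.char.upper(np.char.strip(structure.element.astype("U2")))
    cs = np.flatnonzero((elem == "C") | (elem == "S"))
    if len(cs) < 2:
        return []
    radii = np.where(elem[cs] == "S", VDW_S, VDW_C)
    if bonds is None:
        bonds = covalent_bonds(structure)
    graph_dist = _bond_path_lengths(structure.n_atoms, bonds, limit=3)

    tree = cKDTree(structure.coords[cs])
    out: list[Constraint] = []
    for ii, jj in sorted(tree.query_pairs(2 * VDW_S + D_CUTHP)):
        a, b = int(cs[ii]), int(cs[jj])
        d = np.linalg.norm(structure.coords[a] - structure.coords[b])
        if d >= radii[ii] + radii[jj] + D_CUTHP:
            continue
        if graph_dist.get((min(a, b), max(a, b)), 99) <= 3:
            continue
        out.append(Constraint("hydrophobic-tether", min(a, b), max(a, b), BARS_TETHER))
    return out


def _bond_path_lengths(
    n_atoms: int, bonds: list[Constraint], limit: int
) -> dict[tuple[int, int], int]:
    """Pairs within ``limit`` covalent bonds, mapped to their path length."""
    if not bonds:
        return {}
    rows = [c.i for c in bonds] + [c.j for c in bonds]
    cols = [c.j for c in bonds] + [c.i for c in bonds]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_atoms, n_atoms))
    dist = dijkstra(adj, directed=False, unweighted=True, limit=limit)
    out: dict[tuple[int, int], int] = {}
    ii, jj = np.nonzero(np.isfinite(dist) & (dist > 0))
    for a, b in zip(ii, jj):
        if a < b:
            out[(int(a), int(b))] = int(dist[a, b])
    return out


@dataclass
class ConstraintNetwork:
    """Atoms as bodies plus the bar constraints active at a hydrogen-bond cutoff."""

    n_bodies: int
    constraints: list[Constraint]
    e_cut: float
    d_cuthp: float = D_CUTHP

    def __post_init__(self) -> None:
        pairs = [(c.i, c.j) for c in self.constraints]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate constraints on an atom pair")
        for c in self.constraints:
            if c.kind in ("hydrogen-bond", "salt-bridge") and c.energy >= self.e_cut:
                raise ValueError(
                    f"constraint {c} violates energy cutoff {self.e_cut}"
                )


def build_constraint_network(
    structure: Structure,
    e_cut: float = -1.0,
    hbonds: list[Constraint] | None = None,
    bonds: list[Constraint] | None = None,
    tethers: list[Constraint] | None = None,
) -> ConstraintNetwork:
    """Assemble the constraint network at hydrogen-bond cutoff ``e_cut``.

    Hydrogen bonds / salt bridges enter only when their energy is strictly
    below ``e_cut``; covalent bonds and hydrophobic tethers always enter.
    Pre-detected constraint lists can be passed to avoid recomputation.
    When a pair carries several constraint types, the strongest wins
    (covalent > hydrogen bond > tether).
    """
    if bonds is None:
        bonds = covalent_bonds(structure)
    if hbonds is None:
        hbonds = detect_hydrogen_bonds(structure, bonds=bonds)
    if tethers is None:
        tethers = detect_hydrophobic_tethers(structure, bonds=bonds)

    chosen: dict[tuple[int, int], Constraint] = {}
    for c in tethers:
        chosen[(c.i, c.j)] = c
    for c in hbonds:
        if c.energy < e_cut:
            chosen[(c.i, c.j)] = c
    for c in bonds:
        chosen[(c.i, c.j)] = c
    return ConstraintNetwork(
        n_bodies=structure.n_atoms,
        constraints=sorted(chosen.values(), key=lambda c: (c.i, c.j)),
        e_cut=e_cut,
    )
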