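"""Thermal-unfolding emulation over constraint networks.

Rigidity is re-analysed while the hydrogen-bond inclusion cutoff ``E_cut``
sweeps from weak (-0.1 kcal/mol) to strong (-10 kcal/mol): at each step only
hydrogen bonds/salt bridges stronger than the cutoff remain, so the network
progressively loses its weakest constraints first — an emulation of rising
temperature.  Covalent bonds and hydrophobic tethers are kept throughout.

Internally the sweep runs in reverse (strongest cutoff first) so constraints
are only ever *added* to an incremental pebble game; the recorded series is
then flipped into unfolding order.  The giant rigid cluster shrinks
monotonically along the sweep; the step with the largest drop in its size is
the folded-unfolded transition, and residues whose Cα atoms sit in the giant
cluster just before the transition but are flexible just after (in no rigid
cluster of >= 4 atoms) are the unfolding weak spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..structures import ConformationalEnsemble, Structure
from .constraints import (
    BARS_TETHER,
    Constraint,
    ConstraintNetwork,
    covalent_bonds,
    detect_hydrogen_bonds,
    detect_hydrophobic_tethers,
)
from .pebble import BodyBarGame, RigidClusterDecomposition

__all__ = [
    "UnfoldingTrajectory",
    "WeakSpotProfile",
    "pebble_game_decompose",
    "thermal_unfolding",
    "transition_step",
    "detect_transition",
    "weak_spots",
    "rigidity_index",
    "ensemble_weak_spot_frequencies",
]

logger = logging.getLogger(__name__)

#: a residue counts as flexible when its Cα is in no rigid cluster of at
#: least this many atoms
SMALL_CLUSTER_ATOMS = 4


def pebble_game_decompose(network: ConstraintNetwork) -> RigidClusterDecomposition:
    """Rigid-cluster decomposition of a static constraint network."""
    pairs = np.array([(c.i, c.j) for c in network.constraints], dtype=int).reshape(-1, 2)
    game = BodyBarGame(network.n_bodies, pairs)
    for c in network.constraints:
        game.add_bars(c.i, c.j, c.bars)
    return game.decompose()


@dataclass
class UnfoldingTrajectory:
    """Ordered series of rigid-cluster decompositions along the cutoff sweep.

    ``cutoffs`` decrease from E_start to E_end; ``decomp_index[s]`` points
    into ``decompositions`` (consecutive steps share an entry when no bond
    crossed the cutoff between them).
    """

    structure: Structure
    cutoffs: np.ndarray
    decompositions: list[RigidClusterDecomposition]
    decomp_index: np.ndarray
    n_swept_constraints: int

    @property
    def n_steps(self) -> int:
        return len(self.cutoffs)

    def decomposition_at(self, step: int) -> RigidClusterDecomposition:
        return self.decompositions[self.decomp_index[step]]

    @property
    def giant_sizes(self) -> np.ndarray:
        return np.array(
            [self.decomposition_at(s).giant_size for s in range(self.n_steps)]
        )

    @property
    def transition_index(self) -> int | None:
        return detect_transition(self)


def thermal_unfolding(
    structure: Structure,
    hbonds: list[Constraint] | None = None,
    e_start: float = -0.1,
    e_end: float = -10.0,
    step: float = 0.1,
    bonds: list[Constraint] | None = None,
    tethers: list[Constraint] | None = None,
) -> UnfoldingTrajectory:
    """Sweep the hydrogen-bond cutoff and decompose the network at each step.

    ``hbonds`` (with energies) defaults to Mayo-potential detection; designed
    energy assignments can be passed instead.  ``step`` must be positive and
    ``e_start > e_end`` (both negative, kcal/mol).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if not (e_end < e_start < 0):
        raise ValueError("need e_end < e_start < 0")
    if bonds is None:
        bonds = covalent_bonds(structure)
    if tethers is None:
        tethers = detect_hydrophobic_tethers(structure, bonds=bonds)
    if hbonds is None:
        hbonds = detect_hydrogen_bonds(structure, bonds=bonds)

    n_steps = int(round((e_start - e_end) / step)) + 1
    cutoffs = e_start - step * np.arange(n_steps)

    covalent_pairs = {(c.i, c.j) for c in bonds}
    tether_by_pair = {(c.i, c.j): c for c in tethers if (c.i, c.j) not in covalent_pairs}
    swept = [
        c for c in hbonds
        if (c.i, c.j) not in covalent_pairs and c.energy < e_start
    ]
    swept.sort(key=lambda c: c.energy)  # strongest (most negative) first

    all_pairs = (
        [(c.i, c.j) for c in bonds]
        + list(tether_by_pair)
        + [(c.i, c.j) for c in swept]
    )
    game = BodyBarGame(structure.n_atoms, np.array(all_pairs, dtype=int).reshape(-1, 2))
    for c in bonds:
        game.add_bars(c.i, c.j, c.bars)
    for c in tether_by_pair.values():
        game.add_bars(c.i, c.j, c.bars)

    # reverse sweep: strongest cutoff first, bonds only ever added
    decomps: list[RigidClusterDecomposition] = []
    rev_index = np.empty(n_steps, dtype=int)
    ptr = 0
    for k in range(n_steps - 1, -1, -1):
        changed = False
        while ptr < len(swept) and swept[ptr].energy < cutoffs[k]:
            c = swept[ptr]
            # a pair holding both a tether and a hydrogen bond keeps its 2
            # tether bars throughout; the bond contributes the difference
            extra = c.bars - (BARS_TETHER if (c.i, c.j) in tether_by_pair else 0)
            game.add_bars(c.i, c.j, extra)
            ptr += 1
            changed = True
        if changed or not decomps:
            decomps.append(game.decompose())
        rev_index[k] = len(decomps) - 1
    return UnfoldingTrajectory(
        structure=structure,
        cutoffs=cutoffs,
        decompositions=decomps,
        decomp_index=rev_index,
        n_swept_constraints=len(swept),
    )


def transition_step(sizes: np.ndarray) -> int | None:
    """Transition step of a giant-cluster size series (None if flat).

    The transition is the step at which the giant cluster loses the most
    bodies in a single step; ties resolve to the earliest step.  The index
    is the first post-drop step, so the states immediately before/after the
    transition are ``index - 1`` / ``index``.
    """
    sizes = np.asarray(sizes)
    if len(sizes) < 2:
        raise ValueError("transition detection needs >= 2 sweep steps")
    drops = sizes[:-1] - sizes[1:]
    if np.all(drops <= 0):
        return None
    return int(np.argmax(drops)) + 1


def detect_transition(unfolding: UnfoldingTrajectory) -> int | None:
    """Step index of the folded-unfolded transition (None for a flat series)."""
    return transition_step(unfolding.giant_sizes)


def weak_spots(
    unfolding: UnfoldingTrajectory, transition: int | None = None
) -> set[int]:
    """Residues (0-based) that initiate unfolding at the transition.

    A residue is a weak spot when its Cα atom belongs to the giant rigid
    cluster immediately before the transition and is flexible immediately
    after — i.e. no longer in the giant cluster, and in no rigid cluster of
    >= 4 atoms.  Returns the empty set when there is no transition.
    """
    if transition is None:
        transition = detect_transition(unfolding)
    if transition is None:
        return set()
    before = unfolding.decomposition_at(transition - 1)
    after = unfolding.decomposition_at(transition)
    topo = unfolding.structure
    ca = topo.ca_indices()
    res_of = topo.atom_residue_index
    in_giant_before = before.giant_members()
    out: set[int] = set()
    for a in ca:
        if not in_giant_before[a]:
            continue
        lbl = after.labels[a]
        if after.labels[a] == after.giant_label:
            continue
        if after.sizes[lbl] < SMALL_CLUSTER_ATOMS:
            out.add(int(res_of[a]))
    return out


def rigidity_index(
    unfolding: UnfoldingTrajectory,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue rigidity index r_i (kcal/mol) and a still-rigid flag.

    For each backbone bond (N-Cα and Cα-C) of a residue, r is the cutoff at
    the first sweep step where the bond no longer lies inside any rigid
    cluster; the residue index averages its two backbone bonds.  Lower
    (more negative) r_i means the residue stays rigid longer.  Residues
    whose backbone is still rigid at the end of the sweep get r = E_end and
    are flagged.
    """
    topo = unfolding.structure
    name = np.char.strip(topo.name.astype("U8"))
    res_of = topo.atom_residue_index
    n_res = topo.n_residues
    atom_of = [dict() for _ in range(n_res)]
    for a in range(topo.n_atoms):
        atom_of[res_of[a]].setdefault(name[a], a)

    # bond -> step at which it first leaves every rigid cluster
    def bond_release_step(a: int, b: int) -> int | None:
        for s in range(unfolding.n_steps):
            d = unfolding.decomposition_at(s)
            la, lb = d.labels[a], d.labels[b]
            if la != lb or d.sizes[la] < 2:
                return s
        return None

    r = np.empty(n_res)
    still_rigid = np.zeros(n_res, dtype=bool)
    e_end = unfolding.cutoffs[-1]
    for res in range(n_res):
        atoms = atom_of[res]
        vals = []
        flags = []
        for pair in (("N", "CA"), ("CA", "C")):
            if pair[0] in atoms and pair[1] in atoms:
                s = bond_release_step(atoms[pair[0]], atoms[pair[1]])
                if s is None:
                    vals.append(e_end)
                    flags.append(True)
                else:
                    vals.append(unfolding.cutoffs[s])
                    flags.append(False)
        if not vals:
            vals = [unfolding.cutoffs[0]]
            flags = [False]
        r[res] = float(np.mean(vals))
        still_rigid[res] = all(flags)
    return r, still_rigid


@dataclass
class WeakSpotProfile:
    """Ensemble weak-spot frequencies and their rank order."""

    frequencies: np.ndarray     # per residue, in [0, 1]
    rank: np.ndarray            # residue indices, decreasing frequency
    n_snapshots: int
    n_no_transition: int = 0
    giant_series: list[np.ndarray] | None = None  # per snapshot, if collected

    def __post_init__(self) -> None:
        if np.any((self.frequencies < 0) | (self.frequencies > 1)):
            raise ValueError("frequencies must lie in [0, 1]")

    def top_fraction(self, fraction: float) -> set[int]:
        k = int(np.ceil(fraction * len(self.frequencies)))
        return set(int(i) for i in self.rank[:k])


def ensemble_weak_spot_frequencies(
    ensemble: ConformationalEnsemble,
    n_samples: int = 500,
    e_start: float = -0.1,
    e_end: float = -10.0,
    step: float = 0.1,
    constraint_source=None,
    collect_series: bool = False,
) -> WeakSpotProfile:
    """Weak-spot frequency of every residue over an ensemble of networks.

    Thermal unfolding runs on (up to) ``n_samples`` snapshots taken evenly
    along the ensemble; each snapshot contributes its weak-spot set, and a
    residue's frequency is the fraction of snapshots in which it appears.
    Snapshots without a transition contribute empty sets (counted and
    logged).  ``constraint_source`` optionally maps a snapshot Structure to
    its energy-carrying constraints (e.g. designed energies); the default
    is Mayo-potential hydrogen-bond detection.
    """
    topo = ensemble.topology
    n_res = topo.n_residues
    if n_samples >= ensemble.n_frames:
        frame_idx = np.arange(ensemble.n_frames)
    else:
        frame_idx = np.linspace(0, ensemble.n_frames - 1, n_samples).round().astype(int)
    bonds = covalent_bonds(topo)  # name-based: identical for every snapshot

    counts = np.zeros(n_res)
    n_flat = 0
    series: list[np.ndarray] | None = [] if collect_series else None
    for f in frame_idx:
        snap = topo.with_coords(ensemble.frames[f])
        hb = constraint_source(snap) if constraint_source is not None else None
        traj = thermal_unfolding(
            snap, hbonds=hb, e_start=e_start, e_end=e_end, step=step, bonds=bonds
        )
        ws = weak_spots(traj)
        if not ws and detect_transition(traj) is None:
            n_flat += 1
        for r in ws:
            counts[r] += 1
        if series is not None:
            series.append(traj.giant_sizes)
    if n_flat:
        logger.info("%d/%d snapshots showed no unfolding transition", n_flat, len(frame_idx))
    freqs = counts / len(frame_idx)
    rank = np.argsort(-freqs, kind="stable")
    return WeakSpotProfile(
        frequencies=freqs, rank=rank, n_snapshots=len(frame_idx),
        n_no_transition=n_flat, giant_series=series,
    )
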