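"""Body-bar pebble game: rank-oracle equivalence and structural properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ensembleflex.rigidity import BodyBarGame, body_bar_rank, pebble_game_decompose
from ensembleflex.rigidity.constraints import Constraint, ConstraintNetwork


def play(n, edge_bars):
    pairs = np.array([(u, v) for (u, v, _) in edge_bars], dtype=int).reshape(-1, 2)
    game = BodyBarGame(n, pairs)
    for u, v, b in edge_bars:
        game.add_bars(u, v, b)
    return game


def expand(edge_bars):
    bars = []
    for u, v, b in edge_bars:
        bars.extend([(u, v)] * b)
    return bars


def test_locked_dumbbell_is_one_cluster():
    game = play(2, [(0, 1, 6)])
    d = game.decompose()
    assert d.n_clusters == 1
    assert game.dof == 6


def test_five_bar_chain_keeps_hinge_freedom():
    game = play(3, [(0, 1, 5), (1, 2, 5)])
    assert game.dof == 8  # 6 rigid-body + 2 hinge rotations
    d = game.decompose()
    assert d.n_clusters == 3  # no pair fully locked


def test_six_ring_of_five_bar_edges_is_minimally_rigid():
    # 30 bars = 6*6 - 6: generically rigid with no redundant bar
    game = play(6, [(i, (i + 1) % 6, 5) for i in range(6)])
    assert game.n_independent == 30
    d = game.decompose()
    assert d.n_clusters == 1
    assert game.dof == 6


def test_redundant_bars_are_rejected():
    game = play(2, [(0, 1, 6)])
    assert game.add_bars(0, 1, 3) == 0  # already locked
    assert game.dof == 6


@pytest.mark.parametrize("seed", range(5))
def test_independent_count_matches_rank_oracle_random(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        n = int(rng.integers(2, 9))
        edges = {}
        for _ in range(int(rng.integers(1, 3 * n))):
            u, v = rng.integers(0, n, 2)
            if u == v:
                continue
            key = (min(u, v), max(u, v))
            edges[key] = min(edges.get(key, 0) + int(rng.integers(1, 7)), 6)
        eb = [(u, v, b) for (u, v), b in edges.items()]
        if not eb:
            continue
        game = play(n, eb)
        assert game.n_independent == body_bar_rank(n, expand(eb), rng=rng)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(st.integers(0, 5), st.integers(0, 5), st.integers(1, 6)),
    min_size=1, max_size=12,
))
def test_independent_count_matches_rank_oracle_property(edge_list):
    eb = [(u, v, b) for (u, v, b) in edge_list if u != v]
    if not eb:
        return
    game = play(6, eb)
    assert game.n_independent == body_bar_rank(6, expand(eb), rng=123)


def test_decomposition_independent_of_insertion_order():
    rng = np.random.default_rng(10)
    eb = [(0, 1, 6), (1, 2, 5), (2, 3, 5), (3, 0, 5), (0, 2, 5),
          (4, 5, 2), (2, 4, 5), (5, 6, 6), (6, 7, 3)]
    ref = None
    for shuffle in range(10):
        order = rng.permutation(len(eb))
        game = play(8, [eb[i] for i in order])
        labels = game.decompose().labels
        canon = _canonical(labels)
        if ref is None:
            ref = canon
        assert canon == ref


def _canonical(labels):
    seen = {}
    out = []
    for l in labels:
        out.append(seen.setdefault(l, len(seen)))
    return tuple(out)


def test_removing_a_constraint_never_enlarges_clusters():
    rng = np.random.default_rng(11)
    eb = [(0, 1, 5), (1, 2, 5), (2, 0, 5), (2, 3, 6), (3, 4, 5), (4, 0, 5),
          (1, 3, 2), (4, 2, 5)]
    full = play(5, eb).decompose()
    for drop in range(len(eb)):
        sub = play(5, [e for k, e in enumerate(eb) if k != drop]).decompose()
        # every cluster of the reduced network is contained in a full-network cluster
        for lbl in range(sub.n_clusters):
            members = np.flatnonzero(sub.labels == lbl)
            assert len(set(full.labels[members])) == 1


def test_labels_partition_bodies():
    game = play(6, [(0, 1, 6), (2, 3, 5), (4, 5, 2)])
    d = game.decompose()
    assert d.labels.min() >= 0
    assert d.sizes.sum() == 6
    assert d.dof >= 6


def test_network_decomposition_entry_point():
    net = ConstraintNetwork(
        n_bodies=3,
        constraints=[Constraint("covalent-locked", 0, 1, 6),
                     Constraint("covalent-rotatable", 1, 2, 5)],
        e_cut=-1.0,
    )
    d = pebble_game_decompose(net)
    assert d.labels[0] == d.labels[1] != d.labels[2]
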