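"""(6,6) body-bar pebble game: rigid-cluster decomposition of bar networks.

Every atom is a rigid body carrying 6 pebbles (its 6 degrees of freedom).
A bar between two bodies is inserted as an independent constraint when 7
pebbles can be gathered on its endpoints — one pebble then pays for the bar
and the bar is recorded as a directed edge; otherwise the bar is redundant.
Independent-bar counts of this game equal the generic rank of the body-bar
rigidity matrix (Tay's theorem), which the test-suite oracle checks
numerically.

Rigid clusters are read off the final pebble configuration: after gathering
6 pebbles on a seed body and pinning them, exactly the bodies that cannot
reach any free pebble through the directed network are mutually rigid with
the seed.  Mutual rigidity of bodies is transitive, so clusters partition
the bodies.

The inner loops are numba-compiled; the per-pair bar-orientation count is a
dense (n, n) int16 matrix, which bounds practical problem sizes to a few
thousand bodies (ample for per-snapshot protein networks at desk scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["BodyBarGame", "RigidClusterDecomposition"]

K_PEBBLES = 6  # pebbles per body = DOF of a free rigid body


@njit(cache=True)
def _find_pebble(indptr, indices, count, pebbles, visited, parent, stamp, u, avoid):
    """DFS from ``u`` for a free pebble (not on ``u``/``avoid``); move it to u.

    Returns True and updates the game state (pebble counts, edge
    orientations along the augmenting path) on success.
    """
    n = len(pebbles)
    stack = np.empty(n, dtype=np.int64)
    top = 0
    stack[top] = u
    top += 1
    visited[u] = stamp
    parent[u] = -1
    while top > 0:
        top -= 1
        x = stack[top]
        if x != u and x != avoid and pebbles[x] > 0:
            # move pebble from x back to u, reversing the path edges
            b = x
            a = parent[b]
            while a != -1:
                count[a, b] -= 1
                count[b, a] += 1
                b = a
                a = parent[b]
            pebbles[x] -= 1
            pebbles[u] += 1
            return True
        for idx in range(indptr[x], indptr[x + 1]):
            y = indices[idx]
            if visited[y] != stamp and count[x, y] > 0:
                visited[y] = stamp
                parent[y] = x
                stack[top] = y
                top += 1
    return False


@njit(cache=True)
def _add_bars(indptr, indices, count, pebbles, visited, parent, stamp, u, v, bars):
    """Insert ``bars`` bars between u and v; return (accepted, new stamp)."""
    accepted = 0
    if u == v:
        return accepted, stamp  # self-bars are always redundant
    for _ in range(bars):
        while pebbles[u] + pebbles[v] < K_PEBBLES + 1:
            stamp += 1
            moved = _find_pebble(indptr, indices, count, pebbles, visited, parent, stamp, u, v)
            if not moved:
                stamp += 1
                moved = _find_pebble(
                    indptr, indices, count, pebbles, visited, parent, stamp, v, u
                )
            if not moved:
                break
        if pebbles[u] + pebbles[v] >= K_PEBBLES + 1:
            if pebbles[u] > 0:
                pebbles[u] -= 1
                count[u, v] += 1
            else:
                pebbles[v] -= 1
                count[v, u] += 1
            accepted += 1
        else:
            break  # further bars on this pair are redundant too
    return accepted, stamp


@njit(cache=True)
def _cluster_of(indptr, indices, count, pebbles, visited, parent, stamp, seed):
    """Membership mask of the rigid cluster containing ``seed``."""
    n = len(pebbles)
    # gather 6 pebbles on the seed (always possible in a (6,6)-sparse state)
    while pebbles[seed] < K_PEBBLES:
        stamp += 1
        if not _find_pebble(indptr, indices, count, pebbles, visited, parent, stamp, seed, -1):
            break
    # reverse reachability: bodies with a directed path to a free pebble
    reach = np.zeros(n, dtype=np.bool_)
    queue = np.empty(n, dtype=np.int64)
    head = 0
    tail = 0
    for x in range(n):
        if x != seed and pebbles[x] > 0:
            reach[x] = True
            queue[tail] = x
            tail += 1
    while head < tail:
        b = queue[head]
        head += 1
        for idx in range(indptr[b], indptr[b + 1]):
            a = indices[idx]
            if not reach[a] and count[a, b] > 0:
                reach[a] = True
                queue[tail] = a
                tail += 1
    member = np.empty(n, dtype=np.bool_)
    for x in range(n):
        member[x] = not reach[x]
    member[seed] = True
    return member, stamp


@njit(cache=True)
def _decompose(indptr, indices, count, pebbles, visited, parent, stamp, order):
    """Label every body with its rigid-cluster id, scanning ``order``."""
    n = len(pebbles)
    labels = np.full(n, -1, dtype=np.int64)
    next_label = 0
    for k in range(len(order)):
        s = order[k]
        if labels[s] != -1:
            continue
        member, stamp = _cluster_of(indptr, indices, count, pebbles, visited, parent, stamp, s)
        for x in range(n):
            if member[x] and labels[x] == -1:
                labels[x] = next_label
        next_label += 1
    return labels, stamp


@dataclass
class RigidClusterDecomposition:
    """Partition of bodies into rigid clusters.

    ``labels[i]`` is the cluster id of body i; ``sizes[c]`` its body count;
    ``giant_label`` identifies the largest cluster; ``dof`` is the total
    remaining degrees of freedom (>= 6 for any nonempty network).
    """

    labels: np.ndarray
    sizes: np.ndarray
    dof: int

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def giant_label(self) -> int:
        return int(np.argmax(self.sizes))

    @property
    def giant_size(self) -> int:
        return int(self.sizes.max()) if len(self.sizes) else 0

    @property
    def floppy_modes(self) -> int:
        return self.dof - 6

    def giant_members(self) -> np.ndarray:
        return self.labels == self.giant_label


class BodyBarGame:
    """Incremental (6,6) pebble game over a fixed set of candidate pairs.

    ``pairs`` is the superset of body pairs that may ever receive bars;
    bars are inserted with :meth:`add_bars` (insertion order never changes
    the final decomposition, only which individual bars are flagged
    redundant).
    """

    def __init__(self, n_bodies: int, pairs: np.ndarray):
        self.n = int(n_bodies)
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        if len(pairs) and (pairs.min() < 0 or pairs.max() >= self.n):
            raise ValueError("pair index out of range")
        # symmetric CSR adjacency over unique pairs
        both = np.vstack([pairs, pairs[:, ::-1]]) if len(pairs) else pairs
        if len(both):
            both = np.unique(both, axis=0)
            both = both[both[:, 0] != both[:, 1]]
        counts = np.bincount(both[:, 0], minlength=self.n) if len(both) else np.zeros(self.n, int)
        self.indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self.indices = (both[np.argsort(both[:, 0], kind="stable"), 1].astype(np.int64)
                        if len(both) else np.empty(0, dtype=np.int64))
        self.count = np.zeros((self.n, self.n), dtype=np.int16)
        self.pebbles = np.full(self.n, K_PEBBLES, dtype=np.int64)
        self._visited = np.zeros(self.n, dtype=np.int64)
        self._parent = np.full(self.n, -1, dtype=np.int64)
        self._stamp = 0
        self.n_independent = 0

    def add_bars(self, u: int, v: int, bars: int) -> int:
        """Insert bars between bodies u and v; returns how many were independent."""
        accepted, self._stamp = _add_bars(
            self.indptr, self.indices, self.count, self.pebbles,
            self._visited, self._parent, self._stamp, int(u), int(v), int(bars),
        )
        self.n_independent += accepted
        return accepted

    @property
    def dof(self) -> int:
        """Remaining degrees of freedom = free pebbles."""
        return int(self.pebbles.sum())

    def cluster_of(self, seed: int) -> np.ndarray:
        member, self._stamp = _cluster_of(
            self.indptr, self.indices, self.count, self.pebbles,
            self._visited, self._parent, self._stamp, int(seed),
        )
        return member

    def decompose(self, order: np.ndarray | None = None) -> RigidClusterDecomposition:
        if order is None:
            order = np.arange(self.n, dtype=np.int64)
        labels, self._stamp = _decompose(
            self.indptr, self.indices, self.count, self.pebbles,
            self._visited, self._parent, self._stamp,
            np.asarray(order, dtype=np.int64),
        )
        sizes = np.bincount(labels)
        return RigidClusterDecomposition(labels=labels, sizes=sizes, dof=self.dof)
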