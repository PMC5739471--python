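"""Numeric oracle: generic rank of the body-bar rigidity matrix.

For a multigraph of rigid bodies joined by bars, the number of independent
constraints equals the rank of the rigidity matrix at generic bar
attachments (Tay's theorem).  Each bar between bodies u and v, attached at
points ``a_u``/``a_v``, constrains the relative velocity of its endpoints
along the bar direction; with body velocities ``(v, w)`` (translation,
angular) the row reads ``[d, a_u x d]`` on u and ``[-d, -(a_v x d)]`` on v,
where ``d = a_u - a_v``.

This module exists purely to validate the pebble game on small graphs; the
pebble game never calls it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["body_bar_rank", "body_bar_dof"]


def body_bar_rank(
    n_bodies: int,
    bars: list[tuple[int, int]] | np.ndarray,
    rng: np.random.Generator | int | None = None,
    trials: int = 2,
) -> int:
    """Generic rank of the body-bar rigidity matrix.

    ``bars`` lists one entry per bar (repeat a pair for multiple bars).
    Random attachments are resampled ``trials`` times and the maximum rank
    taken, guarding against accidental degeneracy.
    """
    bars = np.asarray(bars, dtype=int).reshape(-1, 2)
    bars = bars[bars[:, 0] != bars[:, 1]]  # self-bars never constrain
    if len(bars) == 0:
        return 0
    rng = np.random.default_rng(rng)
    best = 0
    for _ in range(trials):
        M = np.zeros((len(bars), 6 * n_bodies))
        for r, (u, v) in enumerate(bars):
            a_u = rng.uniform(-1.0, 1.0, 3)
            a_v = rng.uniform(-1.0, 1.0, 3)
            d = a_u - a_v
            M[r, 6 * u:6 * u + 3] = d
            M[r, 6 * u + 3:6 * u + 6] = np.cross(a_u, d)
            M[r, 6 * v:6 * v + 3] = -d
            M[r, 6 * v + 3:6 * v + 6] = -np.cross(a_v, d)
        best = max(best, int(np.linalg.matrix_rank(M, tol=1e-8)))
    return best


def body_bar_dof(n_bodies: int, bars, rng=None) -> int:
    """Generic degrees of freedom: 6 per body minus independent constraints."""
    return 6 * n_bodies - body_bar_rank(n_bodies, bars, rng=rng)
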