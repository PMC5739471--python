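"""Least-squares superposition of ensemble frames (Kabsch algorithm).

The rotation minimising the RMSD of a selected atom subset is computed from
the SVD of the cross-covariance of centred coordinates, with the usual
determinant correction to exclude reflections.
"""

from __future__ import annotations

import numpy as np

from .structures import ConformationalEnsemble

__all__ = ["kabsch", "apply_transform", "superpose", "rmsd"]


class UnderdeterminedSuperpositionError(ValueError):
    """Fewer than 3 atoms were selected for superposition."""


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid transform taking ``mobile`` onto ``target``.

    Returns ``(R, t_mobile, t_target)`` such that
    ``(mobile - t_mobile) @ R.T + t_target`` minimises the least-squares
    deviation.  Both inputs are (M, 3).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2:
        raise ValueError("mobile and target must both be (M, 3)")
    if len(mobile) < 3:
        raise UnderdeterminedSuperpositionError(
            f"superposition needs >= 3 atoms, got {len(mobile)}"
        )
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cm, ct


def apply_transform(
    coords: np.ndarray, R: np.ndarray, t_mobile: np.ndarray, t_target: np.ndarray
) -> np.ndarray:
    return (coords - t_mobile) @ R.T + t_target


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(np.sqrt((diff ** 2).sum(axis=-1).mean()))


def superpose(
    ensemble: ConformationalEnsemble,
    selection: np.ndarray | None = None,
    reference: int | str = "mean",
) -> ConformationalEnsemble:
    """Superpose every frame onto a common reference.

    Parameters
    ----------
    selection:
        Boolean mask or integer indices of the atoms used for the fit
        (default: Cα atoms; the transform is applied to all atoms).
    reference:
        ``"mean"`` (default): fit to frame 0, take the mean, then fit every
        frame to that mean (one iteration).  An integer selects a fixed
        reference frame.

    A single-frame ensemble is returned unchanged.
    """
    if ensemble.n_frames == 1:
        return ConformationalEnsemble(
            topology=ensemble.topology,
            frames=ensemble.frames.copy(),
            frame_ids=list(ensemble.frame_ids),
            alignment={"reference": "self", "n_selected": ensemble.n_atoms},
        )

    if selection is None:
        sel = ensemble.topology.ca_indices()
        if len(sel) == 0:
            sel = np.arange(ensemble.n_atoms)
    else:
        sel = np.asarray(selection)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
    if len(sel) < 3:
        raise UnderdeterminedSuperpositionError(
            f"superposition needs >= 3 selected atoms, got {len(sel)}"
        )

    frames = ensemble.frames
    if reference == "mean":
        ref = _fit_all(frames, sel, frames[0][sel]).mean(axis=0)[sel]
        ref_label = "mean"
    else:
        ref = frames[int(reference)][sel]
        ref_label = int(reference)
    fitted = _fit_all(frames, sel, ref)
    return ConformationalEnsemble(
        topology=ensemble.topology,
        frames=fitted,
        frame_ids=list(ensemble.frame_ids),
        alignment={"reference": ref_label, "n_selected": int(len(sel))},
    )


def _fit_all(frames: np.ndarray, sel: np.ndarray, ref_sel: np.ndarray) -> np.ndarray:
    out = np.empty_like(frames)
    for k in range(frames.shape[0]):
        R, tm, tt = kabsch(frames[k][sel], ref_sel)
        out[k] = apply_transform(frames[k], R, tm, tt)
    return out
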