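"""Essential dynamics: PCA of ensemble coordinates, slow-mode profiles, hinges.

PCA diagonalises the covariance of the superposed coordinates; in the MD
convention the largest-variance principal components are the "slowest"
collective modes.  The per-residue normalized squared displacement carried
by the first k modes is the slow-mode profile: maxima mark regions swept by
global motions, local minima mark immobilized hinge positions that
coordinate the collective changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .structures import ConformationalEnsemble

__all__ = ["ModeSpectrum", "SlowModeProfile", "pca", "slow_mode_profile", "identify_hinges"]

#: first/last residues of a profile never count as hinges (termini are
#: trivially mobile / ill-defined)
TERMINAL_EXCLUSION = 2


@dataclass
class ModeSpectrum:
    """PCA eigenpairs of the selected coordinates.

    ``eigvecs`` columns are orthonormal 3S-vectors; ``eigvals`` (Å^2) are
    sorted descending and sum to the total variance of the selected
    coordinates.
    """

    eigvals: np.ndarray        # (m,) descending
    eigvecs: np.ndarray        # (3S, m)
    mean: np.ndarray           # (S, 3)
    selection: np.ndarray      # atom indices used

    @property
    def n_sites(self) -> int:
        return len(self.mean)

    def displacement_profile(self, mode: int) -> np.ndarray:
        """Per-site squared displacement |u_i|^2 of one mode (sums to 1)."""
        u = self.eigvecs[:, mode].reshape(-1, 3)
        return (u ** 2).sum(axis=1)

    def project(self, frames: np.ndarray) -> np.ndarray:
        """Project (N, S, 3) frames onto the modes -> (N, m) scores."""
        x = frames.reshape(frames.shape[0], -1) - self.mean.reshape(-1)[None, :]
        return x @ self.eigvecs


@dataclass
class SlowModeProfile:
    """Per-residue normalized squared displacement over the first k modes."""

    values: np.ndarray
    k_modes: int
    weighting: str

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")
        if abs(self.values.sum() - 1.0) > 1e-8:
            raise ValueError("profile must be normalized to sum 1")


def pca(
    ensemble: ConformationalEnsemble, selection: np.ndarray | None = None
) -> ModeSpectrum:
    """PCA of the selected coordinates (default Cα) about the ensemble mean."""
    ensemble.require_frames(2, "PCA")
    if selection is None:
        sel = ensemble.topology.ca_indices()
        if len(sel) == 0:
            sel = np.arange(ensemble.n_atoms)
    else:
        sel = np.asarray(selection)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
    x = ensemble.frames[:, sel, :].reshape(ensemble.n_frames, -1)
    mean = x.mean(axis=0)
    centered = x - mean[None, :]
    cov = (centered.T @ centered) / (ensemble.n_frames - 1)
    vals, vecs = eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    return ModeSpectrum(
        eigvals=vals, eigvecs=vecs, mean=mean.reshape(-1, 3), selection=sel
    )


def slow_mode_profile(
    spectrum: ModeSpectrum, k_modes: int = 3, weighting: str = "eigenvalue"
) -> SlowModeProfile:
    """Combine the first ``k_modes`` displacement profiles into one.

    ``weighting="eigenvalue"`` weights each mode by its variance (default);
    ``"uniform"`` averages the normalized per-mode profiles.  The result is
    normalized to sum 1 and is invariant to eigenvector sign flips.
    """
    if k_modes < 1:
        raise ValueError("k_modes must be >= 1")
    if k_modes > spectrum.eigvecs.shape[1]:
        raise ValueError(
            f"k_modes={k_modes} exceeds available modes {spectrum.eigvecs.shape[1]}"
        )
    combined = np.zeros(spectrum.n_sites)
    for m in range(k_modes):
        prof = spectrum.displacement_profile(m)
        if weighting == "eigenvalue":
            combined += spectrum.eigvals[m] * prof
        elif weighting == "uniform":
            combined += prof
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
    total = combined.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: zero total displacement")
    return SlowModeProfile(values=combined / total, k_modes=k_modes, weighting=weighting)


def identify_hinges(
    profile: SlowModeProfile | np.ndarray,
    window: int = 5,
    quantile: float = 0.1,
) -> list[int]:
    """Hinge residues: sliding-window local minima below a profile quantile.

    A residue qualifies when its profile value is the minimum of the
    centered window around it AND falls below the given quantile of the
    whole profile.  The first and last ``TERMINAL_EXCLUSION`` residues are
    ineligible.  Returns residues ranked ascending by profile value.
    """
    values = profile.values if isinstance(profile, SlowModeProfile) else np.asarray(profile)
    n = len(values)
    if n < window:
        raise ValueError(f"profile length {n} < window {window}")
    half = window // 2
    threshold = np.quantile(values, quantile)
    hinges = []
    for i in range(TERMINAL_EXCLUSION, n - TERMINAL_EXCLUSION):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if values[i] <= values[lo:hi].min() and values[i] <= threshold:
            hinges.append(i)
    hinges.sort(key=lambda i: values[i])
    return hinges
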