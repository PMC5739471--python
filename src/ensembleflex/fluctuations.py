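"""Per-residue fluctuation statistics over conformational ensembles.

Three statistics live here:

* **RMSF / B-factor** — root-mean-square fluctuation of each residue's Cα
  about the ensemble mean, and the crystallographic B-factor equivalent
  ``B = (8 pi^2 / 3) RMSF^2``.
* **Distance-fluctuation force constants** — for each residue i, the mean
  distance ``d_i`` to all other residues (or atoms) is tracked over frames
  and converted to an effective force constant ``k_i = 3 k_B T / Var(d_i)``.
  Rigid, allosterically central sites fluctuate little in their mean
  distances and so carry large force constants; hinge centers appear as
  sharp peaks.  The statistic is built from internal distances only and is
  therefore invariant under global rotation/translation of every frame.
* **Residue depth** — mean distance of a residue's atoms to the nearest
  solvent-accessible surface point, averaged over the ensemble; the surface
  is approximated by rolling-probe-accessible dots on atom spheres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structures import ConformationalEnsemble, Structure

__all__ = [
    "BOLTZMANN_KCAL",
    "rmsf",
    "bfactor",
    "ForceConstantProfile",
    "distance_fluctuation_force_constants",
    "DepthProfile",
    "residue_depth",
]

BOLTZMANN_KCAL = 0.0019872041  # kcal mol^-1 K^-1

#: variance floor (Å^2) below which a site counts as rigid, and the capped
#: force constant (kcal mol^-1 Å^-2) such sites are assigned
VARIANCE_FLOOR = 1e-8
FORCE_CONSTANT_CAP = 1e6

_VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "P": 1.8}
_DEFAULT_VDW = 1.7


def rmsf(ensemble: ConformationalEnsemble, selection: np.ndarray | None = None) -> np.ndarray:
    """Per-residue RMSF (Å) of the selected atoms (default Cα).

    ``RMSF_i = sqrt( mean_t |r_i(t) - <r_i>|^2 )``.  The ensemble is assumed
    superposed; at least 2 frames are required.
    """
    ensemble.require_frames(2, "RMSF")
    if selection is None:
        sel = ensemble.topology.ca_indices()
        if len(sel) == 0:
            sel = np.arange(ensemble.n_atoms)
    else:
        sel = np.asarray(selection)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
    x = ensemble.frames[:, sel, :]
    dev = x - x.mean(axis=0, keepdims=True)
    msf = (dev ** 2).sum(axis=-1).mean(axis=0)
    return np.sqrt(msf)


def bfactor(rmsf_profile: np.ndarray) -> np.ndarray:
    """Computed B-factors (Å^2): ``B = (8 pi^2 / 3) RMSF^2``."""
    r = np.asarray(rmsf_profile, dtype=float)
    return (8.0 * np.pi ** 2 / 3.0) * r ** 2


@dataclass
class ForceConstantProfile:
    """Per-residue effective force constants k_i (kcal mol^-1 Å^-2).

    ``capped`` flags residues whose distance variance fell below the rigid
    floor; their k_i is the cap value, not a measured number.
    """

    k: np.ndarray
    capped: np.ndarray
    temperature: float
    representation: str

    def __post_init__(self) -> None:
        if np.any(self.k <= 0):
            raise ValueError("force constants must be positive")


def distance_fluctuation_force_constants(
    ensemble: ConformationalEnsemble,
    representation: str = "ca",
    temperature: float = 300.0,
    exclude_neighbors: int = 1,
) -> ForceConstantProfile:
    """Distance-fluctuation force constants ``k_i = 3 k_B T / Var(d_i)``.

    For every frame the instantaneous mean distance ``d_i`` from site i to
    all eligible sites j is computed; its variance over frames (sample
    variance, N-1) is inverted into a force constant.  Chain neighbors
    within ``exclude_neighbors`` residues of i (and i itself) are excluded,
    since those distances are nearly constant.

    representation:
        ``"ca"`` — sites are Cα atoms, one per residue.
        ``"allatom"`` — d is computed per atom against all atoms of
        non-neighboring residues, then k is averaged within each residue.

    Superposition is not required: the statistic depends on internal
    distances only.
    """
    ensemble.require_frames(2, "distance-fluctuation analysis")
    topo = ensemble.topology
    n_res = topo.n_residues
    if n_res < 2 + 2 * exclude_neighbors:
        raise ValueError("too few residues for neighbor-excluded distance statistic")
    kBT = BOLTZMANN_KCAL * temperature

    if representation == "ca":
        sel = topo.ca_indices()
        if len(sel) != n_res:
            raise ValueError("ca representation requires one Cα per residue")
        site_res = np.arange(n_res)
        d_i = _mean_distance_series(ensemble.frames[:, sel, :], site_res, exclude_neighbors)
        var = d_i.var(axis=0, ddof=1)
        k_site, capped = _invert_variance(var, kBT)
        return ForceConstantProfile(k_site, capped, temperature, representation)

    if representation == "allatom":
        site_res = topo.atom_residue_index
        d_i = _mean_distance_series(ensemble.frames, site_res, exclude_neighbors)
        var = d_i.var(axis=0, ddof=1)
        k_atom, capped_atom = _invert_variance(var, kBT)
        k_res = np.empty(n_res)
        capped_res = np.empty(n_res, dtype=bool)
        for r in range(n_res):
            mask = site_res == r
            k_res[r] = k_atom[mask].mean()
            capped_res[r] = capped_atom[mask].all()
        return ForceConstantProfile(k_res, capped_res, temperature, representation)

    raise ValueError(f"unknown representation {representation!r}")


def _mean_distance_series(
    frames: np.ndarray, site_res: np.ndarray, exclude_neighbors: int
) -> np.ndarray:
    """(N, S) series of mean distances d_i per frame, neighbor-excluded."""
    n_frames, n_sites, _ = frames.shape
    eligible = np.abs(site_res[:, None] - site_res[None, :]) > exclude_neighbors
    counts = eligible.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("some sites have no eligible partners after neighbor exclusion")
    out = np.empty((n_frames, n_sites))
    # frame-chunked to keep the (S, S) distance matrix memory bounded
    for t in range(n_frames):
        diff = frames[t][:, None, :] - frames[t][None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))
        out[t] = (dist * eligible).sum(axis=1) / counts
    return out


def _invert_variance(var: np.ndarray, kBT: float) -> tuple[np.ndarray, np.ndarray]:
    capped = var < VARIANCE_FLOOR
    k = np.where(capped, FORCE_CONSTANT_CAP, 3.0 * kBT / np.where(capped, 1.0, var))
    return k, capped


# ---------------------------------------------------------------------------
# Residue depth
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Per-residue depth (Å), ensemble-averaged; 0 means at the surface."""

    depth: np.ndarray
    probe_radius: float

    def __post_init__(self) -> None:
        if np.any(self.depth < -1e-9):
            raise ValueError("depth must be non-negative")


def residue_depth(
    ensemble_or_structure: ConformationalEnsemble | Structure,
    probe_radius: float = 1.4,
    n_dots: int = 128,
    frame_stride: int = 1,
) -> DepthProfile:
    """Residue depth from a dot-surface approximation.

    Each atom sphere (van der Waals radius + probe) is covered with
    ``n_dots`` quasi-uniform dots; a dot is solvent-accessible when it lies
    outside every other atom's probe-expanded sphere.  An atom's depth is
    its distance to the nearest accessible dot minus its own expanded
    radius (clipped at 0, so surface atoms have depth 0); residue depth
    averages over the residue's atoms, and ensembles average over frames
    (``frame_stride`` subsamples frames for speed).
    """
    if isinstance(ensemble_or_structure, Structure):
        topo = ensemble_or_structure
        frames = ensemble_or_structure.coords[None, :, :]
    else:
        topo = ensemble_or_structure.topology
        frames = ensemble_or_structure.frames[::frame_stride]
    if topo.n_atoms == 0:
        raise ValueError("empty structure")

    radii = np.array(
        [_VDW_RADII.get(str(e).strip().upper(), _DEFAULT_VDW) for e in topo.element]
    )
    expanded = radii + probe_radius
    dots_unit = _fibonacci_sphere(n_dots)
    res_of_atom = topo.atom_residue_index

    depth_sum = np.zeros(topo.n_residues)
    for frame in frames:
        atom_depth = _frame_atom_depth(frame, expanded, dots_unit)
        for r in range(topo.n_residues):
            depth_sum[r] += atom_depth[res_of_atom == r].mean()
    depth = depth_sum / len(frames)
    return DepthProfile(depth=np.clip(depth, 0.0, None), probe_radius=probe_radius)


def _frame_atom_depth(
    coords: np.ndarray, expanded: np.ndarray, dots_unit: np.ndarray
) -> np.ndarray:
    n = len(coords)
    # candidate dots on every atom's expanded sphere
    dots = coords[:, None, :] + expanded[:, None, None] * dots_unit[None, :, :]
    dots = dots.reshape(-1, 3)
    tree = cKDTree(coords)
    # a dot is buried if strictly inside some OTHER atom's expanded sphere
    max_r = expanded.max()
    neighbor_lists = tree.query_ball_point(dots, max_r)
    owner = np.repeat(np.arange(n), dots_unit.shape[0])
    accessible = np.ones(len(dots), dtype=bool)
    for d, nbrs in enumerate(neighbor_lists):
        for a in nbrs:
            if a == owner[d]:
                continue
            if np.linalg.norm(dots[d] - coords[a]) < expanded[a] - 1e-9:
                accessible[d] = False
                break
    acc_dots = dots[accessible]
    if len(acc_dots) == 0:
        # fully occluded surface (cannot happen for finite clusters)
        return np.zeros(n)
    dot_tree = cKDTree(acc_dots)
    dist, _ = dot_tree.query(coords)
    return np.clip(dist - expanded, 0.0, None)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere dots (golden-angle spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
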