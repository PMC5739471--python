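"""Synthetic structures and conformational ensembles with known ground truth.

The generator builds a two-domain toy protein — two compact serpentine
lattices of residues joined by an extended linker — plus an anisotropic
network model (ANM) over its Cα atoms.  Ensembles are drawn from the exact
ANM Gaussian, so every downstream statistic (RMSF, force constants, PCA
modes) has an analytic oracle, and the linker is a hinge by construction.
For the rigidity analyses, a designed set of hydrogen-bond-like constraints
carries a bimodal energy spectrum in which a chosen "weak region" dissolves
first during thermal unfolding.

The lattice geometry is deliberate: consecutive Cα atoms sit 3.8 Å apart
(both along rows and at turns), rows and layers are spaced so that no two
carbon atoms of different residues fall inside the hydrophobic-tether
cutoff, and each residue carries an idealized backbone (N, CA, C, O), an
amide hydrogen and a short pseudo side-chain carbon (CB).  Domain rigidity
therefore rests entirely on the designed noncovalent constraints, which is
what makes the unfolding ground truth exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structures import ConformationalEnsemble, Structure

__all__ = [
    "ToyProteinSpec",
    "ElasticNetworkModel",
    "GenerationError",
    "ConnectivityError",
    "build_toy_structure",
    "anm_build",
    "anm_msf",
    "sample_ensemble",
    "assign_constraint_energies",
    "ground_truth",
]

_CA_SPACING = 3.8  # Å, consecutive Cα distance
_ATOM_NAMES = ("N", "CA", "C", "O", "CB", "H")
_ATOM_ELEMENTS = ("N", "C", "C", "O", "C", "H")


class GenerationError(ValueError):
    """Toy-structure generation produced degenerate geometry."""


class ConnectivityError(ValueError):
    """The elastic network is disconnected at the chosen cutoff."""


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class ToyProteinSpec:
    """Blueprint of the two-domain toy protein.

    ``domain_sizes`` are residues per domain; each domain is a serpentine
    lattice with ``row_length`` residues per row and ``rows_per_layer`` rows
    per layer.  ``weak_region`` is a 0-based inclusive residue range whose
    noncovalent constraints receive weak energies.
    """

    domain_sizes: tuple[int, ...] = (24, 16)
    linker_length: int = 5
    row_length: int = 6
    rows_per_layer: int = 2
    weak_region: tuple[int, int] | None = (18, 22)
    jitter: float = 0.05          # Å, seeded positional jitter (breaks lattice symmetry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_residues < 10:
            raise ParameterError("toy protein needs >= 10 residues")
        if self.weak_region is not None:
            a, b = self.weak_region
            if not (0 <= a <= b < self.total_residues):
                raise ParameterError(
                    f"weak_region {self.weak_region} outside 0..{self.total_residues - 1}"
                )

    @property
    def total_residues(self) -> int:
        return sum(self.domain_sizes) + self.linker_length * (len(self.domain_sizes) - 1)

    @property
    def linker_ranges(self) -> list[tuple[int, int]]:
        """0-based inclusive residue ranges of the linkers."""
        out = []
        pos = 0
        for size in self.domain_sizes[:-1]:
            pos += size
            out.append((pos, pos + self.linker_length - 1))
            pos += self.linker_length
        return out

    @property
    def weak_residues(self) -> list[int]:
        if self.weak_region is None:
            return []
        a, b = self.weak_region
        return list(range(a, b + 1))


def _serpentine(
    n: int, row_len: int, rows_per_layer: int, origin: np.ndarray, sign: int
) -> np.ndarray:
    """Cα positions of a compact serpentine lattice starting at ``origin``.

    Rows run along x (alternating direction, overall direction ``sign``),
    rows stack along y, layers along z, all at the Cα spacing so chain
    continuity holds at every turn.
    """
    s = _CA_SPACING
    pos = np.empty((n, 3))
    for k in range(n):
        row, col = divmod(k, row_len)
        layer, row_in_layer = divmod(row, rows_per_layer)
        x = col if row % 2 == 0 else row_len - 1 - col
        # serpentine in y as well, so layer changes step only in z
        y = row_in_layer if layer % 2 == 0 else rows_per_layer - 1 - row_in_layer
        pos[k] = origin + np.array([sign * x * s, y * s, layer * s])
    return pos


def _ca_trace(spec: ToyProteinSpec) -> np.ndarray:
    """Cα positions of domains plus extended linkers, chained end to end.

    Each linker leaves its domain along x on the side where the serpentine
    exits, and the next domain continues growing in that direction, so
    domains and linkers never overlap.
    """
    s = _CA_SPACING
    coords: list[np.ndarray] = []
    cursor = np.zeros(3)
    sign = 1
    for d, size in enumerate(spec.domain_sizes):
        dom = _serpentine(size, spec.row_length, spec.rows_per_layer, cursor, sign)
        coords.append(dom)
        if d < len(spec.domain_sizes) - 1:
            n_rows = -(-size // spec.row_length)
            if (n_rows - 1) % 2 == 1:          # last row reversed: exit on start side
                sign = -sign
            # slightly zigzagged extended linker: keeps consecutive Cα at the
            # chain spacing but avoids a collinear segment (a collinear linker
            # would leave a free torsion of the next domain in the ANM)
            dy = 0.8
            dx = sign * float(np.sqrt(s ** 2 - dy ** 2))
            point = dom[-1].copy()
            linker = np.empty((spec.linker_length, 3))
            for k in range(spec.linker_length):
                point = point + np.array([dx, dy if k % 2 == 0 else -dy, 0.0])
                linker[k] = point
            coords.append(linker)
            cursor = point + np.array([dx, dy if spec.linker_length % 2 == 0 else -dy, 0.0])
    return np.vstack(coords)


def build_toy_structure(spec: ToyProteinSpec) -> Structure:
    """Build the toy protein: backbone + amide H + pseudo side-chain CB.

    Deterministic for a given ``spec.seed``.  Raises :class:`GenerationError`
    if any two atoms come closer than 0.5 Å.
    """
    rng = np.random.default_rng(spec.seed)
    ca = _ca_trace(spec)
    n = len(ca)
    ca = ca + rng.normal(scale=spec.jitter, size=ca.shape)
    centroid = ca.mean(axis=0)

    # peptide atoms are interpolated along the actual Cα-Cα segments, so the
    # geometry stays sane at serpentine turns
    segs = np.diff(ca, axis=0)                       # seg[i] = CA(i+1) - CA(i)
    coords = []
    for i in range(n):
        seg_fwd = segs[i] if i < n - 1 else segs[-1]
        seg_bwd = segs[i - 1] if i > 0 else segs[0]
        u_fwd = _perpendicular(seg_fwd / np.linalg.norm(seg_fwd))
        u_bwd = _perpendicular(seg_bwd / np.linalg.norm(seg_bwd))
        # carbonyl O and amide H sit on opposite sides of the same chain-normal
        w_fwd = np.cross(seg_fwd / np.linalg.norm(seg_fwd), u_fwd)
        w_bwd = np.cross(seg_bwd / np.linalg.norm(seg_bwd), u_bwd)
        t = _chain_direction(ca, i)
        outward = ca[i] - centroid
        outward -= outward.dot(t) * t
        norm = np.linalg.norm(outward)
        outward = outward / norm if norm > 1e-6 else u_fwd
        n_pos = ca[i] - 0.34 * seg_bwd if i > 0 else ca[i] - 0.34 * seg_fwd
        c_pos = ca[i] + 0.34 * seg_fwd if i < n - 1 else ca[i] + 0.34 * seg_bwd
        o_pos = c_pos + 1.23 * w_fwd
        cb_pos = ca[i] + 0.8 * outward
        h_pos = n_pos - 0.98 * w_bwd
        coords.append(np.vstack([n_pos, ca[i], c_pos, o_pos, cb_pos, h_pos]))
    coords = np.vstack(coords)

    tree = cKDTree(coords)
    close = tree.query_pairs(0.5)
    if close:
        raise GenerationError(f"degenerate geometry: {len(close)} atom pairs < 0.5 Å")

    n_atoms = n * len(_ATOM_NAMES)
    return Structure(
        serial=np.arange(1, n_atoms + 1),
        name=np.array(list(_ATOM_NAMES) * n, dtype="U6"),
        element=np.array(list(_ATOM_ELEMENTS) * n, dtype="U2"),
        chain=np.full(n_atoms, "A", dtype="U4"),
        resnum=np.repeat(np.arange(1, n + 1), len(_ATOM_NAMES)),
        icode=np.full(n_atoms, "", dtype="U1"),
        resname=np.full(n_atoms, "ALA", dtype="U5"),
        coords=coords,
        occupancy=np.ones(n_atoms),
        b_factor=np.zeros(n_atoms),
    )


def _chain_direction(ca: np.ndarray, i: int) -> np.ndarray:
    if i == 0:
        d = ca[1] - ca[0]
    elif i == len(ca) - 1:
        d = ca[-1] - ca[-2]
    else:
        d = ca[i + 1] - ca[i - 1]
    return d / np.linalg.norm(d)


def _perpendicular(t: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(t, ref)
    return u / np.linalg.norm(u)


# ---------------------------------------------------------------------------
# Anisotropic network model
# ---------------------------------------------------------------------------

@dataclass
class ElasticNetworkModel:
    """Cα-level harmonic network: Hessian eigenpairs sorted ascending.

    ``eigvals`` are in units of ``gamma`` (spring constant); the 6 rigid-body
    modes of a connected, non-degenerate network have eigenvalue ~0.
    """

    ca_coords: np.ndarray         # (A, 3)
    cutoff: float
    gamma: float
    hessian: np.ndarray           # (3A, 3A)
    eigvals: np.ndarray           # ascending
    eigvecs: np.ndarray           # columns, matching eigvals

    ZERO_TOL = 1e-8               # relative to largest eigenvalue

    @property
    def n_nodes(self) -> int:
        return len(self.ca_coords)

    @property
    def n_zero_modes(self) -> int:
        scale = max(self.eigvals.max(), 1.0)
        return int(np.sum(self.eigvals < self.ZERO_TOL * scale))

    @property
    def degenerate(self) -> bool:
        return self.n_zero_modes != 6

    def nonzero_modes(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.n_zero_modes
        return self.eigvals[k:], self.eigvecs[:, k:]


def anm_build(structure_or_coords, cutoff: float = 15.0, gamma: float = 1.0) -> ElasticNetworkModel:
    """Assemble and diagonalise the ANM Hessian over Cα atoms.

    Raises :class:`ConnectivityError` if the contact graph is disconnected at
    ``cutoff`` (the caller must raise the cutoff).
    """
    if isinstance(structure_or_coords, Structure):
        ca = structure_or_coords.coords[structure_or_coords.ca_mask()]
    else:
        ca = np.asarray(structure_or_coords, dtype=float)
    n = len(ca)
    if n < 3:
        raise ParameterError(f"ANM needs >= 3 Cα atoms, got {n}")

    diff = ca[:, None, :] - ca[None, :, :]
    dist2 = (diff ** 2).sum(axis=-1)
    contact = (dist2 <= cutoff ** 2) & ~np.eye(n, dtype=bool)

    n_comp, _ = connected_components(contact, directed=False)
    if n_comp > 1:
        raise ConnectivityError(
            f"elastic network disconnected at cutoff {cutoff} Å "
            f"({n_comp} components); raise the cutoff"
        )

    H = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(contact, k=1))
    for i, j in zip(ii, jj):
        d = diff[i, j]
        block = -gamma * np.outer(d, d) / dist2[i, j]
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block

    vals, vecs = eigh(H)
    vals = np.clip(vals, 0.0, None)  # clip tiny negative round-off
    return ElasticNetworkModel(
        ca_coords=ca, cutoff=cutoff, gamma=gamma, hessian=H, eigvals=vals, eigvecs=vecs
    )


def anm_msf(model: ElasticNetworkModel, amplitude: float = 1.0) -> np.ndarray:
    """Analytic per-node mean-square fluctuation of the sampled Gaussian.

    Equals ``amplitude`` times the trace of each 3x3 diagonal block of the
    Hessian pseudo-inverse (rigid-body modes excluded).
    """
    vals, vecs = model.nonzero_modes()
    contrib = (vecs ** 2) / vals[None, :]          # (3A, m)
    per_coord = contrib.sum(axis=1) * amplitude
    return per_coord.reshape(-1, 3).sum(axis=1)


def sample_ensemble(
    model: ElasticNetworkModel,
    n_frames: int,
    amplitude: float = 0.5,
    n_modes: int | None = None,
    seed: int = 0,
    structure: Structure | None = None,
) -> ConformationalEnsemble:
    """Draw frames from the ANM Gaussian.

    Each frame is ``mean + sum_m z_m u_m sqrt(amplitude / lambda_m)`` with
    ``z_m`` standard normal, over the ``n_modes`` softest non-rigid modes
    (default: all).  With ``structure`` given (full-atom topology whose Cα
    atoms built the model), every atom of a residue is translated by its Cα
    displacement, so intra-residue geometry is preserved in every snapshot.
    """
    if amplitude <= 0:
        raise ParameterError("amplitude must be > 0")
    vals, vecs = model.nonzero_modes()
    if n_modes is None:
        n_modes = len(vals)
    if n_modes > len(vals):
        raise ParameterError(
            f"requested {n_modes} modes, only {len(vals)} non-rigid modes available"
        )
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, n_modes))
    scales = np.sqrt(amplitude / vals[:n_modes])
    disp = (z * scales[None, :]) @ vecs[:, :n_modes].T     # (N, 3A)
    ca_disp = disp.reshape(n_frames, -1, 3)

    if structure is None:
        topo = _ca_only_structure(model.ca_coords)
        frames = model.ca_coords[None, :, :] + ca_disp
    else:
        topo = structure
        res_of_atom = structure.atom_residue_index
        if structure.n_residues != model.n_nodes:
            raise ParameterError(
                "structure residue count does not match ANM node count"
            )
        frames = structure.coords[None, :, :] + ca_disp[:, res_of_atom, :]
    return ConformationalEnsemble(topology=topo, frames=frames)


def _ca_only_structure(ca: np.ndarray) -> Structure:
    n = len(ca)
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.full(n, "CA", dtype="U6"),
        element=np.full(n, "C", dtype="U2"),
        chain=np.full(n, "A", dtype="U4"),
        resnum=np.arange(1, n + 1),
        icode=np.full(n, "", dtype="U1"),
        resname=np.full(n, "ALA", dtype="U5"),
        coords=ca,
        occupancy=np.ones(n),
        b_factor=np.zeros(n),
    )


# ---------------------------------------------------------------------------
# Designed constraint energies for the rigidity study
# ---------------------------------------------------------------------------

def assign_constraint_energies(
    structure: Structure,
    weak_region: tuple[int, int] | None,
    strong_energy: float = -12.0,
    weak_energy: float = -2.0,
    seed: int = 0,
    contact_cutoff: float = 5.5,
    min_sequence_sep: int = 3,
    jitter: float = 0.05,
) -> dict[tuple[int, int], float]:
    """Designed hydrogen-bond-like constraints with a bimodal energy spectrum.

    Candidate constraints join the backbone N of residue i to the backbone O
    of residue j for every residue pair with |i-j| >= ``min_sequence_sep``
    and Cα-Cα distance <= ``contact_cutoff``.  Constraints touching the weak
    region get energies near ``weak_energy``; all others near
    ``strong_energy``.  A small seeded jitter makes every energy unique, so
    the removal order during thermal unfolding is total.

    Returns a mapping ``(atom_index_N_i, atom_index_O_j) -> energy`` in
    kcal/mol (more negative = stronger).
    """
    if not (strong_energy < weak_energy < 0):
        raise ParameterError(
            f"need strong_energy < weak_energy < 0, got {strong_energy}, {weak_energy}"
        )
    rng = np.random.default_rng(seed)
    ca_idx = structure.ca_indices()
    ca = structure.coords[ca_idx]
    n_res = structure.n_residues
    name = np.char.strip(structure.name.astype("U6"))
    res_of_atom = structure.atom_residue_index
    n_atom_of_res = {}
    o_atom_of_res = {}
    for a in range(structure.n_atoms):
        if name[a] == "N":
            n_atom_of_res[res_of_atom[a]] = a
        elif name[a] == "O":
            o_atom_of_res[res_of_atom[a]] = a

    weak = set()
    if weak_region is not None:
        weak = set(range(weak_region[0], weak_region[1] + 1))

    tree = cKDTree(ca)
    energies: dict[tuple[int, int], float] = {}
    for i, j in sorted(tree.query_pairs(contact_cutoff)):
        if abs(i - j) < min_sequence_sep:
            continue
        if i not in n_atom_of_res or j not in o_atom_of_res:
            continue
        base = weak_energy if (i in weak or j in weak) else strong_energy
        e = base + rng.uniform(0.0, jitter)
        energies[(n_atom_of_res[i], o_atom_of_res[j])] = e
    return energies


# ---------------------------------------------------------------------------
# Fixture presets
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("two-domain", "weak-patch", "rigid-block")

#: study conditions per fixture kind: toy blueprint, ANM cutoff, and the
#: target root-mean Cα fluctuation (Å) the sampled ensemble should show
_FIXTURE_PARAMS = {
    # equal domains centre the hinge pivot in the linker
    "two-domain": dict(
        spec=dict(domain_sizes=(20, 20), row_length=5, weak_region=None),
        anm_cutoff=20.0, target_rmsf=1.5,
    ),
    # asymmetric domains make the giant rigid cluster unambiguous; the weak
    # patch is the last row of the larger domain
    "weak-patch": dict(
        spec=dict(domain_sizes=(24, 16), row_length=6, weak_region=(18, 22)),
        anm_cutoff=15.0, target_rmsf=0.7,
    ),
    # single compact domain: no hinge, no designed weakness
    "rigid-block": dict(
        spec=dict(domain_sizes=(24,), row_length=6, weak_region=None),
        anm_cutoff=15.0, target_rmsf=0.7,
    ),
}


def fixture_spec(kind: str, seed: int = 0) -> tuple[ToyProteinSpec, dict]:
    """Toy blueprint and generation parameters for a named fixture kind."""
    if kind not in _FIXTURE_PARAMS:
        raise ParameterError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    params = _FIXTURE_PARAMS[kind]
    return ToyProteinSpec(seed=seed, **params["spec"]), {
        "anm_cutoff": params["anm_cutoff"],
        "target_rmsf": params["target_rmsf"],
    }


def amplitude_for_rmsf(model: ElasticNetworkModel, target_rmsf: float) -> float:
    """Sampling amplitude giving a mean per-residue RMSF of ``target_rmsf`` Å."""
    return target_rmsf ** 2 / float(anm_msf(model, 1.0).mean())


def generate_fixture(
    kind: str,
    seed: int = 0,
    n_frames: int = 500,
    out_dir: str = ".",
    header: tuple[str, ...] = (),
) -> dict:
    """Write a multi-model PDB fixture plus its ground-truth JSON sidecar.

    Returns a dict with the written paths and the ground-truth payload.
    Deterministic for a given seed.
    """
    import json
    from pathlib import Path

    from .io import write_ensemble_pdb

    spec, params = fixture_spec(kind, seed)
    structure = build_toy_structure(spec)
    model = anm_build(structure, cutoff=params["anm_cutoff"])
    amplitude = amplitude_for_rmsf(model, params["target_rmsf"])
    ensemble = sample_ensemble(
        model, n_frames, amplitude=amplitude, seed=seed, structure=structure
    )
    gt = ground_truth(spec, model, amplitude=amplitude)
    gt["kind"] = kind
    gt["n_frames"] = n_frames
    if spec.weak_region is not None:
        gt["constraint_energies"] = {
            "strong": -12.0, "weak": -2.0, "contact_cutoff": 5.5,
            "min_sequence_sep": 3, "jitter": 0.05, "seed": seed,
        }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb_path = out / f"{kind}.pdb"
    json_path = out / f"{kind}.json"
    write_ensemble_pdb(ensemble, pdb_path, header=header)
    json_path.write_text(json.dumps(gt, indent=1))
    return {"pdb": str(pdb_path), "sidecar": str(json_path), "ground_truth": gt}


def constraint_assigner_from_sidecar(sidecar: dict):
    """Per-snapshot designed-constraint source reconstructed from a sidecar.

    Returns a callable mapping a snapshot :class:`Structure` to the designed
    hydrogen-bond-like :class:`~ensembleflex.rigidity.Constraint` list, or
    None when the fixture has no designed energies.
    """
    from .rigidity.constraints import BARS_HBOND, Constraint

    if sidecar.get("weak_region") is None or "constraint_energies" not in sidecar:
        return None
    ce = sidecar["constraint_energies"]
    weak_region = tuple(sidecar["weak_region"])

    def source(snapshot: Structure) -> list:
        energies = assign_constraint_energies(
            snapshot,
            weak_region,
            strong_energy=ce["strong"],
            weak_energy=ce["weak"],
            seed=ce["seed"],
            contact_cutoff=ce["contact_cutoff"],
            min_sequence_sep=ce["min_sequence_sep"],
            jitter=ce["jitter"],
        )
        return [
            Constraint("hydrogen-bond", min(a, b), max(a, b), BARS_HBOND, e)
            for (a, b), e in energies.items()
        ]

    return source


def ground_truth(spec: ToyProteinSpec, model: ElasticNetworkModel | None = None,
                 amplitude: float = 0.5) -> dict:
    """Ground-truth sidecar for a generated fixture (JSON-serialisable)."""
    gt = {
        "n_residues": spec.total_residues,
        "domain_sizes": list(spec.domain_sizes),
        "linker_ranges": [list(r) for r in spec.linker_ranges],
        "weak_region": list(spec.weak_region) if spec.weak_region else None,
        "weak_residues": spec.weak_residues,
        "seed": spec.seed,
    }
    if model is not None:
        gt["analytic_msf"] = anm_msf(model, amplitude).tolist()
        gt["anm_cutoff"] = model.cutoff
        gt["amplitude"] = amplitude
    return gt
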