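"""Full analysis pipeline: fluctuations → PCA → force constants → depth →
rigidity → thermal unfolding → weak spots, with a provenance manifest.

Every output is a tab-separated table (or a B-factor-annotated PDB) whose
header records the tool version, the configuration and the seed, so a run
with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .structures import ConformationalEnsemble
from .io import read_ensemble, write_bfactor_pdb, write_residue_table
from .superpose import superpose
from .fluctuations import (
    bfactor,
    distance_fluctuation_force_constants,
    residue_depth,
    rmsf,
)
from .collective import identify_hinges, pca, slow_mode_profile
from .synthetic import constraint_assigner_from_sidecar
from .rigidity import (
    build_constraint_network,
    covalent_bonds,
    detect_transition,
    ensemble_weak_spot_frequencies,
    pebble_game_decompose,
    rigidity_index,
    thermal_unfolding,
    weak_spots,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records which."""


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run (defaults follow the analysis
    conditions: T = 300 K, hydrogen-bond cutoff -1.0 kcal/mol, hydrophobic
    pad 0.25 Å, 500 weak-spot samples)."""

    input_path: str
    output_dir: str
    seed: int = 0
    temperature: float = 300.0
    dfc_representation: str = "ca"
    pca_profile_modes: int = 3
    pca_map_modes: int = 5
    hinge_window: int = 5
    hinge_quantile: float = 0.1
    e_cut: float = -1.0
    e_start: float = -0.1
    e_end: float = -10.0
    e_step: float = 0.1
    n_samples: int = 500
    depth_stride: int = 10
    sidecar_path: str | None = None  # fixture ground-truth JSON (designed energies)

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.dfc_representation not in ("ca", "allatom"):
            raise ValueError("dfc_representation must be 'ca' or 'allatom'")
        if not (self.e_end < self.e_start < 0):
            raise ValueError("need e_end < e_start < 0")
        if self.e_step <= 0 or self.n_samples < 1:
            raise ValueError("e_step must be > 0 and n_samples >= 1")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the report directory.

    On stage failure the manifest marks the failed stage, partial outputs
    are retained and :class:`PipelineError` is raised.
    """
    from . import __version__

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [
        f"ensembleflex {__version__}",
        "config: " + json.dumps(asdict(config), sort_keys=True),
        f"seed: {config.seed}",
    ]
    manifest: list[tuple[str, str, str]] = []  # stage, file, status
    stage = "read"
    try:
        ensemble = read_ensemble(config.input_path)
        topo = ensemble.topology
        sidecar = None
        if config.sidecar_path:
            sidecar = json.loads(Path(config.sidecar_path).read_text())

        stage = "superpose"
        aligned = superpose(ensemble)

        stage = "fluctuations"
        prof_rmsf = rmsf(aligned)
        write_residue_table(prof_rmsf, out / "rmsf.tsv", topo, "rmsf_A", header)
        write_residue_table(
            bfactor(prof_rmsf), out / "bfactor.tsv", topo, "bfactor_A2", header
        )
        manifest += [("fluctuations", "rmsf.tsv", "ok"),
                     ("fluctuations", "bfactor.tsv", "ok")]

        stage = "pca"
        spectrum = pca(aligned)
        with open(out / "pca_eigenvalues.tsv", "w", encoding="utf-8") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write("mode\teigenvalue_A2\n")
            for m, v in enumerate(spectrum.eigvals[: 3 * spectrum.n_sites]):
                fh.write(f"{m + 1}\t{v:.6g}\n")
        profile = slow_mode_profile(spectrum, k_modes=config.pca_profile_modes)
        write_residue_table(
            profile.values, out / "slow_mode_profile.tsv", topo, "norm_sq_disp", header
        )
        hinges = identify_hinges(profile, config.hinge_window, config.hinge_quantile)
        (out / "hinges.tsv").write_text(
            "".join(f"# {line}\n" for line in header)
            + "rank\tresidue_index\tprofile_value\n"
            + "".join(
                f"{k + 1}\t{r}\t{profile.values[r]:.6g}\n" for k, r in enumerate(hinges)
            ),
            encoding="utf-8",
        )
        map_profile = slow_mode_profile(spectrum, k_modes=min(
            config.pca_map_modes, spectrum.eigvecs.shape[1]))
        write_bfactor_pdb(
            topo, map_profile.values * 1e3, out / "slow_mode_map.pdb", header
        )
        manifest += [("pca", "pca_eigenvalues.tsv", "ok"),
                     ("pca", "slow_mode_profile.tsv", "ok"),
                     ("pca", "hinges.tsv", "ok"),
                     ("pca", "slow_mode_map.pdb", "ok")]

        stage = "force-constants"
        fc = distance_fluctuation_force_constants(
            ensemble, config.dfc_representation, config.temperature
        )
        write_residue_table(
            fc.k, out / "force_constants.tsv", topo, "k_kcal_mol_A2", header
        )
        manifest.append(("force-constants", "force_constants.tsv", "ok"))

        stage = "depth"
        depth = residue_depth(ensemble, frame_stride=config.depth_stride)
        write_residue_table(depth.depth, out / "residue_depth.tsv", topo, "depth_A", header)
        manifest.append(("depth", "residue_depth.tsv", "ok"))

        stage = "rigidity"
        snap = topo.with_coords(ensemble.frames[0])
        bonds = covalent_bonds(snap)
        source = constraint_assigner_from_sidecar(sidecar) if sidecar else None
        hbonds = source(snap) if source else None
        network = build_constraint_network(snap, e_cut=config.e_cut,
                                           hbonds=hbonds, bonds=bonds)
        decomp = pebble_game_decompose(network)
        ca = topo.ca_indices()
        with open(out / "rigid_clusters.tsv", "w", encoding="utf-8") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write("residue_index\tcluster\tcluster_atoms\n")
            for r, a in enumerate(ca):
                lbl = decomp.labels[a]
                fh.write(f"{r}\t{lbl}\t{decomp.sizes[lbl]}\n")
        manifest.append(("rigidity", "rigid_clusters.tsv", "ok"))

        stage = "unfolding"
        traj = thermal_unfolding(
            snap, hbonds=hbonds, e_start=config.e_start,
            e_end=config.e_end, step=config.e_step, bonds=bonds,
        )
        sizes = traj.giant_sizes
        with open(out / "giant_cluster.tsv", "w", encoding="utf-8") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write("cutoff_kcal_mol\tgiant_cluster_atoms\n")
            for c, s in zip(traj.cutoffs, sizes):
                fh.write(f"{c:.2f}\t{s}\n")
        r_i, still_rigid = rigidity_index(traj)
        write_residue_table(r_i, out / "rigidity_index.tsv", topo, "r_kcal_mol", header)
        t = detect_transition(traj)
        ws = sorted(weak_spots(traj, t)) if t is not None else []
        manifest += [("unfolding", "giant_cluster.tsv", "ok"),
                     ("unfolding", "rigidity_index.tsv", "ok")]

        stage = "weak-spots"
        profile_ws = ensemble_weak_spot_frequencies(
            ensemble, n_samples=config.n_samples,
            e_start=config.e_start, e_end=config.e_end, step=config.e_step,
            constraint_source=source,
        )
        write_residue_table(
            profile_ws.frequencies, out / "weak_spot_frequency.tsv", topo,
            "frequency", header,
        )
        write_bfactor_pdb(
            topo, profile_ws.frequencies, out / "weak_spot_map.pdb", header
        )
        manifest += [("weak-spots", "weak_spot_frequency.tsv", "ok"),
                     ("weak-spots", "weak_spot_map.pdb", "ok")]
    except Exception as exc:
        manifest.append((stage, "-", f"failed: {exc}"))
        _write_manifest(out, header, manifest)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    _write_manifest(out, header, manifest)
    return out


def _write_manifest(out: Path, header: list[str], manifest) -> None:
    with open(out / "manifest.tsv", "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("stage\tfile\tstatus\n")
        for stage, fname, status in manifest:
            fh.write(f"{stage}\t{fname}\t{status}\n")
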