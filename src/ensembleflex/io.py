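"""Reading and writing structures, ensembles and per-residue result tables.

PDB parsing and fixed-column writing are delegated to :mod:`biotite`; this
module converts to/from the package's own array-backed containers and adds the
ensemble bookkeeping (multi-model stacking, frame-consistency checks) and the
TSV / B-factor-map outputs used by every analysis stage.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .structures import ConformationalEnsemble, EnsembleConsistencyError, Structure

__all__ = [
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble_pdb",
    "write_residue_table",
    "write_bfactor_pdb",
    "structure_from_atom_array",
    "structure_to_atom_array",
]


class PDBFormatError(ValueError):
    """Input file could not be parsed as PDB."""


def structure_from_atom_array(atoms: bst.AtomArray) -> Structure:
    """Convert a biotite AtomArray to a :class:`Structure`."""
    occ = (
        atoms.occupancy
        if "occupancy" in atoms.get_annotation_categories()
        else np.ones(atoms.array_length())
    )
    bf = (
        atoms.b_factor
        if "b_factor" in atoms.get_annotation_categories()
        else np.zeros(atoms.array_length())
    )
    serial = (
        atoms.atom_id
        if "atom_id" in atoms.get_annotation_categories()
        else np.arange(1, atoms.array_length() + 1)
    )
    return Structure(
        serial=np.asarray(serial, dtype=int),
        name=atoms.atom_name.astype("U6"),
        element=atoms.element.astype("U2"),
        chain=atoms.chain_id.astype("U4"),
        resnum=np.asarray(atoms.res_id, dtype=int),
        icode=atoms.ins_code.astype("U1"),
        resname=atoms.res_name.astype("U5"),
        coords=np.asarray(atoms.coord, dtype=float),
        occupancy=np.asarray(occ, dtype=float),
        b_factor=np.asarray(bf, dtype=float),
    )


def structure_to_atom_array(structure: Structure) -> bst.AtomArray:
    atoms = bst.AtomArray(structure.n_atoms)
    atoms.coord = np.asarray(structure.coords, dtype=np.float32)
    atoms.chain_id = structure.chain.astype("U4")
    atoms.res_id = structure.resnum
    atoms.ins_code = structure.icode.astype("U1")
    atoms.res_name = structure.resname.astype("U5")
    atoms.atom_name = structure.name.astype("U6")
    atoms.element = structure.element.astype("U2")
    atoms.set_annotation("occupancy", structure.occupancy.astype(float))
    atoms.set_annotation("b_factor", structure.b_factor.astype(float))
    atoms.set_annotation("atom_id", structure.serial.astype(int))
    return atoms


def _read_pdb(path: str | Path) -> PDBFile:
    try:
        return PDBFile.read(str(path))
    except Exception as exc:  # biotite raises several parse error types
        raise PDBFormatError(f"cannot parse PDB file {path}: {exc}") from exc


def read_structure(path: str | Path, model: int | str = "first") -> Structure:
    """Read a single model from a PDB file.

    Parameters
    ----------
    path:
        PDB file path.
    model:
        ``"first"`` for model 1, or a 1-based model number.

    Alternate locations are resolved to the highest-occupancy conformer;
    hydrogens are retained if present.
    """
    pdb = _read_pdb(path)
    model_no = 1 if model == "first" else int(model)
    try:
        atoms = pdb.get_structure(
            model=model_no,
            altloc="occupancy",
            extra_fields=["occupancy", "b_factor", "atom_id"],
        )
    except Exception as exc:
        raise PDBFormatError(f"cannot extract model {model_no} from {path}: {exc}")
    if atoms.array_length() == 0:
        raise ValueError(f"model {model_no} of {path} contains no atoms")
    return structure_from_atom_array(atoms)


def read_ensemble(source: str | Path) -> ConformationalEnsemble:
    """Read a conformational ensemble.

    ``source`` is either a multi-model PDB file (frames = models, in file
    order) or a directory of single-model PDB files (frames = files, in
    sorted filename order).  All frames must share atom count and ordering;
    a mismatch raises :class:`EnsembleConsistencyError` naming the offending
    frame.  The topology is taken from the first frame.
    """
    source = Path(source)
    if source.is_dir():
        paths = sorted(p for p in source.iterdir() if p.suffix.lower() == ".pdb")
        if not paths:
            raise ValueError(f"no .pdb files in directory {source}")
        structures = [read_structure(p) for p in paths]
        topo = structures[0]
        frames = np.empty((len(structures), topo.n_atoms, 3))
        for k, s in enumerate(structures):
            if s.n_atoms != topo.n_atoms or not np.array_equal(s.name, topo.name):
                raise EnsembleConsistencyError(
                    f"frame {paths[k].name} does not match topology "
                    f"({s.n_atoms} atoms vs {topo.n_atoms})"
                )
            frames[k] = s.coords
        return ConformationalEnsemble(
            topology=topo, frames=frames, frame_ids=[p.name for p in paths]
        )

    pdb = _read_pdb(source)
    n_models = pdb.get_model_count()
    first = read_structure(source, model=1)
    frames = np.empty((n_models, first.n_atoms, 3))
    frames[0] = first.coords
    for m in range(2, n_models + 1):
        try:
            atoms = pdb.get_structure(model=m, altloc="occupancy")
        except Exception as exc:
            raise EnsembleConsistencyError(
                f"frame {m} of {source} is inconsistent with model 1: {exc}"
            ) from exc
        if atoms.array_length() != first.n_atoms:
            raise EnsembleConsistencyError(
                f"frame {m} of {source} has {atoms.array_length()} atoms, "
                f"expected {first.n_atoms}"
            )
        frames[m - 1] = atoms.coord
    return ConformationalEnsemble(
        topology=first,
        frames=frames,
        frame_ids=[str(m) for m in range(1, n_models + 1)],
    )


def write_structure(
    structure: Structure, path: str | Path, header: Sequence[str] = ()
) -> None:
    """Write a single-model PDB file (REMARK lines for ``header``)."""
    pdb = PDBFile()
    pdb.set_structure(structure_to_atom_array(structure))
    _prepend_remarks(pdb, header)
    pdb.write(str(path))


def write_ensemble_pdb(
    ensemble: ConformationalEnsemble, path: str | Path, header: Sequence[str] = ()
) -> None:
    """Write an ensemble as a multi-model PDB file."""
    stack = bst.stack(
        [
            structure_to_atom_array(ensemble.topology.with_coords(f))
            for f in ensemble.frames
        ]
    )
    pdb = PDBFile()
    pdb.set_structure(stack)
    _prepend_remarks(pdb, header)
    pdb.write(str(path))


def _prepend_remarks(pdb: PDBFile, header: Sequence[str]) -> None:
    if header:
        remarks = [f"REMARK 250 {line}"[:80] for line in header]
        pdb.lines = remarks + pdb.lines


def write_residue_table(
    values: Mapping[tuple[str, int, str], float] | np.ndarray | Sequence[float],
    path: str | Path,
    structure: Structure,
    column: str = "value",
    header: Sequence[str] = (),
) -> None:
    """Write a per-residue TSV: chain, resnum, icode, resname, value.

    ``values`` may be a mapping keyed by residue_id or an array in residue
    index order.  Unknown residue_ids raise ``KeyError``.
    """
    rids = structure.residue_ids()
    names = structure.residue_names()
    if isinstance(values, Mapping):
        unknown = set(values) - set(rids)
        if unknown:
            raise KeyError(f"residue_ids not in structure: {sorted(unknown)[:5]}")
        ordered = [values[rid] for rid in rids]
    else:
        arr = np.asarray(values, dtype=float)
        if len(arr) != len(rids):
            raise ValueError(
                f"got {len(arr)} values for {len(rids)} residues"
            )
        ordered = arr.tolist()
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write(f"chain\tresnum\ticode\tresname\t{column}\n")
        for (chain, resnum, icode), name, v in zip(rids, names, ordered):
            fh.write(f"{chain}\t{resnum}\t{icode}\t{name}\t{v:.6g}\n")


def write_bfactor_pdb(
    structure: Structure,
    values: Mapping[tuple[str, int, str], float] | np.ndarray | Sequence[float],
    path: str | Path,
    header: Sequence[str] = (),
) -> None:
    """Write a PDB whose B-factor column carries a per-residue value."""
    rids = structure.residue_ids()
    if isinstance(values, Mapping):
        unknown = set(values) - set(rids)
        if unknown:
            raise KeyError(f"residue_ids not in structure: {sorted(unknown)[:5]}")
        per_res = np.array([values[rid] for rid in rids], dtype=float)
    else:
        per_res = np.asarray(values, dtype=float)
        if len(per_res) != len(rids):
            raise ValueError(
                f"got {len(per_res)} values for {len(rids)} residues"
            )
    bf = per_res[structure.atom_residue_index]
    out = Structure(
        serial=structure.serial,
        name=structure.name,
        element=structure.element,
        chain=structure.chain,
        resnum=structure.resnum,
        icode=structure.icode,
        resname=structure.resname,
        coords=structure.coords,
        occupancy=structure.occupancy,
        b_factor=bf,
    )
    write_structure(out, path, header=header)
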