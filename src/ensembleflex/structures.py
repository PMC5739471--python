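"""Core containers: structures, conformational ensembles, domain annotations.

A :class:`Structure` is a column-oriented atom table (numpy arrays) with a
residue index that maps each ``(chain, resnum, icode)`` triple to a contiguous
0-based integer.  A :class:`ConformationalEnsemble` stacks N coordinate frames
over one shared topology; it is the substrate of every ensemble statistic in
the package (RMSF, force constants, PCA, per-snapshot rigidity networks).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "ConformationalEnsemble",
    "DomainAnnotation",
    "EnsembleConsistencyError",
    "InsufficientFramesError",
]


class EnsembleConsistencyError(ValueError):
    """Frames of an ensemble disagree on atom count or ordering."""


class InsufficientFramesError(ValueError):
    """An ensemble statistic was requested with too few frames."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom row, in PDB conventions (coordinates in Å)."""

    serial: int
    name: str
    element: str
    chain: str
    resnum: int
    icode: str
    resname: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)


@dataclass
class Structure:
    """Column-oriented structure: parallel arrays, one entry per atom.

    ``residue_starts`` holds the first atom index of each residue, so residue
    ``r`` owns atoms ``residue_starts[r]:residue_starts[r+1]``; atoms of a
    residue are contiguous by construction.
    """

    serial: np.ndarray          # (A,) int
    name: np.ndarray            # (A,) str
    element: np.ndarray         # (A,) str
    chain: np.ndarray           # (A,) str
    resnum: np.ndarray          # (A,) int
    icode: np.ndarray           # (A,) str
    resname: np.ndarray         # (A,) str
    coords: np.ndarray          # (A, 3) float, Å
    occupancy: np.ndarray       # (A,) float
    b_factor: np.ndarray        # (A,) float
    residue_starts: np.ndarray = field(default=None)  # (R+1,) int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (A, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.residue_starts is None:
            self.residue_starts = _compute_residue_starts(
                self.chain, self.resnum, self.icode
            )

    # -- sizes ---------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def n_residues(self) -> int:
        return len(self.residue_starts) - 1

    # -- residue bookkeeping -------------------------------------------------
    @property
    def atom_residue_index(self) -> np.ndarray:
        """(A,) array: 0-based residue index of every atom."""
        out = np.empty(self.n_atoms, dtype=int)
        for r in range(self.n_residues):
            out[self.residue_starts[r]:self.residue_starts[r + 1]] = r
        return out

    def residue_ids(self) -> list[tuple[str, int, str]]:
        starts = self.residue_starts[:-1]
        return [
            (str(self.chain[i]), int(self.resnum[i]), str(self.icode[i]))
            for i in starts
        ]

    @property
    def residue_index(self) -> dict[tuple[str, int, str], int]:
        """Mapping residue_id -> contiguous 0-based index."""
        return {rid: r for r, rid in enumerate(self.residue_ids())}

    def residue_names(self) -> list[str]:
        return [str(self.resname[i]) for i in self.residue_starts[:-1]]

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain:
            if not seen or seen[-1] != c:
                if c not in seen:
                    seen.append(str(c))
        return seen

    def atom_indices(self, residue: int) -> np.ndarray:
        return np.arange(
            self.residue_starts[residue], self.residue_starts[residue + 1]
        )

    def select(self, mask: np.ndarray) -> "Structure":
        """New Structure restricted to atoms where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return Structure(
            serial=self.serial[mask],
            name=self.name[mask],
            element=self.element[mask],
            chain=self.chain[mask],
            resnum=self.resnum[mask],
            icode=self.icode[mask],
            resname=self.resname[mask],
            coords=self.coords[mask],
            occupancy=self.occupancy[mask],
            b_factor=self.b_factor[mask],
        )

    def ca_mask(self) -> np.ndarray:
        return np.char.strip(self.name.astype("U6")) == "CA"

    def ca_indices(self) -> np.ndarray:
        return np.flatnonzero(self.ca_mask())

    def atoms(self) -> Iterable[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                serial=int(self.serial[i]),
                name=str(self.name[i]),
                element=str(self.element[i]),
                chain=str(self.chain[i]),
                resnum=int(self.resnum[i]),
                icode=str(self.icode[i]),
                resname=str(self.resname[i]),
                coord=self.coords[i].copy(),
                occupancy=float(self.occupancy[i]),
                b_factor=float(self.b_factor[i]),
            )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))


def _compute_residue_starts(
    chain: np.ndarray, resnum: np.ndarray, icode: np.ndarray
) -> np.ndarray:
    n = len(chain)
    if n == 0:
        return np.array([0], dtype=int)
    starts = [0]
    for i in range(1, n):
        if (
            chain[i] != chain[i - 1]
            or resnum[i] != resnum[i - 1]
            or icode[i] != icode[i - 1]
        ):
            starts.append(i)
    starts.append(n)
    return np.asarray(starts, dtype=int)


@dataclass
class ConformationalEnsemble:
    """N aligned snapshots of one structure.

    ``frames`` is (N, A, 3) in Å; every frame shares the atom count and order
    of ``topology``.  ``alignment`` records the superposition applied (or None
    if the ensemble is raw).
    """

    topology: Structure
    frames: np.ndarray
    frame_ids: list[str] = None
    alignment: dict | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (N, A, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise EnsembleConsistencyError(
                f"frames have {self.frames.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if self.frame_ids is None:
            self.frame_ids = [str(i) for i in range(self.frames.shape[0])]
        if len(self.frame_ids) != self.frames.shape[0]:
            raise EnsembleConsistencyError("frame_ids length != frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def require_frames(self, n: int, what: str = "statistic") -> None:
        if self.n_frames < n:
            raise InsufficientFramesError(
                f"{what} needs at least {n} frames, got {self.n_frames}"
            )

    def mean_coords(self) -> np.ndarray:
        return self.frames.mean(axis=0)

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass
class DomainAnnotation:
    """Named residue ranges per chain, e.g. NTD 1-215 / MD 216-552 / CTD 553-690.

    Ranges are (first, last) author residue numbers, inclusive, and must not
    overlap within a chain.
    """

    domains: dict[str, dict[str, tuple[int, int]]]

    def __post_init__(self) -> None:
        for chain, ranges in self.domains.items():
            spans = sorted(ranges.values())
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise ValueError(
                        f"overlapping domain ranges in chain {chain!r}: "
                        f"({a1},{b1}) and ({a2},{b2})"
                    )
            for name, (a, b) in ranges.items():
                if a > b:
                    raise ValueError(f"empty domain range {name!r}: ({a},{b})")

    def domain_of(self, chain: str, resnum: int) -> str | None:
        for name, (a, b) in self.domains.get(chain, {}).items():
            if a <= resnum <= b:
                return name
        return None

    def residue_labels(self, structure: Structure) -> list[str | None]:
        return [
            self.domain_of(c, n) for (c, n, _) in structure.residue_ids()
        ]
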