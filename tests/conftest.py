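"""Shared fixtures: toy structures, ANM models, sampled ensembles.

Session-scoped fixtures keep the heavier generator products (500-frame
ensembles, eigendecompositions) to one computation per run.
"""

import numpy as np
import pytest

import ensembleflex as ef
from ensembleflex.synthetic import amplitude_for_rmsf


@pytest.fixture(scope="session")
def weak_patch_case():
    """Weak-patch toy: structure, ANM, 500-frame ensemble, designed energies."""
    spec, params = ef.fixture_spec("weak-patch", seed=11)
    structure = ef.build_toy_structure(spec)
    model = ef.anm_build(structure, cutoff=params["anm_cutoff"])
    amplitude = amplitude_for_rmsf(model, params["target_rmsf"])
    ensemble = ef.sample_ensemble(
        model, 500, amplitude=amplitude, seed=11, structure=structure
    )
    gt = ef.ground_truth(spec, model, amplitude)
    gt["constraint_energies"] = {
        "strong": -12.0, "weak": -2.0, "contact_cutoff": 5.5,
        "min_sequence_sep": 3, "jitter": 0.05, "seed": 11,
    }
    return {
        "spec": spec, "structure": structure, "model": model,
        "amplitude": amplitude, "ensemble": ensemble, "ground_truth": gt,
        "constraint_source": ef.constraint_assigner_from_sidecar(gt),
    }


@pytest.fixture(scope="session")
def two_domain_case():
    """Two-domain hinge toy with a 500-frame superposed ensemble."""
    spec, params = ef.fixture_spec("two-domain", seed=7)
    structure = ef.build_toy_structure(spec)
    model = ef.anm_build(structure, cutoff=params["anm_cutoff"])
    amplitude = amplitude_for_rmsf(model, params["target_rmsf"])
    ensemble = ef.sample_ensemble(
        model, 500, amplitude=amplitude, seed=7, structure=structure
    )
    return {
        "spec": spec, "structure": structure, "model": model,
        "amplitude": amplitude, "ensemble": ensemble,
        "aligned": ef.superpose(ensemble),
        "linker": spec.linker_ranges[0],
    }


@pytest.fixture()
def tiny_structure():
    """Three Cα-only particles in a line, 4 Å apart."""
    n = 3
    return ef.Structure(
        serial=np.arange(1, n + 1),
        name=np.full(n, "CA", dtype="U6"),
        element=np.full(n, "C", dtype="U2"),
        chain=np.full(n, "A", dtype="U4"),
        resnum=np.arange(1, n + 1),
        icode=np.full(n, "", dtype="U1"),
        resname=np.full(n, "GLY", dtype="U5"),
        coords=np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]]),
        occupancy=np.ones(n),
        b_factor=np.zeros(n),
    )


def make_structure(coords, names=None, elements=None, resnums=None,
                   resnames=None, chains=None):
    """Helper to build ad-hoc structures in tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if names is None:
        names = ["CA"] * n
    if elements is None:
        elements = [nm[0] for nm in names]
    if resnums is None:
        resnums = list(range(1, n + 1))
    if resnames is None:
        resnames = ["GLY"] * n
    if chains is None:
        chains = ["A"] * n
    return ef.Structure(
        serial=np.arange(1, n + 1),
        name=np.array(names, dtype="U6"),
        element=np.array(elements, dtype="U2"),
        chain=np.array(chains, dtype="U4"),
        resnum=np.array(resnums, dtype=int),
        icode=np.full(n, "", dtype="U1"),
        resname=np.array(resnames, dtype="U5"),
        coords=coords,
        occupancy=np.ones(n),
        b_factor=np.zeros(n),
    )
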