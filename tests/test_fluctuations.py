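"""Fluctuation statistics: RMSF closed forms, force-constant oracle, depth."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import ensembleflex as ef
from ensembleflex.fluctuations import (
    BOLTZMANN_KCAL,
    FORCE_CONSTANT_CAP,
    residue_depth,
)
from ensembleflex.structures import InsufficientFramesError
from ensembleflex.synthetic import anm_msf

from conftest import make_structure


def brute_force_dfc(frames, temperature=300.0, exclude_neighbors=1):
    """Independent loop-based implementation of the force-constant statistic
    for one-site-per-residue ensembles."""
    n_frames, n_sites, _ = frames.shape
    kBT = BOLTZMANN_KCAL * temperature
    k = np.empty(n_sites)
    for i in range(n_sites):
        d_series = []
        for t in range(n_frames):
            ds = []
            for j in range(n_sites):
                if abs(i - j) <= exclude_neighbors:
                    continue
                ds.append(np.linalg.norm(frames[t, i] - frames[t, j]))
            d_series.append(np.mean(ds))
        var = np.var(d_series, ddof=1)
        k[i] = 3 * kBT / var
    return k


def test_identical_frames_have_zero_rmsf(tiny_structure):
    ens = ef.ConformationalEnsemble(
        tiny_structure, np.stack([tiny_structure.coords] * 3)
    )
    np.testing.assert_array_equal(ef.rmsf(ens), 0.0)
    with pytest.raises(InsufficientFramesError):
        ef.rmsf(ef.ConformationalEnsemble(tiny_structure, tiny_structure.coords[None]))


def test_alternating_displacement_gives_exact_rmsf(tiny_structure):
    delta = 0.7
    up = tiny_structure.coords.copy()
    down = tiny_structure.coords.copy()
    up[1, 2] += delta
    down[1, 2] -= delta
    ens = ef.ConformationalEnsemble(tiny_structure, np.stack([up, down] * 3))
    prof = ef.rmsf(ens)
    assert prof[1] == pytest.approx(delta, abs=1e-12)
    assert prof[0] == prof[2] == 0.0
    np.testing.assert_allclose(
        ef.bfactor(prof), (8 * np.pi ** 2 / 3) * prof ** 2
    )


def test_rmsf_matches_analytic_anm_variance(weak_patch_case):
    aligned = ef.superpose(weak_patch_case["ensemble"])
    prof = ef.rmsf(aligned)
    analytic = anm_msf(weak_patch_case["model"], weak_patch_case["amplitude"])
    rel = np.abs(prof ** 2 - analytic) / analytic
    assert np.mean(rel <= 0.10) >= 0.90


def test_rmsf_is_frame_permutation_equivariant(weak_patch_case):
    ens = weak_patch_case["ensemble"]
    sub = ef.ConformationalEnsemble(ens.topology, ens.frames[:50])
    perm = np.random.default_rng(0).permutation(50)
    shuffled = ef.ConformationalEnsemble(ens.topology, ens.frames[:50][perm])
    np.testing.assert_allclose(ef.rmsf(sub), ef.rmsf(shuffled), atol=1e-12)


def test_dfc_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    frames = rng.uniform(-5, 5, (12, 3, 3))
    s = make_structure(frames[0])
    ens = ef.ConformationalEnsemble(s, frames)
    prof = ef.distance_fluctuation_force_constants(ens, "ca", exclude_neighbors=0)
    oracle = brute_force_dfc(frames, exclude_neighbors=0)
    np.testing.assert_allclose(prof.k, oracle, rtol=1e-10)


def test_dfc_doubles_exactly_with_temperature():
    rng = np.random.default_rng(1)
    frames = rng.uniform(-5, 5, (10, 4, 3))
    ens = ef.ConformationalEnsemble(make_structure(frames[0]), frames)
    k300 = ef.distance_fluctuation_force_constants(ens, "ca", 300.0).k
    k600 = ef.distance_fluctuation_force_constants(ens, "ca", 600.0).k
    np.testing.assert_allclose(k600, 2 * k300, rtol=1e-12)


def test_rigid_rotation_ensemble_is_capped():
    from scipy.spatial.transform import Rotation

    base = np.random.default_rng(2).uniform(-5, 5, (6, 3))
    frames = np.stack(
        [base @ Rotation.random(random_state=k).as_matrix().T for k in range(8)]
    )
    ens = ef.ConformationalEnsemble(make_structure(base), frames)
    prof = ef.distance_fluctuation_force_constants(ens, "ca")
    assert prof.capped.all()
    assert np.all(prof.k == FORCE_CONSTANT_CAP)


def test_dfc_invariant_under_global_motion(weak_patch_case):
    from scipy.spatial.transform import Rotation

    ens = weak_patch_case["ensemble"]
    sub = ef.ConformationalEnsemble(ens.topology, ens.frames[:40].copy())
    k0 = ef.distance_fluctuation_force_constants(sub, "ca").k
    rng = np.random.default_rng(3)
    moved = np.stack([
        f @ Rotation.random(random_state=k).as_matrix().T + rng.uniform(-9, 9, 3)
        for k, f in enumerate(sub.frames)
    ])
    k1 = ef.distance_fluctuation_force_constants(
        ef.ConformationalEnsemble(ens.topology, moved), "ca"
    ).k
    assert np.max(np.abs(k1 - k0) / k0) <= 1e-6


def test_allatom_representation_runs_and_matches_scale(weak_patch_case):
    ens = weak_patch_case["ensemble"]
    sub = ef.ConformationalEnsemble(ens.topology, ens.frames[:30])
    prof = ef.distance_fluctuation_force_constants(sub, "allatom")
    assert prof.k.shape == (ens.topology.n_residues,)
    assert np.all(prof.k > 0)


def test_hinge_region_carries_maximal_force_constant(two_domain_case):
    prof = ef.distance_fluctuation_force_constants(two_domain_case["aligned"], "ca")
    a, b = two_domain_case["linker"]
    assert a - 2 <= int(np.argmax(prof.k)) <= b + 2
    # the hinge is a sharp peak; the softest quartile lies deep in the domains
    assert prof.k.max() >= 2 * np.median(prof.k)
    q25_residues = np.argsort(prof.k)[: len(prof.k) // 4]
    assert all(r < a - 3 or r > b + 3 for r in q25_residues)


# ---------------------------------------------------------------------------
# residue depth
# ---------------------------------------------------------------------------

def test_single_atom_depth_is_zero():
    s = make_structure([[0.0, 0.0, 0.0]])
    prof = residue_depth(s)
    assert prof.depth[0] == pytest.approx(0.0, abs=1e-9)


def test_icosahedral_cluster_center_is_deepest():
    phi = (1 + 5 ** 0.5) / 2
    shell = np.array(
        [[0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
         [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
         [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1]]
    )
    shell = shell / np.linalg.norm(shell[0]) * 3.5
    coords = np.vstack([[0.0, 0.0, 0.0], shell])
    prof = residue_depth(make_structure(coords))
    assert prof.depth[0] > prof.depth[1:].max()


def test_depth_tracks_distance_from_centroid():
    # ~250 atoms on a close-packed lattice ball (no probe-sized cavities)
    g = np.mgrid[-8:8:2.0, -8:8:2.0, -8:8:2.0].reshape(3, -1).T
    coords = g[np.linalg.norm(g, axis=1) <= 8]
    prof = residue_depth(make_structure(coords), n_dots=64)
    r = np.linalg.norm(coords - coords.mean(0), axis=1)
    rho, _ = spearmanr(prof.depth, -r)
    assert rho >= 0.9
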