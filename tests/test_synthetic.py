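"""Generator ground truth: geometry, ANM identities, sampling statistics."""

import numpy as np
import pytest
from scipy.linalg import pinvh

import ensembleflex as ef
from ensembleflex.synthetic import (
    ConnectivityError,
    ParameterError,
    amplitude_for_rmsf,
    anm_msf,
    assign_constraint_energies,
)


def test_residue_and_atom_counts():
    spec = ef.ToyProteinSpec(domain_sizes=(20, 20), linker_length=5,
                             row_length=5, weak_region=None)
    s = ef.build_toy_structure(spec)
    assert s.n_residues == 45
    assert s.n_atoms == 45 * 6  # N, CA, C, O, CB, amide H per residue


def test_same_seed_is_bit_identical():
    a = ef.build_toy_structure(ef.ToyProteinSpec(seed=9))
    b = ef.build_toy_structure(ef.ToyProteinSpec(seed=9))
    np.testing.assert_array_equal(a.coords, b.coords)
    c = ef.build_toy_structure(ef.ToyProteinSpec(seed=10))
    assert not np.array_equal(a.coords, c.coords)


def test_consecutive_ca_spacing():
    s = ef.build_toy_structure(ef.ToyProteinSpec(seed=2))
    ca = s.coords[s.ca_mask()]
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    assert np.all(np.abs(d - 3.8) <= 0.2)


def test_collinear_points_are_degenerate_anm():
    pts = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
    m = ef.anm_build(pts, cutoff=10.0)
    assert m.n_zero_modes > 6
    assert m.degenerate


def test_connected_toy_has_exactly_six_zero_modes(weak_patch_case):
    m = weak_patch_case["model"]
    assert m.n_zero_modes == 6
    assert not m.degenerate
    # Hessian is symmetric PSD
    H = m.hessian
    np.testing.assert_allclose(H, H.T, atol=1e-10)
    assert m.eigvals.min() >= -1e-10


def test_disconnected_network_raises():
    pts = np.vstack([np.random.default_rng(0).uniform(0, 5, (5, 3)),
                     np.random.default_rng(1).uniform(50, 55, (5, 3))])
    with pytest.raises(ConnectivityError):
        ef.anm_build(pts, cutoff=10.0)


def test_msf_matches_pseudoinverse_oracle(weak_patch_case):
    m = weak_patch_case["model"]
    msf = anm_msf(m, amplitude=1.0)
    # closed-form oracle: diagonal 3x3 block traces of the Hessian
    # pseudo-inverse, with the same rigid-body-mode cut as the model
    Hinv = pinvh(m.hessian, atol=m.ZERO_TOL * m.eigvals.max())
    oracle = np.diag(Hinv).reshape(-1, 3).sum(axis=1)
    np.testing.assert_allclose(msf, oracle, rtol=1e-8)


def test_tiny_amplitude_collapses_to_mean(weak_patch_case):
    m = weak_patch_case["model"]
    s = weak_patch_case["structure"]
    ens = ef.sample_ensemble(m, 5, amplitude=1e-24, seed=0, structure=s)
    assert np.max(np.abs(ens.frames - s.coords[None])) <= 1e-6
    with pytest.raises(ParameterError):
        ef.sample_ensemble(m, 5, amplitude=0.0)


def test_sampled_variance_matches_analytic(weak_patch_case):
    m = weak_patch_case["model"]
    amp = weak_patch_case["amplitude"]
    ens = weak_patch_case["ensemble"]  # 500 frames
    ca = ens.topology.ca_indices()
    dev = ens.frames[:, ca, :] - ens.frames[:, ca, :].mean(axis=0, keepdims=True)
    empirical = (dev ** 2).sum(axis=-1).mean(axis=0)
    analytic = anm_msf(m, amp)
    rel = np.abs(empirical - analytic) / analytic
    assert np.mean(rel <= 0.10) >= 0.90


def test_two_seeds_differ_but_share_covariance(weak_patch_case):
    m = weak_patch_case["model"]
    amp = weak_patch_case["amplitude"]
    a = ef.sample_ensemble(m, 400, amplitude=amp, seed=1)
    b = ef.sample_ensemble(m, 400, amplitude=amp, seed=2)
    assert not np.allclose(a.frames[0], b.frames[0])
    va = (a.frames - a.frames.mean(0)).reshape(400, -1).var(axis=0)
    vb = (b.frames - b.frames.mean(0)).reshape(400, -1).var(axis=0)
    # same underlying Gaussian: per-coordinate variances agree within
    # sampling error (chi-square spread at N=400)
    mask = va > va.max() * 1e-3
    assert np.median(np.abs(va[mask] - vb[mask]) / va[mask]) < 0.25


def test_designed_energy_assignment(weak_patch_case):
    s = weak_patch_case["structure"]
    spec = weak_patch_case["spec"]
    # empty weak region: all energies near the strong value
    e0 = assign_constraint_energies(s, None, seed=0)
    assert all(-12.0 <= v <= -11.9 for v in e0.values())
    energies = assign_constraint_energies(s, spec.weak_region, seed=0)
    assert len(set(energies.values())) == len(energies)  # unique after jitter
    res_of = s.atom_residue_index
    weak = set(spec.weak_residues)
    order = sorted(energies.items(), key=lambda kv: kv[1], reverse=True)
    n_weak = sum(1 for (a, b), _ in order
                 if res_of[a] in weak or res_of[b] in weak)
    removal_first = order[:n_weak]  # weakest (least negative) first
    assert all(res_of[a] in weak or res_of[b] in weak
               for (a, b), _ in removal_first)
    with pytest.raises(ParameterError):
        assign_constraint_energies(s, spec.weak_region, strong_energy=-1.0,
                                   weak_energy=-5.0)


def test_hinge_is_in_linker_by_construction(two_domain_case):
    prof = ef.slow_mode_profile(ef.pca(two_domain_case["aligned"]), k_modes=3)
    a, b = two_domain_case["linker"]
    eligible = prof.values[2:-2]
    amin = 2 + int(np.argmin(eligible))
    assert a - 2 <= amin <= b + 2
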