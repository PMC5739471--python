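"""PCA identities, slow-mode profiles and hinge detection."""

import numpy as np
import pytest

import ensembleflex as ef
from ensembleflex.collective import ModeSpectrum, identify_hinges, slow_mode_profile

from conftest import make_structure


def _spectrum(ensemble):
    return ef.pca(ensemble)


def test_rank_one_ensemble_concentrates_variance():
    base = np.random.default_rng(0).uniform(-5, 5, (10, 3))
    direction = np.zeros((10, 3))
    direction[4] = [1.0, 0, 0]
    amplitudes = np.linspace(-2, 2, 9)
    frames = np.stack([base + a * direction for a in amplitudes])
    ens = ef.ConformationalEnsemble(make_structure(base), frames)
    spec = _spectrum(ens)
    assert spec.eigvals[0] / spec.eigvals.sum() >= 0.999


def test_eigenvalues_match_svd_oracle(weak_patch_case):
    ens = ef.superpose(weak_patch_case["ensemble"])
    spec = _spectrum(ens)
    ca = ens.topology.ca_indices()
    x = ens.frames[:, ca, :].reshape(ens.n_frames, -1)
    sv = np.linalg.svd(x - x.mean(0), compute_uv=False)
    oracle = sv ** 2 / (ens.n_frames - 1)
    m = len(oracle)
    np.testing.assert_allclose(spec.eigvals[:m], oracle, atol=1e-8)


def test_projections_have_zero_mean_and_eigenvalue_variance(weak_patch_case):
    ens = ef.superpose(weak_patch_case["ensemble"])
    spec = _spectrum(ens)
    ca = ens.topology.ca_indices()
    scores = spec.project(ens.frames[:, ca, :])
    np.testing.assert_allclose(scores.mean(axis=0)[:20], 0.0, atol=1e-8)
    np.testing.assert_allclose(
        scores.var(axis=0, ddof=1)[:20], spec.eigvals[:20], atol=1e-8
    )


def test_orthonormality_and_variance_conservation(weak_patch_case):
    ens = ef.superpose(weak_patch_case["ensemble"])
    spec = _spectrum(ens)
    G = spec.eigvecs.T @ spec.eigvecs
    assert np.max(np.abs(G - np.eye(G.shape[0]))) <= 1e-8
    ca = ens.topology.ca_indices()
    x = ens.frames[:, ca, :].reshape(ens.n_frames, -1)
    total = (x - x.mean(0)).var(axis=0, ddof=1).sum()
    assert abs(spec.eigvals.sum() - total) / total <= 1e-6


def test_reconstruction_from_all_modes(weak_patch_case):
    ens = ef.superpose(weak_patch_case["ensemble"])
    spec = _spectrum(ens)
    ca = ens.topology.ca_indices()
    x = ens.frames[:5, ca, :].reshape(5, -1) - spec.mean.reshape(-1)[None]
    back = (x @ spec.eigvecs) @ spec.eigvecs.T
    np.testing.assert_allclose(back, x, atol=1e-8)


def _delta_spectrum(n_sites, hot_sites, eigvals):
    """Hand-built spectrum: each mode moves exactly one site."""
    vecs = np.zeros((3 * n_sites, len(hot_sites)))
    for m, site in enumerate(hot_sites):
        vecs[3 * site, m] = 1.0
    return ModeSpectrum(
        eigvals=np.asarray(eigvals, dtype=float),
        eigvecs=vecs,
        mean=np.zeros((n_sites, 3)),
        selection=np.arange(n_sites),
    )


def test_single_localized_mode_gives_delta_profile():
    spec = _delta_spectrum(10, [7], [2.0])
    prof = slow_mode_profile(spec, k_modes=1)
    assert prof.values[7] == pytest.approx(1.0)
    assert prof.values.sum() == pytest.approx(1.0)


def test_uniform_weighting_splits_mass_equally():
    spec = _delta_spectrum(10, [2, 5, 8], [3.0, 2.0, 1.0])
    prof = slow_mode_profile(spec, k_modes=3, weighting="uniform")
    for site in (2, 5, 8):
        assert prof.values[site] == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        slow_mode_profile(spec, k_modes=0)


def test_profile_invariant_to_eigenvector_sign_flips(weak_patch_case):
    ens = ef.superpose(weak_patch_case["ensemble"])
    spec = _spectrum(ens)
    flipped = ModeSpectrum(
        eigvals=spec.eigvals, eigvecs=-spec.eigvecs,
        mean=spec.mean, selection=spec.selection,
    )
    np.testing.assert_allclose(
        slow_mode_profile(spec, 3).values, slow_mode_profile(flipped, 3).values
    )


def test_monotone_profile_yields_no_hinge():
    assert identify_hinges(np.linspace(0.0, 1.0, 20) / np.linspace(0, 1, 20).sum()) == []


def test_v_shaped_profile_has_single_hinge_at_vertex():
    v = np.abs(np.arange(21) - 10).astype(float) + 1.0
    v /= v.sum()
    hinges = identify_hinges(v, window=5, quantile=0.1)
    assert hinges == [10]


def test_two_domain_hinges_land_in_linker(two_domain_case):
    prof = slow_mode_profile(ef.pca(two_domain_case["aligned"]), k_modes=3)
    hinges = identify_hinges(prof)
    a, b = two_domain_case["linker"]
    assert any(a - 2 <= h <= b + 2 for h in hinges)
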