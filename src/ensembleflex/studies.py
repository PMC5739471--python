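"""Self-contained validation studies over the synthetic generator.

Each function sets up a complete study — generate the toy system, run the
analysis under test, score it against the generator's ground truth or an
independent oracle — and returns plain numbers.  The acceptance script and
the heavier end of the test suite both drive these, so the studies stay in
one place and are always recomputed from scratch.
"""

from __future__ import annotations

import itertools

import numpy as np

from .structures import ConformationalEnsemble
from .superpose import superpose
from .fluctuations import (
    BOLTZMANN_KCAL,
    distance_fluctuation_force_constants,
)
from .collective import pca, slow_mode_profile
from .synthetic import (
    amplitude_for_rmsf,
    anm_build,
    build_toy_structure,
    constraint_assigner_from_sidecar,
    fixture_spec,
    ground_truth,
    sample_ensemble,
)
from .rigidity import BodyBarGame, body_bar_rank, ensemble_weak_spot_frequencies

__all__ = [
    "pebble_rank_agreement",
    "hinge_recovery",
    "weak_spot_recovery",
    "dfc_bruteforce",
    "dfc_oracle_error",
    "pca_svd_error",
]


# ---------------------------------------------------------------------------
# pebble game vs generic rigidity-matrix rank
# ---------------------------------------------------------------------------

def _play(n: int, edge_bars: list[tuple[int, int, int]]) -> int:
    pairs = np.array([(u, v) for (u, v, _) in edge_bars], dtype=int).reshape(-1, 2)
    game = BodyBarGame(n, pairs)
    for u, v, b in edge_bars:
        game.add_bars(u, v, b)
    return game.n_independent


def _expand(edge_bars):
    bars = []
    for u, v, b in edge_bars:
        bars.extend([(u, v)] * b)
    return bars


def pebble_rank_agreement(
    seed: int = 0,
    n_random_five: int = 500,
    n_random_eight: int = 200,
) -> dict:
    """Agreement rate of the pebble game with the generic rank oracle.

    Covers: every multigraph on 3 bodies with 0-6 bars per pair; every
    multigraph on 4 bodies with bars per pair in {0, 2, 5, 6} (the bar
    counts molecular constraints actually use); seeded random multigraphs
    on 5 bodies with 0-6 bars; and random multigraphs on up to 8 bodies.
    """
    rng = np.random.default_rng(seed)
    n_cases = 0
    n_agree = 0

    def check(n, eb):
        nonlocal n_cases, n_agree
        if not eb:
            return
        n_cases += 1
        if _play(n, eb) == body_bar_rank(n, _expand(eb), rng=rng):
            n_agree += 1

    pairs3 = list(itertools.combinations(range(3), 2))
    for bars in itertools.product(range(7), repeat=len(pairs3)):
        check(3, [(u, v, b) for (u, v), b in zip(pairs3, bars) if b > 0])

    pairs4 = list(itertools.combinations(range(4), 2))
    for bars in itertools.product((0, 2, 5, 6), repeat=len(pairs4)):
        check(4, [(u, v, b) for (u, v), b in zip(pairs4, bars) if b > 0])

    pairs5 = list(itertools.combinations(range(5), 2))
    for _ in range(n_random_five):
        bars = rng.integers(0, 7, len(pairs5))
        check(5, [(u, v, b) for (u, v), b in zip(pairs5, bars) if b > 0])

    for _ in range(n_random_eight):
        n = int(rng.integers(2, 9))
        edges = {}
        for _ in range(int(rng.integers(1, 3 * n + 1))):
            u, v = rng.integers(0, n, 2)
            if u == v:
                continue
            key = (min(u, v), max(u, v))
            edges[key] = min(edges.get(key, 0) + int(rng.integers(1, 7)), 6)
        check(n, [(u, v, b) for (u, v), b in edges.items()])

    return {
        "n_cases": n_cases,
        "n_agree": n_agree,
        "agreement_pct": 100.0 * n_agree / n_cases,
    }


# ---------------------------------------------------------------------------
# hinge recovery on two-domain ensembles
# ---------------------------------------------------------------------------

def hinge_recovery(
    n_runs: int = 20,
    n_frames: int = 500,
    seed: int = 0,
    tolerance: int = 2,
) -> dict:
    """Fraction of seeded two-domain ensembles whose slow-mode minimum and
    force-constant maximum land inside the designed linker (± tolerance)."""
    slow_hits = 0
    dfc_hits = 0
    for run in range(n_runs):
        run_seed = seed * 1000 + run
        spec, params = fixture_spec("two-domain", seed=run_seed)
        structure = build_toy_structure(spec)
        model = anm_build(structure, cutoff=params["anm_cutoff"])
        amplitude = amplitude_for_rmsf(model, params["target_rmsf"])
        ensemble = sample_ensemble(
            model, n_frames, amplitude=amplitude, seed=run_seed + 1,
            structure=structure,
        )
        aligned = superpose(ensemble)
        a, b = spec.linker_ranges[0]

        profile = slow_mode_profile(pca(aligned), k_modes=3)
        lo = 2  # terminal residues are hinge-ineligible
        amin = lo + int(np.argmin(profile.values[lo:-lo]))
        slow_hits += a - tolerance <= amin <= b + tolerance

        k = distance_fluctuation_force_constants(aligned, "ca").k
        amax = int(np.argmax(k))
        dfc_hits += a - tolerance <= amax <= b + tolerance

    return {
        "n_runs": n_runs,
        "slow_mode_pct": 100.0 * slow_hits / n_runs,
        "force_constant_pct": 100.0 * dfc_hits / n_runs,
    }


# ---------------------------------------------------------------------------
# weak-spot recovery on a designed-weak-region ensemble
# ---------------------------------------------------------------------------

def weak_spot_recovery(
    seed: int = 0,
    n_frames: int = 500,
    n_samples: int = 500,
) -> dict:
    """Weak-spot frequency study on the weak-patch toy.

    Returns the fraction of designed weak residues ranked in the top decile
    of weak-spot frequency, and the fraction of snapshots whose
    giant-cluster series is non-increasing (1.0 = all)."""
    spec, params = fixture_spec("weak-patch", seed=seed)
    structure = build_toy_structure(spec)
    model = anm_build(structure, cutoff=params["anm_cutoff"])
    amplitude = amplitude_for_rmsf(model, params["target_rmsf"])
    ensemble = sample_ensemble(
        model, n_frames, amplitude=amplitude, seed=seed + 1, structure=structure
    )
    gt = ground_truth(spec, model, amplitude)
    gt["constraint_energies"] = {
        "strong": -12.0, "weak": -2.0, "contact_cutoff": 5.5,
        "min_sequence_sep": 3, "jitter": 0.05, "seed": seed,
    }
    source = constraint_assigner_from_sidecar(gt)
    profile = ensemble_weak_spot_frequencies(
        ensemble, n_samples=n_samples, constraint_source=source,
        collect_series=True,
    )
    designed = set(spec.weak_residues)
    top = profile.top_fraction(0.1)
    monotone = sum(
        1 for series in profile.giant_series if np.all(np.diff(series) <= 0)
    )
    return {
        "n_snapshots": profile.n_snapshots,
        "recovery_pct": 100.0 * len(top & designed) / len(designed),
        "monotonic_fraction": monotone / len(profile.giant_series),
        "n_no_transition": profile.n_no_transition,
        "designed_min_frequency": float(profile.frequencies[sorted(designed)].min()),
    }


# ---------------------------------------------------------------------------
# small numeric oracles
# ---------------------------------------------------------------------------

def dfc_bruteforce(
    frames: np.ndarray, temperature: float = 300.0, exclude_neighbors: int = 1
) -> np.ndarray:
    """Loop-based reference for the distance-fluctuation force constant
    (one site per residue); independent of the vectorised implementation."""
    n_frames, n_sites, _ = frames.shape
    kBT = BOLTZMANN_KCAL * temperature
    out = np.empty(n_sites)
    for i in range(n_sites):
        d_series = []
        for t in range(n_frames):
            ds = []
            for j in range(n_sites):
                if abs(i - j) <= exclude_neighbors:
                    continue
                ds.append(float(np.linalg.norm(frames[t, i] - frames[t, j])))
            d_series.append(float(np.mean(ds)))
        out[i] = 3 * kBT / np.var(d_series, ddof=1)
    return out


def _ad_hoc_structure(coords):
    from .structures import Structure

    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.full(n, "CA", dtype="U6"),
        element=np.full(n, "C", dtype="U2"),
        chain=np.full(n, "A", dtype="U4"),
        resnum=np.arange(1, n + 1),
        icode=np.full(n, "", dtype="U1"),
        resname=np.full(n, "GLY", dtype="U5"),
        coords=coords,
        occupancy=np.ones(n),
        b_factor=np.zeros(n),
    )


def dfc_oracle_error(seed: int = 0) -> float:
    """Max relative deviation of the force-constant statistic from the
    brute-force oracle on a hand-sized 3-particle ensemble."""
    rng = np.random.default_rng(seed)
    frames = rng.uniform(-5, 5, (12, 3, 3))
    ensemble = ConformationalEnsemble(_ad_hoc_structure(frames[0]), frames)
    k = distance_fluctuation_force_constants(ensemble, "ca", exclude_neighbors=0).k
    oracle = dfc_bruteforce(frames, exclude_neighbors=0)
    return float(np.max(np.abs(k - oracle) / oracle))


def pca_svd_error(seed: int = 0, n_frames: int = 200) -> float:
    """Max absolute eigenvalue deviation of the PCA from an SVD oracle on a
    weak-patch ensemble."""
    spec, params = fixture_spec("weak-patch", seed=seed)
    structure = build_toy_structure(spec)
    model = anm_build(structure, cutoff=params["anm_cutoff"])
    amplitude = amplitude_for_rmsf(model, params["target_rmsf"])
    ensemble = superpose(sample_ensemble(
        model, n_frames, amplitude=amplitude, seed=seed + 1, structure=structure
    ))
    spectrum = pca(ensemble)
    ca = ensemble.topology.ca_indices()
    x = ensemble.frames[:, ca, :].reshape(n_frames, -1)
    sv = np.linalg.svd(x - x.mean(0), compute_uv=False)
    oracle = sv ** 2 / (n_frames - 1)
    m = len(oracle)
    return float(np.max(np.abs(spectrum.eigvals[:m] - oracle)))
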