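#!/usr/bin/env python
"""Collective dynamics of the two-domain ensemble: PCA slow modes and hinges.

The slow-mode profile's minima should sit in the designed linker; this is
scored over 20 independently seeded ensembles (together with the
force-constant route to the same hinge) and written under
``results/collective/``.
"""

import json
from pathlib import Path

import numpy as np

import ensembleflex as ef
from ensembleflex.studies import hinge_recovery

ROOT = Path(__file__).resolve().parent.parent
FIXTURES = ROOT / "results" / "fixtures"
OUT = ROOT / "results" / "collective"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pdb = FIXTURES / "two-domain.pdb"
    if not pdb.exists():
        ef.generate_fixture("two-domain", seed=SEED, n_frames=500, out_dir=FIXTURES)
    ensemble = ef.read_ensemble(pdb)
    sidecar = json.loads((FIXTURES / "two-domain.json").read_text())
    aligned = ef.superpose(ensemble)
    header = [f"ensembleflex analysis, seed {SEED}"]

    spectrum = ef.pca(aligned)
    top3 = spectrum.eigvals[:3] / spectrum.eigvals.sum()
    print(f"PCA: first three modes carry {100 * top3.sum():.0f}% of the variance "
          f"({', '.join(f'{100 * v:.0f}%' for v in top3)})")

    profile = ef.slow_mode_profile(spectrum, k_modes=3)
    ef.write_residue_table(profile.values, OUT / "slow_mode_profile.tsv",
                           ensemble.topology, "norm_sq_disp", header)
    hinges = ef.identify_hinges(profile)
    linker = sidecar["linker_ranges"][0]
    print(f"hinge residues (0-based): {hinges}; designed linker: {linker}")

    recovery = hinge_recovery(n_runs=20, n_frames=500, seed=SEED)
    print(f"over 20 seeded ensembles: slow-mode minimum inside linker ±2 in "
          f"{recovery['slow_mode_pct']:.0f}% of runs, force-constant maximum in "
          f"{recovery['force_constant_pct']:.0f}%")
    (OUT / "hinge_recovery.json").write_text(json.dumps(recovery, indent=1))
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    main()
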