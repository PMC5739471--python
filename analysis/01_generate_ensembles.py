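#!/usr/bin/env python
"""Generate the three synthetic conformational ensembles the analyses run on.

Writes multi-model PDB fixtures plus ground-truth sidecars (designed hinge
location, weak region, analytic per-residue variance) under
``results/fixtures/``:

* two-domain   — equal compact domains on a flexible linker (hinge study)
* weak-patch   — asymmetric domains, one row of designed-weak constraints
                 (thermal-unfolding / weak-spot study)
* rigid-block  — a single compact domain (negative control)
"""

import json
from pathlib import Path

import ensembleflex as ef

SEED = 1
N_FRAMES = 500
OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    for kind in ef.FIXTURE_KINDS:
        res = ef.generate_fixture(kind, seed=SEED, n_frames=N_FRAMES, out_dir=OUT)
        gt = res["ground_truth"]
        print(f"{kind}: {gt['n_residues']} residues, {N_FRAMES} frames -> {res['pdb']}")
        if gt["linker_ranges"]:
            print(f"  designed hinge (linker residues, 0-based): {gt['linker_ranges']}")
        if gt.get("weak_region"):
            print(f"  designed weak region (0-based): {gt['weak_region']}")
    print(f"\nfixtures and sidecars written under {OUT}")


if __name__ == "__main__":
    main()
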