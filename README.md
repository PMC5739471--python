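# ensembleflex

Ensemble-based structural stability analysis for proteins: given a
conformational ensemble (a multi-model PDB, a directory of snapshots, or
the bundled synthetic generator), the package computes

* per-residue **RMSF / B-factor** mobility profiles,
* **distance-fluctuation force constants** `k_i = 3 k_B T / Var(d_i)`,
  where `d_i` is residue *i*'s mean distance to all other residues — rigid,
  allosterically central sites carry large `k_i`, and hinge centres show up
  as sharp peaks,
* **PCA slow-mode profiles** (normalized squared displacement over the
  largest-variance modes) with hinge detection at the profile minima,
* ensemble-averaged **residue depth** (distance to the solvent-accessible
  surface),
* **FIRST-style constraint-network rigidity**: atoms as rigid bodies joined
  by covalent bars, Mayo-energy hydrogen bonds, salt bridges and
  hydrophobic tethers, decomposed into rigid clusters with a (6,6)
  body-bar **pebble game**,
* **thermal-unfolding emulation**: the hydrogen-bond cutoff sweeps from
  −0.1 to −10 kcal/mol, weakest bonds dissolving first; the step where the
  giant rigid cluster breaks apart is the folded→unfolded transition,
  residues that leave the giant cluster there are **weak spots**
  (unfolding nuclei), and per-residue weak-spot frequencies are ranked
  over a 500-snapshot ensemble of networks.

It is written for structural bioinformaticians who have (or want to
emulate) MD ensembles of multi-domain assemblies — chaperone–client
complexes, kinases — and need reproducible per-residue stability maps.

Because real MD trajectories are rarely shippable, the package includes a
first-class synthetic generator: two-domain toy proteins whose ensembles
are drawn from an exact anisotropic-network-model Gaussian, with hinge
locations, fluctuation variances and designed-weak regions known by
construction. Every analysis stage is validated against that ground truth
or an independent oracle (brute-force force constants, SVD eigenvalues,
generic rigidity-matrix rank).

## Worked example

Generate a 500-frame ensemble of the weak-patch toy (45 residues, two
domains, a designed 5-residue weak region) and run the full pipeline:

```bash
flex fixture weak-patch --seed 1 --output-dir demo
flex pipeline demo/weak-patch.pdb --sidecar demo/weak-patch.json \
     --output-dir demo/report --seed 1
```

Equivalent analyses as scripts live under `analysis/` (each regenerates
its inputs if missing and writes tables under `results/`):

```text
$ python analysis/04_rigidity_unfolding.py
network: 94 designed noncovalent constraints over 270 atoms
giant cluster: 105 -> 84 atoms across the sweep
unfolding transition at cutoff -2.00 kcal/mol; weak spots (0-based): [18, 19, 20, 21, 22, 23]
designed weak region: [18, 19, 20, 21, 22]
rigidity index: designed-strong mean -10.0, designed-weak mean -2.0 kcal/mol (lower = rigid longer); 36 residues still rigid at the sweep end

$ python analysis/05_weak_spots.py
500 snapshots analysed (0 without a transition)
top-ranked weak spots (0-based): 18 (1.00), 19 (1.00), 20 (1.00), 21 (1.00), 22 (1.00), 23 (1.00), 0 (0.00), 1 (0.00)
designed weak residues: [18, 19, 20, 21, 22]
recovery: 100% of designed residues in the top decile; giant-cluster series monotone in 500/500 snapshots
```

Reading this: the designed weak constraints sit near −2 kcal/mol, so the
giant rigid cluster (105 atoms, the larger domain) loses exactly the weak
patch when the sweep passes −2 — the transition — and those residues are
the top-ranked weak spots in every one of the 500 per-snapshot networks.
Residues held by −12 kcal/mol constraints never unfold inside the sweep
(rigidity index −10.0, flagged). The hinge study is the same story on the
fluctuation side:

```text
$ python analysis/03_collective_modes.py
PCA: first three modes carry 96% of the variance (85%, 6%, 5%)
hinge residues (0-based): [24, 20]; designed linker: [20, 24]
over 20 seeded ensembles: slow-mode minimum inside linker ±2 in 100% of runs, force-constant maximum in 100%
```

All CLI subcommands (`fixture`, `rmsf`, `dfc`, `depth`, `pca`, `rigidity`,
`unfold`, `weakspots`, `pipeline`) accept `--seed` and `--output-dir`;
every output table starts with a header recording version, command line
and seed, and a fixed seed reproduces outputs byte for byte.

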