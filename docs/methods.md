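# Methods

`ensembleflex` characterises the structural stability of a protein from a
conformational ensemble (a set of aligned snapshots, e.g. from molecular
dynamics) along two complementary routes: **fluctuation statistics** that
read stability off the ensemble's geometry, and a **constraint-network
rigidity analysis** that reads it off the topology of each snapshot's bond
network. A synthetic ensemble generator with exactly known ground truth
closes the loop: every statistic the package computes can be scored against
what the generator built in.

## Fluctuation statistics

**RMSF and B-factors.** After least-squares superposition (Kabsch, one
iteration against the ensemble mean), the per-residue root-mean-square
fluctuation of the Cα atoms is

    RMSF_i = sqrt( <|r_i - <r_i>|^2> ),     B_i = (8π²/3) RMSF_i².

**Distance-fluctuation force constants.** For residue *i*, let
`d_i(t) = <d_ij(t)>_{j*}` be its instantaneous mean distance to all other
residues, excluding *i* itself and its chain neighbours *i±1* (their
distances are nearly constant). The effective force constant is

    k_i = 3 k_B T / Var(d_i),    k_B T = 0.5961 kcal/mol at T = 300 K,

in kcal·mol⁻¹·Å⁻², using the sample variance (N−1) over frames. Rigid,
allosterically central sites barely change their mean distances and carry
large k_i; hinge centres appear as sharp peaks. Because only internal
distances enter, the statistic is invariant under global rotation and
translation of every frame, and doubling T doubles every finite k_i
exactly. Two representations are supported: `ca` (one site per residue) and
`allatom` (per-atom statistic against all atoms of non-neighbouring
residues, averaged within the residue); the neighbour-exclusion rule is
applied uniformly in both. Sites whose distance variance falls below
ε = 1e−8 Å² (e.g. rigid-rotation ensembles) are capped at k = 1e6 and
flagged rather than reported as infinite.

**PCA slow modes and hinges.** The covariance of the superposed Cα
coordinates is diagonalised; in the MD convention the largest-variance
principal components are the slowest collective modes. The per-residue
normalized squared displacement summed over the first k modes (k = 3 for
profiles, 5 for structural maps) forms the slow-mode profile; it sums to 1
and is invariant to eigenvector sign. Mode combination defaults to
eigenvalue weighting (each mode contributes in proportion to its variance);
uniform weighting is available since either convention is defensible.
Hinges are sliding-window local minima of the profile (window 5) that also
fall below the 0.1 profile quantile; the two terminal residues at each end
are ineligible because chain termini are trivially mobile.

**Residue depth.** Each atom sphere (van der Waals radius + 1.4 Å probe) is
covered with ≥ 64 quasi-uniform dots (golden-angle spiral); a dot is
solvent-accessible if it lies outside every other atom's probe-expanded
sphere. An atom's depth is its distance to the nearest accessible dot minus
its own expanded radius (0 for surface atoms); residues average over their
atoms and ensembles average over frames (subsampled by a configurable
stride, default 10). The dot-surface approximation does not remove interior
probe-sized cavities; for densely packed structures this does not matter,
for loosely packed ones depth can be underestimated.

## Constraint-network rigidity

**Network construction.** Atoms are rigid bodies (6 degrees of freedom);
interactions are bar constraints:

| constraint                  | bars | source |
|-----------------------------|------|--------|
| rotatable covalent bond     | 5    | backbone name templates + covalent-radius fallback |
| locked covalent bond        | 6    | peptide C–N links, double bonds (C=O) |
| hydrogen bond / salt bridge | 5    | geometric detection, energy-gated |
| hydrophobic tether          | 2    | C/S pairs within vdW sum + 0.25 Å |

Hydrogen bonds are detected from donor–H⋯acceptor geometry (N/O donor with
bonded H, donor–acceptor ≤ 3.6 Å, D–H–A angle > 100°) and scored with a
Mayo-form well over the donor–acceptor distance,

    E = V₀ [5 (d₀/d)¹² − 6 (d₀/d)¹⁰] cos²θ,   V₀ = 8 kcal/mol, d₀ = 2.8 Å,

so an ideal linear 2.8 Å bond scores −8 kcal/mol. The full angular form
used by molecular rigidity codes branches on donor/acceptor hybridisation;
the cos²θ factor keeps the well depth and the distance/angle gates without
requiring hybridisation assignment, which is the level of detail the
synthetic studies need. Salt bridges (charged-group N/O pairs within 4 Å)
get a fixed −10 kcal/mol so they persist deep into the unfolding sweep.
Only hydrogen bonds/salt bridges with E < E_cut (default −1.0 kcal/mol)
enter the network; hydrophobic tethers use the vdW radii 1.7 Å (C) and
1.8 Å (S) plus a 0.25 Å pad, excluding pairs within three covalent bonds.
When a pair carries several constraint types the strongest wins
(covalent > hydrogen bond > tether). Structures without hydrogens raise an
explicit error rather than silently finding no bonds.

**Pebble game.** Rigid-cluster decomposition uses the (6,6) body-bar pebble
game: 6 pebbles per body; a bar is independent if 7 pebbles can be gathered
on its endpoints, and then consumes one. Independent-bar counts equal the
generic rank of the body-bar rigidity matrix (Tay's theorem); the package
carries a separate numeric rank oracle (random generic bar attachments,
SVD rank) used only for validation, and the test suite checks agreement on
exhaustive 3-body multigraphs (0–6 bars/pair), exhaustive 4-body
multigraphs over the molecular bar counts {2,5,6}, and seeded random 5–8
body graphs. Clusters are read from the pebble configuration: pin 6
pebbles on a seed body; exactly the bodies with no directed path to a free
pebble are rigid with it. Mutual rigidity of bodies is transitive, so
clusters partition the atoms; the decomposition is independent of bar
insertion order. The inner loops are numba-compiled, and the pair
bookkeeping uses a dense (n_atoms)² orientation matrix — ample for
per-snapshot networks of a few thousand atoms, the intended scale.

**Thermal unfolding.** The hydrogen-bond cutoff sweeps from −0.1 to
−10.0 kcal/mol in 0.1 steps (configurable): weaker bonds drop out first,
emulating rising temperature, while covalent bonds and hydrophobic tethers
are retained throughout. Internally the sweep runs in reverse (strongest
cutoff first) so the incremental pebble game only ever gains constraints;
the recorded series is flipped into unfolding order, which also guarantees
the giant-cluster size series is non-increasing by construction of the
constraint nesting. The **transition** is the step with the largest
single-step drop in giant-cluster size, ties resolving to the earliest
step (the analysis needs one operational criterion for "breaks apart"; the
largest drop is the natural one and the tie rule makes it deterministic).
A flat series yields a no-transition sentinel.

**Rigidity index.** For each residue, r_i is the cutoff at which its two
backbone bonds (N–Cα, Cα–C) first fall outside every rigid cluster,
averaged over the two bonds; lower (more negative) r_i means the residue
stays rigid longer. Residues still rigid at the sweep end are assigned
r = E_end and flagged.

**Weak spots.** At the transition, residues whose Cα belongs to the giant
cluster immediately before and is flexible immediately after — not in the
giant cluster, and in no rigid cluster of ≥ 4 atoms — are weak spots
(unfolding nuclei). Over an ensemble, unfolding runs on up to 500
snapshots taken evenly along the trajectory, each with its own geometry-
derived network; a residue's weak-spot frequency is the fraction of
snapshots in which it qualifies (snapshots without a transition contribute
empty sets and are counted), and residues are ranked by decreasing
frequency.

## The synthetic generator, and what it does and does not emulate

The toy protein is a chain of compact serpentine lattice domains (3.8 Å Cα
spacing everywhere, including turns) joined by extended, slightly
zigzagged linkers; each residue carries an idealized backbone (N, Cα, C,
O), an amide hydrogen and a short pseudo-side-chain carbon. The zigzag
matters: a perfectly collinear linker would leave the second domain a free
torsion in the elastic network. Lattice spacings are chosen so no two
carbons of different residues fall inside the hydrophobic-tether cutoff —
domain rigidity then rests entirely on the designed noncovalent
constraints, which makes the unfolding ground truth exact.

Ensembles are drawn from the Gaussian of an anisotropic network model
(pairwise Cα springs inside a cutoff; Hessian eigenmodes) rather than from
toy dynamics, because the ANM covariance is analytic: per-residue variances
equal the diagonal blocks of the Hessian pseudo-inverse, giving exact
oracles for RMSF, PCA and force-constant behaviour. All atoms of a residue
translate with their Cα, so intra-residue geometry is preserved in every
snapshot. Sampling amplitude is set by a target mean RMSF (1.5 Å for the
hinge study, 0.7 Å for the rigidity study — large enough to decorrelate
snapshot networks, small enough to keep domains intact).

Three fixture presets define the study conditions:

* **two-domain** (20+20 residues, 5-residue linker, ANM cutoff 20 Å):
  equal domains centre the hinge pivot in the linker; ground truth is that
  slow-mode minima and force-constant maxima fall inside the linker.
* **weak-patch** (24+16 residues, linker 5, cutoff 15 Å): designed
  hydrogen-bond-like constraints join backbone N/O atoms of residue pairs
  within 5.5 Å (sequence separation ≥ 3); constraints touching the
  5-residue weak patch (the last row of the larger domain) get energies
  near −2 kcal/mol, all others near −12 kcal/mol — below the sweep floor,
  so the designed scaffold persists to the end and the only transition is
  the weak patch detaching. A 0.05 kcal/mol seeded jitter makes the
  removal order total. Ground truth: the transition sits at ≈ −2 kcal/mol
  and the weak residues are the top-ranked weak spots.
* **rigid-block** (single 24-residue domain): negative control.

What passing these studies shows: the statistics, the pebble game and the
unfolding machinery are correct on systems where the answer is known
exactly. What it does not show: behaviour on real MD ensembles — the toys
have no side-chain rotamers, no realistic hydrogen-bond geometry or energy
spectrum, no solvent, and fluctuation magnitudes far more homogeneous than
real proteins. Mayo-energy hydrogen-bond detection is therefore exercised
on hand-built geometries separately from the designed-energy studies.

## Numerical choices and degenerate inputs

* ANM rigid-body modes are identified by eigenvalue < 1e−8 relative to the
  largest; a connected non-degenerate network has exactly 6 (collinear
  geometries are flagged as degenerate, disconnected networks raise).
* Force-constant cap 1e6 kcal·mol⁻¹·Å⁻² at variance floor 1e−8 Å²
  (flagged, never silently infinite).
* Transition ties → earliest step; weak-spot ranking ties → stable order
  by residue index.
* Superposition requires ≥ 3 selected atoms; fluctuation statistics
  require ≥ 2 frames; a single-frame ensemble passes through superposition
  unchanged.
* Alternate locations resolve to the highest-occupancy conformer on read.
* Covalent topology is name/sequence-templated for backbone atoms with a
  covalent-radius distance fallback for anything else, so unknown residues
  and ligands still receive bonds.
* The rank oracle resamples generic attachments twice and takes the
  maximum rank, guarding against accidental degeneracy of one draw.

## Known limitations

* The dense pair matrix in the pebble game bounds networks to a few
  thousand bodies; per-residue coarse networks or sparser bookkeeping
  would be needed far beyond that.
* Residue depth uses an accessible-dot surface without cavity suppression.
* The hydrogen-bond angular term does not distinguish donor/acceptor
  hybridisation, and hydrogens are required (no hydrogen inference is
  performed beyond the generator's idealized amide hydrogens).
* Designed constraint energies, not Mayo energies, drive the synthetic
  unfolding studies; the two meet only in the shared network/pebble/sweep
  machinery.
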