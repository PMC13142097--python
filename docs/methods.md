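# Methods

## Scope and model

`pdzflex` quantifies per-residue conformational diversity of protein
domains from four observables and cross-checks them against each other:

1. **Multi-structure Cα RMSD.** Domain copies are harvested from
   multi-chain crystal structures by author residue range, restricted to
   the residues resolved in *all* copies, and compared all-against-all
   after optimal rigid superposition. The per-residue profile is the mean,
   over pairs, of the per-site deviation after each pair's superposition.
2. **Crystallographic B-factors**, via the isotropic relation
   B = 8π²⟨u²⟩, where ⟨u²⟩ is the per-direction mean-square displacement.
3. **Trajectory RMSF** about the iteratively refined mean structure,
   averaged over independent replicates.
4. **Steady-state heteronuclear NOE ratios** I_sat/I_unsat, which drop
   with fast-timescale backbone mobility.

Flexible regions are maximal contiguous runs of profile values strictly
beyond a threshold. Defaults: average pairwise RMSD > 1.0 Å, RMSF >
0.12 Å, NOE ratio < 0.75, B-factor above the grand mean of the averaged
track. Runs shorter than 2 residues are treated as single-residue spikes
and not called; gaps in residue numbering break runs because a profile
asserts nothing about unmodelled residues. All comparisons are strict, so
a value exactly at the threshold is never flagged.

## Superposition

The Kabsch solution: centre both point sets (over the fit selection),
take the SVD of the cross-covariance H = Aᵀ B, and form R = V diag(1,1,d) Uᵀ
with d = sign(det(V Uᵀ)), which corrects reflections so det(R) = +1
always, including on mirrored inputs. Fit sets must contain at least three
non-collinear points (rank checked at relative tolerance 1e-8); RMSD and
per-site deviations are reported over **all** sites even when the fit uses
a subset (needed for rigid-core profiling). Fixed numerical contracts:
rotations orthonormal to 1e-10, pair RMSD symmetric to 1e-8 Å, and
rmsd² equals the mean squared per-site deviation to 1e-10 relative.

Two independent reference implementations live in `pdzflex.reference` for
cross-checking: an exhaustive z-y-z Euler rotation-grid search (global 6°
scan refined locally to 1°, translation handled exactly by centroid
matching, cost evaluated through tr(R·M) so the scan is O(1) per rotation
in the number of points) and Horn's closed-form quaternion method (largest
eigenvalue of the 4×4 key matrix). They share no code path with the SVD
route.

## Clustering

Agglomerative clustering runs directly on the precomputed RMSD matrix with
average (UPGMA, default), single or complete linkage. The linkage choice
is configuration because published ensemble analyses rarely state it;
UPGMA is monotone, so merge heights never decrease. Ties in the minimum
inter-cluster distance are broken deterministically by the smallest
lexicographic pair of cluster representatives (a cluster's representative
is its lexicographically smallest member label) — this is why the
implementation is in-package rather than delegated to scipy, whose
tie-breaking is unspecified; scipy's `linkage` serves as a cross-check
oracle in the tests on tie-free matrices. Flat cuts replay the first
n − k merges; inter-cluster distances default to the mean over all
cross-pairs (consistent with average linkage), with min/max variants.
Dendrograms export as ultrametric Newick (leaf depth = merge height / 2).

## Per-residue averaging

The pair set for the per-residue average pairwise RMSD is configurable:
all pairs (default) or within-group pairs (e.g. per chain), because both
groupings are scientifically meaningful — all-pairs measures total
ensemble spread, within-chain pairs isolate diversity from systematic
chain differences caused by crystal packing. The superposition per pair
defaults to a global fit on all common residues; a core `fit_selection`
is available when a rigid reference frame is wanted. Both options are
kept because the choice measurably shifts loop amplitudes.

## B-factors

Members are ranked by the mean Cα B over common residues; the extreme
members' tracks are reported with the per-residue mean over all members.
Per-residue B is the Cα B-factor, not a residue average over atoms,
matching the Cα basis of the rest of the pipeline. No cross-crystal
resolution/overall-B normalisation is applied by default (raw B values are
plotted in practice); an optional per-member z-score mode removes overall
offsets when crystals of very different quality are mixed.

## RMSF

Frames are windowed to [t_min, t_max] and subsampled by matching target
times t_min + k·stride to the nearest frame in the window (so a stride
equal to the native spacing is a pure window cut). Each replicate is
superposed iteratively onto the running mean structure over the fit
selection, starting from the first frame as reference, until the mean
moves < 1e-6 Å (max 10 iterations). The reference is the refined mean,
not frame 1, because the mean minimises the summed fluctuation and makes
RMSF independent of which frame happens to come first. Replicates
aggregate residue-wise into mean and *population* standard deviation
(SD = 0 for a single replicate). Units are Å throughout; an explicit
nm→Å converter (×10) is provided for trajectory data produced in
nanometres — note that with nm-native tooling a 0.12 printed threshold
would be 1.2 Å, so the threshold is configurable and defaults to 0.12 Å.

For iid per-coordinate Gaussian noise of scale σ the expected RMSF is
σ√3 (E|u|² = 3σ²); the delta-method standard error of the per-residue
estimate over T frames is σ/√(2T). This analytic law is the oracle for
the trajectory stack.

## Contacts

A residue pair across two domains is a contact when any heavy-atom pair
(elements other than H/D; waters excluded) is within 4.5 Å. Hydrogen
bonds are approximated donor/acceptor-agnostically as N/O–N/O pairs
within 3.5 Å with no angular term, since crystal models usually lack
hydrogens; both cutoffs are parameters, and the drivers report
cutoff sensitivity rather than asserting a single participation figure.
Region participation is the fraction of a span's residues appearing in at
least one contact pair; spans with participation above 0.8 are treated as
interface-held.

## Synthetic data

The generator emulates the study conditions of a tandem-PDZ crystal
campaign: 10 structures × 2 chains, each chain carrying a PDZ1-like
domain (residues 114–193) and a PDZ2-like domain (197–273) on a shared
helical Cα scaffold (radius 2.28 Å, rise 1.5 Å, 100°/residue → consecutive
spacing 3.80 ± 0.02 Å, seeded 0.01 Å perturbation). Flexibility is iid
per-coordinate Gaussian displacement about the shared scaffold: σ = 1.5 Å
inside the flexible spans (defaults: chain B PDZ1, residues 119–125 and
181–184), σ = 0.05 Å elsewhere, plus a per-structure rigid-body jitter
(rotation ≤ 5°, translation ≤ 2 Å) that the superposition stage must
remove. Chain asymmetry — the crystal-packing restraint that renders one
chain's copies more uniform — is modelled simply as the *absence* of the
elevated-σ regions on chain A, not as explicit lattice neighbours.
B-factors are written as 8π²σ² of the generating σ; because σ is the same
for every structure, the per-member B tracks are identical and the
highest/lowest-B member ranking is degenerate by construction.

Trajectories are scaffold + iid Gaussian noise per residue-wise σ map; the
defaults use σ = 0.4 Å for flexible loops (RMSF σ√3 ≈ 0.69 Å, well above
the 0.12 Å flag) and σ = 0.05 Å for the scaffold (≈ 0.087 Å, below it).
"Tandem" runs divide σ by 3 inside restrained interface spans, emulating
cross-domain contacts. NOE tables use
ratio = clip(0.85 − 0.2·σ + ε, 0, 1), ε ~ N(0, 0.02), I_unsat = 1, so
σ = 1.5 Å loops land at ≈ 0.55 (flagged at < 0.75) and scaffold residues
at ≈ 0.84. RNG streams are separated per artifact kind by spawning child
`SeedSequence`s, so identical seeds give byte-identical files and the
artifact kinds do not perturb each other. Ground truth is emitted beside
every dataset so tests never re-derive it from generator internals.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: correlated loop modes and anisotropic motions
(displacements are iid and isotropic), systematic mean-structure shifts
between chains (real chain-A/chain-B clusters arise from packing-induced
*conformational* differences, not just variance differences, so the k=2
cut on synthetic data does not split by chain the way real heatmaps do),
refinement artefacts and model bias in B-factors, chemical-exchange
contributions to NOE ratios, and solvent/force-field physics in
trajectories. Real-data runs should treat thresholds as starting points
and inspect cutoff sensitivity.

## Problem sizes

Default problem sizes were chosen to keep each stage desk-scale while
leaving the statistical margins wide: 10 crystals × 2 chains (20 members,
190 pairs), 100 seeded ensembles for region-recovery rates, 1600 frames
for the RMSF law (3·SE ≈ 0.02 Å at σ = 0.4 Å), 300-frame trajectories
for the 20-seed restraint comparisons, and 50 random instances for the
superposition-oracle sweep.

## Known limitations

- Residue correspondence is by author number (plus insertion code) only;
  no sequence alignment, so ensembles across different numbering schemes
  must be renumbered first.
- Binary MD formats are out of scope; trajectories enter as TSV or
  multi-model PDB.
- The hydrogen-bond proxy ignores geometry beyond distance.
- Region calling reports maximal runs; nested/overlapping structure in a
  profile (e.g. a spike inside a broad region) is not decomposed.
- `flat_clusters` cuts by merge order, which for non-monotone linkages
  (not the defaults) may differ from a height cut.
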