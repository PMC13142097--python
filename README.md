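# pdzflex

Conformational-diversity analysis of tandem PDZ domains from
crystal-structure ensembles, MD trajectories and NMR relaxation data.

## The problem

Multidomain scaffold proteins such as syntenin-1 carry two sequentially
similar PDZ domains (PDZ1, residues 114–193; PDZ2, residues 197–273) that
behave very differently: one can be intrinsically flexible in the loops
flanking its ligand-binding groove while the other stays rigid. A single
crystal structure — or its B-factors alone — cannot establish this.
What can is a *multi-structure* comparison: superpose every pair of domain
copies harvested from many crystals and ask, residue by residue, where
they disagree; then cross-validate the flexible regions against MD
fluctuations and solution-state heteronuclear NOE ratios.

`pdzflex` implements that pipeline for anyone with a set of PDB/mmCIF
files, trajectory frames or NOE peak tables:

- **Domain extraction** by author residue range from multi-chain crystals
  (altloc resolution by occupancy, gap bookkeeping).
- **Kabsch superposition**: the optimal proper rotation/translation via
  SVD of the cross-covariance matrix, with reflection correction, giving
  the Cα RMSD `sqrt(mean_i |R x_i + t − y_i|²)` and per-site deviations.
- **All-pairs RMSD matrices** with agglomerative clustering (UPGMA by
  default), flat cuts, inter-cluster distances and Newick export.
- **Per-residue average pairwise RMSD** profiles with flexible-region
  calling at a strict threshold (default > 1.0 Å, runs of ≥ 2 residues).
- **B-factor aggregation**: highest/average/lowest-B structure tracks and
  above-average flagging, using the isotropic relation B = 8π²⟨u²⟩.
- **Trajectory RMSF**: frame windowing/striding, iterative superposition
  onto the mean structure, replicate mean ± SD, > 0.12 Å flagging.
- **Heteronuclear NOE ratios** I_sat/I_unsat with < 0.75 flagging.
- **Interdomain contacts**: heavy-atom cutoff contacts (4.5 Å), N/O–N/O
  hydrogen-bond proxies (3.5 Å) and region contact participation.
- **A synthetic-data generator** that produces all of the above with
  known ground truth, so every stage is verifiable without downloads.

## Worked example

Generate a synthetic study — 10 two-chain crystals in which only chain B's
PDZ1 loops 119–125 and 181–184 are flexible (per-coordinate σ = 1.5 Å,
scaffold σ = 0.05 Å) — and analyse it:

```bash
pdzflex simulate --out run --seed 1
pdzflex diversity run/crystals/*.pdb --domain PDZ1 --out run/div
```

which logs

```
ensemble: 20 members, 80 common residues (0 dropped from the union)
diversity: 20 members, 2 regions > 1.0 A
```

and `run/div/regions.tsv` contains

```
first	last	length	peak	mean
119	125	7	2.342502	2.094475
181	184	4	2.151311	1.821896
```

i.e. the two injected flexible loops, recovered exactly at the 1.0 Å
threshold, with peak average pairwise RMSD ≈ 2.3 Å. The same library calls
are available in Python (`read_structure`, `extract_domain`,
`build_ensemble`, `pairwise_rmsd_matrix`, `per_residue_avg_rmsd`,
`call_regions`, …).

The `analysis/` directory holds numbered drivers that run the whole story
end to end (simulate → crystal diversity → B-factors → RMSF → NOE →
contacts), printing what each stage found and writing tables under
`results/`. On the default datasets they report, among other things,
within-chain mean pairwise RMSD of 0.12 Å (chain A) vs 1.34 Å (chain B)
for PDZ1, no PDZ2 region above 1.0 Å, NOE ratios ≈ 0.55 in the flexible
loops, and a 0.45 Å RMSF drop at the restrained interface span in the
tandem context.

## Layout

```
src/pdzflex/      library (structure IO, superposition, diversity,
                  B-factor, RMSF, NOE, contacts, synthetic data, CLI)
analysis/         numbered narrative drivers over the library
tests/            pytest suite, including end-to-end acceptance tests
scripts/          acceptance script
docs/methods.md   models, parameters, numerical choices, limitations
```
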