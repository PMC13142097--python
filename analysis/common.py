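"""Shared plumbing for the analysis drivers: dataset location and generation.

The synthetic datasets are materialised once under scratch/data/ (bulk
files) and summary tables are written under results/ by each driver.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

SEED = 20260921  # analysis-wide seed: date of the run
PDZ1_RESIDUES = np.arange(114, 194)
LOOPS = [(119, 125), (181, 184)]
INTERFACE = [(132, 135)]
N_REPLICATES = 5
N_FRAMES = 400


def ensure_data(force: bool = False) -> Path:
    """Generate the synthetic datasets if absent; return the data directory."""
    marker = DATA / "ground_truth.json"
    if marker.exists() and not force:
        return DATA
    from pdzflex.structure import write_structure_pdb
    from pdzflex.rmsf import write_trajectory_tsv
    from pdzflex.synthetic import (
        SyntheticEnsembleSpec,
        default_sigma_map,
        make_crystal_set,
        make_interface_model,
        make_noe_table,
        make_trajectory,
        write_ground_truth,
    )

    (DATA / "crystals").mkdir(parents=True, exist_ok=True)
    (DATA / "traj").mkdir(exist_ok=True)
    spec = SyntheticEnsembleSpec(seed=SEED)
    structures, truth = make_crystal_set(spec)
    for model in structures:
        write_structure_pdb(model, DATA / "crystals" / f"{model.structure_id}.pdb")

    sigma = default_sigma_map(PDZ1_RESIDUES, LOOPS + INTERFACE)
    for rep in range(1, N_REPLICATES + 1):
        traj = make_trajectory(
            N_FRAMES, sigma, seed=SEED + rep, residue_numbers=PDZ1_RESIDUES,
            replicate_id=f"single_rep{rep}",
        )
        write_trajectory_tsv(traj, DATA / "traj" / f"single_rep{rep}.tsv")
        tandem = make_trajectory(
            N_FRAMES, sigma, seed=SEED + 500 + rep, residue_numbers=PDZ1_RESIDUES,
            restrained_regions=INTERFACE, replicate_id=f"tandem_rep{rep}",
        )
        write_trajectory_tsv(tandem, DATA / "traj" / f"tandem_rep{rep}.tsv")

    noe_sigma = spec.sigma_map("B")[: PDZ1_RESIDUES.size]
    table = make_noe_table(noe_sigma, seed=SEED + 77, residue_numbers=PDZ1_RESIDUES)
    table.to_csv(DATA / "noe_pdz1.tsv", sep="\t", index=False, float_format="%.6f")

    iface, iface_truth = make_interface_model()
    write_structure_pdb(iface, DATA / "interface.pdb")
    truth["interface"] = iface_truth
    truth["trajectory"] = {
        "loop_regions": LOOPS,
        "interface_regions": INTERFACE,
        "loop_sigma": 0.4,
        "scaffold_sigma": 0.05,
        "restraint_factor": 3.0,
        "n_frames": N_FRAMES,
        "n_replicates": N_REPLICATES,
    }
    write_ground_truth(truth, marker)
    return DATA


def ground_truth() -> dict:
    ensure_data()
    return json.loads((DATA / "ground_truth.json").read_text())


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
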