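#!/usr/bin/env python
"""Materialise the synthetic study datasets.

Generates the 10 two-chain crystal-like structures (PDZ1-like domain
114-193 and PDZ2-like 197-273 per chain, chain-B PDZ1 loops 119-125 and
181-184 at sigma 1.5 A), five single-domain and five tandem-restrained
trajectory replicates, the NOE peak table and the all-atom interface
fixture, together with the ground-truth record every later driver checks
against.  Bulk files go to scratch/data/.
"""

import json

from common import DATA, ensure_data


def main() -> None:
    ensure_data(force=True)
    truth = json.loads((DATA / "ground_truth.json").read_text())
    n_crystals = len(list((DATA / "crystals").glob("*.pdb")))
    n_traj = len(list((DATA / "traj").glob("*.tsv")))
    print(f"wrote {n_crystals} crystal structures to {DATA / 'crystals'}")
    print(f"wrote {n_traj} trajectory replicates to {DATA / 'traj'}")
    print(f"flexible regions (ground truth): "
          + ", ".join(f"{r['chain_id']}:{r['domain']}:{r['first']}-{r['last']} "
                      f"sigma={r['sigma']} A" for r in truth["flexible_regions"]))
    print(f"scaffold sigma {truth['scaffold_sigma']} A; B-factors follow "
          f"{truth['bfactor_rule']}")


if __name__ == "__main__":
    main()
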