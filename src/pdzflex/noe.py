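"""Steady-state heteronuclear NOE ratio profiles.

The {1H}-15N NOE ratio I_sat / I_unsat per backbone amide is a direct probe
of fast-timescale backbone flexibility: ratios well below ~0.8 indicate
sub-nanosecond mobility.  This module computes the ratio profile from a
peak-intensity table and flags contiguous low-ratio regions (default:
strictly below 0.75).  Unassigned or overlapped residues are simply absent
rows — profiles carry explicit numbering gaps, and gaps break regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyProfileError
from .profiles import FlexibleRegion, ResidueProfile, call_regions

__all__ = [
    "NoeResult",
    "read_peak_table",
    "noe_ratio",
    "flag_low_noe",
    "noe_to_tsv",
]


@dataclass
class NoeResult:
    """NOE ratio profile plus the residues excluded for zero I_unsat."""

    profile: ResidueProfile
    excluded_residues: list[int]


def read_peak_table(path) -> pd.DataFrame:
    """Read a TSV peak table with columns resnum[, resname], I_sat, I_unsat."""
    df = pd.read_csv(path, sep="\t")
    required = {"resnum", "I_sat", "I_unsat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def noe_ratio(table: pd.DataFrame) -> NoeResult:
    """Per-residue I_sat / I_unsat ratios.

    Rows with I_unsat == 0 cannot be evaluated; they are excluded from the
    profile and reported in ``excluded_residues``.
    """
    if len(table) == 0:
        raise EmptyProfileError("peak table is empty")
    if table["resnum"].duplicated().any():
        dup = table.loc[table["resnum"].duplicated(), "resnum"].tolist()
        raise ValueError(f"duplicate residue numbers in peak table: {dup}")
    table = table.sort_values("resnum")
    bad = table["I_unsat"] == 0
    excluded = table.loc[bad, "resnum"].astype(int).tolist()
    good = table.loc[~bad]
    if len(good) == 0:
        raise EmptyProfileError("all rows excluded (I_unsat == 0 everywhere)")
    ratios = good["I_sat"].to_numpy(float) / good["I_unsat"].to_numpy(float)
    profile = ResidueProfile(
        residues=good["resnum"].to_numpy(int),
        values=ratios,
        kind="noe_ratio",
        units="",
    )
    return NoeResult(profile=profile, excluded_residues=excluded)


def flag_low_noe(
    profile: ResidueProfile, threshold: float = 0.75, min_length: int = 2
) -> list[FlexibleRegion]:
    """Regions with NOE ratio strictly below ``threshold`` (default 0.75)."""
    return call_regions(
        profile, threshold=threshold, min_length=min_length, direction="below"
    )


def noe_to_tsv(result: NoeResult, path, threshold: float = 0.75, min_length: int = 2) -> None:
    regions = flag_low_noe(result.profile, threshold=threshold, min_length=min_length)
    flagged = set()
    for reg in regions:
        flagged.update(reg.residues())
    with open(path, "w") as fh:
        fh.write("resnum\tratio\tflagged\n")
        for r, v in zip(result.profile.residues, result.profile.values):
            fh.write(f"{r}\t{v:.6f}\t{int(r in flagged)}\n")
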