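"""Cross-structure B-factor profile aggregation.

For an aligned ensemble the members are ranked by their mean C-alpha
B-factor over the common residues; the tracks of the highest- and
lowest-B structures are reported alongside the per-residue mean over all
members.  Regions strictly above the grand mean of the average track are
flagged as high-B.  The isotropic relation B = 8 pi^2 <u^2> connects
B-factors to the mean-square displacement per direction, which is what the
synthetic generator uses to write consistent B columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingBFactorError
from .profiles import FlexibleRegion, ResidueProfile, call_regions
from .structure import AlignedEnsemble

__all__ = ["BFactorSummary", "bfactor_summary", "flag_above_average", "summary_to_tsv"]


@dataclass
class BFactorSummary:
    """Highest/average/lowest B-factor tracks over an ensemble.

    The max/min structures are selected by overall (mean) B, not per
    residue, so the mean track is not necessarily bracketed by the other
    two at every residue.
    """

    max_structure: ResidueProfile
    mean: ResidueProfile
    min_structure: ResidueProfile
    max_label: str
    min_label: str
    grand_mean: float  # mean of the mean track, A^2


def bfactor_summary(ensemble: AlignedEnsemble, normalize: str = "none") -> BFactorSummary:
    """Aggregate C-alpha B-factor tracks across ensemble members.

    Parameters
    ----------
    normalize : {"none", "zscore"}
        ``"zscore"`` standardises each member's track (per-member mean 0,
        sd 1) before aggregation, removing overall-B offsets between
        crystals; the default aggregates raw B values.
    """
    b = ensemble.b_factors
    if np.any(~np.isfinite(b)):
        i, j = np.argwhere(~np.isfinite(b))[0]
        raise MissingBFactorError(
            f"member {ensemble.labels[i]} lacks a B-factor at residue "
            f"{ensemble.residue_numbers[j]}"
        )
    if normalize == "zscore":
        sd = b.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        b = (b - b.mean(axis=1, keepdims=True)) / sd
    elif normalize != "none":
        raise ValueError(f"unknown normalize mode {normalize!r}")

    member_means = b.mean(axis=1)
    i_max = int(np.argmax(member_means))
    i_min = int(np.argmin(member_means))
    residues = ensemble.residue_numbers
    units = "A^2" if normalize == "none" else ""

    def track(values: np.ndarray, kind: str) -> ResidueProfile:
        return ResidueProfile(residues=residues, values=values, kind=kind, units=units)

    mean_track = b.mean(axis=0)
    return BFactorSummary(
        max_structure=track(b[i_max].copy(), "bfactor_max_structure"),
        mean=track(mean_track, "bfactor_mean"),
        min_structure=track(b[i_min].copy(), "bfactor_min_structure"),
        max_label=ensemble.labels[i_max],
        min_label=ensemble.labels[i_min],
        grand_mean=float(mean_track.mean()),
    )


def flag_above_average(summary: BFactorSummary, min_length: int = 2) -> list[FlexibleRegion]:
    """Regions of the mean track strictly above its grand mean."""
    return call_regions(
        summary.mean, threshold=summary.grand_mean, min_length=min_length
    )


def summary_to_tsv(summary: BFactorSummary, path, min_length: int = 2) -> None:
    regions = flag_above_average(summary, min_length=min_length)
    flagged = set()
    for reg in regions:
        flagged.update(reg.residues())
    with open(path, "w") as fh:
        fh.write("resnum\tb_max_structure\tb_mean\tb_min_structure\tflagged\n")
        for r, hi, me, lo in zip(
            summary.mean.residues,
            summary.max_structure.values,
            summary.mean.values,
            summary.min_structure.values,
        ):
            fh.write(f"{r}\t{hi:.6f}\t{me:.6f}\t{lo:.6f}\t{int(r in flagged)}\n")
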