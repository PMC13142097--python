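"""Per-residue scalar tracks and threshold-based region calling.

A :class:`ResidueProfile` is the common currency of the package: average
pairwise RMSD, RMSF, B-factor and NOE-ratio tracks are all profiles over
author residue numbers.  Flexible (or rigid) regions are called as maximal
contiguous runs of values strictly beyond a threshold; gaps in the residue
numbering break runs, because a profile says nothing about unmodelled
residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ResidueProfile", "FlexibleRegion", "call_regions"]


@dataclass
class ResidueProfile:
    """A scalar value per residue.

    Parameters
    ----------
    residues : array of int
        Author residue numbers, strictly increasing.
    values : array of float
        One value per residue, same length as ``residues``.
    kind : str
        What the values are, e.g. ``"avg_pairwise_rmsd"``, ``"rmsf"``,
        ``"bfactor"``, ``"noe_ratio"``.
    units : str
        Physical units of the values ("A", "A^2" or "" for ratios).
    """

    residues: np.ndarray
    values: np.ndarray
    kind: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.residues.shape != self.values.shape:
            raise ValueError("residues and values must have the same length")
        if self.residues.size and np.any(np.diff(self.residues) <= 0):
            raise ValueError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return self.residues.size

    def value_at(self, residue: int) -> float:
        idx = np.flatnonzero(self.residues == residue)
        if idx.size == 0:
            raise KeyError(f"residue {residue} not in profile")
        return float(self.values[idx[0]])


@dataclass
class FlexibleRegion:
    """A contiguous run of residues beyond a threshold.

    ``peak`` is the most extreme value in the run: the maximum for
    above-threshold calls, the minimum for below-threshold calls.
    """

    first: int
    last: int
    peak: float
    mean: float

    @property
    def length(self) -> int:
        return self.last - self.first + 1

    def residues(self) -> range:
        return range(self.first, self.last + 1)


def call_regions(
    profile: ResidueProfile,
    threshold: float,
    min_length: int = 2,
    direction: str = "above",
) -> list[FlexibleRegion]:
    """Call maximal contiguous runs strictly beyond ``threshold``.

    Parameters
    ----------
    threshold : float
        Boundary value; the comparison is strict, so residues exactly at the
        threshold are never part of a region.
    min_length : int
        Minimum number of residues in a reported run (default 2; shorter
        runs are single-residue spikes and are not reported).
    direction : {"above", "below"}
        ``"above"`` flags values > threshold (RMSD, RMSF, B-factor);
        ``"below"`` flags values < threshold (NOE ratios).

    Gaps in residue numbering terminate a run even if the values on both
    sides pass the threshold.
    """
    if direction not in ("above", "below"):
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if direction == "above":
        hit = profile.values > threshold
    else:
        hit = profile.values < threshold

    regions: list[FlexibleRegion] = []
    run: list[int] = []  # indices of current run

    def flush() -> None:
        if len(run) >= min_length:
            vals = profile.values[run]
            peak = float(vals.max() if direction == "above" else vals.min())
            regions.append(
                FlexibleRegion(
                    first=int(profile.residues[run[0]]),
                    last=int(profile.residues[run[-1]]),
                    peak=peak,
                    mean=float(vals.mean()),
                )
            )
        run.clear()

    for i in range(len(profile)):
        contiguous = bool(run) and profile.residues[i] == profile.residues[run[-1]] + 1
        if hit[i]:
            if run and not contiguous:
                flush()
            run.append(i)
        else:
            flush()
    flush()
    return regions
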