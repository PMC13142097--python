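"""Per-residue C-alpha RMSF from trajectory frames.

The protocol mirrors a standard replicate-averaged MD analysis: frames are
selected from an equilibrated time window at a fixed stride (e.g. every
100 ps from the final 160 ns of a 200 ns run), each replicate's frames are
iteratively superposed onto the running mean structure over a fit
selection, and the RMSF of residue i is the root-mean-square distance of
its C-alpha from its trajectory-mean position.  Replicates are aggregated
residue-wise into mean and population standard deviation.  High-RMSF
regions are called at a strict threshold (default 0.12 Angstrom).

All coordinates are Angstrom; nanometre input must be converted on the way
in (see :func:`nm_to_angstrom`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, EmptySelectionError, MismatchedResiduesError
from .profiles import FlexibleRegion, ResidueProfile, call_regions
from .superpose import kabsch_superpose

__all__ = [
    "Trajectory",
    "RmsfProfile",
    "select_frames",
    "rmsf",
    "aggregate_replicates",
    "flag_high_rmsf",
    "nm_to_angstrom",
    "read_trajectory_tsv",
    "write_trajectory_tsv",
    "rmsf_to_tsv",
]


def nm_to_angstrom(coords: np.ndarray) -> np.ndarray:
    """Convert nanometre coordinates to Angstrom (x 10)."""
    return np.asarray(coords, dtype=float) * 10.0


@dataclass
class Trajectory:
    """Frames of C-alpha coordinates with strictly increasing times (ps)."""

    replicate_id: str
    times: np.ndarray  # (T,) ps
    frames: np.ndarray  # (T, N, 3) Angstrom
    residue_numbers: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        t, n = self.times.size, self.residue_numbers.size
        if self.frames.shape != (t, n, 3):
            raise ValueError(f"frames shape {self.frames.shape} != ({t}, {n}, 3)")
        if t > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.size


def select_frames(traj: Trajectory, t_min: float, t_max: float, stride: float) -> Trajectory:
    """Window frames to ``[t_min, t_max]`` then subsample at ``stride`` ps.

    Subsampling matches each target time ``t_min + k * stride`` to the
    nearest available frame time inside the window (duplicates dropped), so
    a stride equal to the native spacing is a pure window cut.
    """
    if t_min >= t_max:
        raise ValueError("t_min must be < t_max")
    if stride <= 0:
        raise ValueError("stride must be positive")
    in_window = np.flatnonzero((traj.times >= t_min) & (traj.times <= t_max))
    if in_window.size == 0:
        raise EmptySelectionError(
            f"no frames in [{t_min}, {t_max}] ps "
            f"(trajectory spans [{traj.times[0]}, {traj.times[-1]}])"
        )
    window_times = traj.times[in_window]
    targets = np.arange(t_min, t_max + 0.5 * stride, stride)
    picked = np.unique(
        in_window[np.abs(window_times[None, :] - targets[:, None]).argmin(axis=1)]
    )
    return Trajectory(
        replicate_id=traj.replicate_id,
        times=traj.times[picked],
        frames=traj.frames[picked],
        residue_numbers=traj.residue_numbers,
    )


def rmsf(
    traj: Trajectory,
    fit_selection: np.ndarray | list[int] | None = None,
    measure_selection: np.ndarray | list[int] | None = None,
    tol: float = 1e-6,
    max_iter: int = 10,
) -> ResidueProfile:
    """Per-residue RMSF after iterative superposition onto the mean.

    Starting from the first frame as reference, every frame is superposed
    onto the reference over ``fit_selection``, the mean structure is
    recomputed, and the cycle repeats until the mean moves less than
    ``tol`` Angstrom (max ``max_iter`` iterations).  RMSF is reported over
    ``measure_selection`` (default: all residues).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    fit = (
        np.arange(traj.residue_numbers.size)
        if fit_selection is None
        else np.asarray(fit_selection, dtype=int)
    )
    measure = (
        np.arange(traj.residue_numbers.size)
        if measure_selection is None
        else np.asarray(measure_selection, dtype=int)
    )
    frames = traj.frames.copy()
    reference = frames[0]
    for _ in range(max_iter):
        for t in range(frames.shape[0]):
            result = kabsch_superpose(frames[t], reference, fit_selection=fit)
            frames[t] = result.apply(frames[t])
        mean = frames.mean(axis=0)
        shift = float(np.abs(mean - reference).max())
        reference = mean
        if shift < tol:
            break
    fluct = np.sqrt(np.mean(np.sum((frames - reference) ** 2, axis=2), axis=0))
    return ResidueProfile(
        residues=traj.residue_numbers[measure],
        values=fluct[measure],
        kind="rmsf",
        units="A",
    )


@dataclass
class RmsfProfile:
    """Replicate RMSF profiles with residue-wise mean and population SD."""

    per_replicate: list[ResidueProfile]
    mean: ResidueProfile
    sd: ResidueProfile


def aggregate_replicates(profiles: list[ResidueProfile]) -> RmsfProfile:
    """Residue-wise mean and population standard deviation over replicates."""
    if not profiles:
        raise ValueError("need at least one profile")
    residues = profiles[0].residues
    for p in profiles[1:]:
        if not np.array_equal(p.residues, residues):
            raise MismatchedResiduesError("replicate profiles differ in residue sets")
    stack = np.vstack([p.values for p in profiles])
    return RmsfProfile(
        per_replicate=list(profiles),
        mean=ResidueProfile(residues, stack.mean(axis=0), kind="rmsf_mean", units="A"),
        sd=ResidueProfile(residues, stack.std(axis=0), kind="rmsf_sd", units="A"),
    )


def flag_high_rmsf(
    profile: ResidueProfile, threshold: float = 0.12, min_length: int = 2
) -> list[FlexibleRegion]:
    """Regions with RMSF strictly above ``threshold`` (default 0.12 A)."""
    return call_regions(profile, threshold=threshold, min_length=min_length)


# ---------------------------------------------------------------------------
# plain-text trajectory format: one row per (frame, residue)


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("time\tresnum\tx\ty\tz\n")
        for t, frame in zip(traj.times, traj.frames):
            for r, xyz in zip(traj.residue_numbers, frame):
                fh.write(f"{t:.3f}\t{r}\t{xyz[0]:.6f}\t{xyz[1]:.6f}\t{xyz[2]:.6f}\n")


def read_trajectory_tsv(path, replicate_id: str | None = None) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    required = {"time", "resnum", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    times = np.sort(df["time"].unique())
    residues = df.loc[df["time"] == times[0], "resnum"].to_numpy()
    frames = np.empty((times.size, residues.size, 3))
    for i, t in enumerate(times):
        block = df[df["time"] == t].set_index("resnum").loc[residues]
        frames[i] = block[["x", "y", "z"]].to_numpy()
    return Trajectory(
        replicate_id=replicate_id or str(path),
        times=times,
        frames=frames,
        residue_numbers=residues,
    )


def rmsf_to_tsv(aggregate: RmsfProfile, path, threshold: float = 0.12, min_length: int = 2) -> None:
    regions = flag_high_rmsf(aggregate.mean, threshold=threshold, min_length=min_length)
    flagged = set()
    for reg in regions:
        flagged.update(reg.residues())
    with open(path, "w") as fh:
        fh.write("resnum\tmean_rmsf\tsd_rmsf\tflagged\n")
        for r, m, s in zip(aggregate.mean.residues, aggregate.mean.values, aggregate.sd.values):
            fh.write(f"{r}\t{m:.6f}\t{s:.6f}\t{int(r in flagged)}\n")
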