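"""Optimal rigid-body superposition (Kabsch) and C-alpha RMSD.

The Kabsch algorithm finds the proper rotation and translation minimising
the least-squares distance between paired point sets via SVD of the
cross-covariance matrix, with an explicit reflection correction so the
returned rotation always has determinant +1.  The fit may be restricted to
a subset of sites (e.g. a rigid core) while deviations are reported for all
sites — that is what per-residue deviation profiling needs.

Tolerances are fixed: rotations are orthonormal to 1e-10 and pairwise RMSD
is symmetric to 1e-8 Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, InsufficientOverlapError
from .structure import DomainInstance

__all__ = ["SuperpositionResult", "kabsch_superpose", "pair_rmsd"]

#: rank-deficiency tolerance for the degenerate-fit check
_DEGENERACY_RTOL = 1e-8


@dataclass
class SuperpositionResult:
    """Result of a rigid-body superposition.

    ``rotation`` and ``translation`` map mobile onto target:
    ``x_fit = rotation @ x + translation``.  ``rmsd`` and
    ``per_site_deviation`` cover *all* sites after applying the fit,
    regardless of the fit selection.
    """

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float
    per_site_deviation: np.ndarray  # (N,)
    fit_selection: np.ndarray  # indices used for fitting

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def as_matrix(self) -> np.ndarray:
        """The transform as a 3x4 matrix [R | t]."""
        return np.hstack([self.rotation, self.translation[:, None]])


def _check_fit_set(points: np.ndarray) -> None:
    """Require >= 3 distinct, non-collinear fit points."""
    if points.shape[0] < 3:
        raise DegenerateFitError(
            f"fit selection has {points.shape[0]} points; need at least 3"
        )
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    if s[1] <= _DEGENERACY_RTOL * scale:
        raise DegenerateFitError("fit points are collinear or coincident")


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    fit_selection: np.ndarray | list[int] | None = None,
) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``target``.

    Parameters
    ----------
    mobile, target : (N, 3) arrays
        Paired coordinates in Angstrom.
    fit_selection : index array, optional
        Sites used to compute the transform (default: all).  Deviations are
        always reported over all N sites.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (N, 3) arrays")
    if fit_selection is None:
        sel = np.arange(mobile.shape[0])
    else:
        sel = np.asarray(fit_selection, dtype=int)
    m_fit = mobile[sel]
    t_fit = target[sel]
    _check_fit_set(m_fit)
    _check_fit_set(t_fit)

    mu_m = m_fit.mean(axis=0)
    mu_t = t_fit.mean(axis=0)
    h = (m_fit - mu_m).T @ (t_fit - mu_t)
    u, _, vt = np.linalg.svd(h)
    # reflection correction: flip the smallest singular direction if needed
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = mu_t - rotation @ mu_m

    moved = mobile @ rotation.T + translation
    dev = np.linalg.norm(moved - target, axis=1)
    rmsd = float(np.sqrt(np.mean(dev**2)))
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        rmsd=rmsd,
        per_site_deviation=dev,
        fit_selection=sel,
    )


def pair_rmsd(a: DomainInstance, b: DomainInstance) -> float:
    """C-alpha RMSD between two domain instances on their common residues.

    Both instances are restricted to the residues (by author number and
    insertion code) present in both, superposed by Kabsch and the RMSD over
    that common set returned.  Symmetric to 1e-8 Angstrom.
    """
    keys_a = a.residue_keys()
    keys_b = b.residue_keys()
    common = sorted(set(keys_a) & set(keys_b))
    if len(common) < 3:
        raise InsufficientOverlapError(
            f"{a.label} and {b.label} share only {len(common)} residues"
        )
    ia = {k: i for i, k in enumerate(keys_a)}
    ib = {k: i for i, k in enumerate(keys_b)}
    ca = a.ca_coords[[ia[k] for k in common]]
    cb = b.ca_coords[[ib[k] for k in common]]
    return kabsch_superpose(ca, cb).rmsd
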