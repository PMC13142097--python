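"""Brute-force reference implementations of the minimum RMSD.

These deliberately avoid the SVD route used by :mod:`pdzflex.superpose` so
they can serve as independent cross-checks:

* :func:`grid_search_rmsd` scans rotations on a z-y-z Euler grid, refining
  around the best cell down to a requested angular resolution; for each
  rotation the translation is optimal in closed form (centroid matching).
* :func:`quaternion_rmsd` is Horn's closed-form quaternion solution (largest
  eigenvalue of the 4x4 key matrix), an algorithm distinct from Kabsch.

For a rotation R applied to centered mobile coordinates A against centered
target B, the summed squared distance is ``|A|^2 + |B|^2 - 2 tr(R M)`` with
``M = sum_s a_s b_s^T``, so the scan only touches 3x3 matrices whatever N is.
"""

from __future__ import annotations

import numpy as np

__all__ = ["grid_search_rmsd", "quaternion_rmsd"]


def _euler_zyz(alpha: np.ndarray, beta: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Stack of z-y-z Euler rotation matrices, shape (K, 3, 3)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    r = np.empty((alpha.size, 3, 3))
    r[:, 0, 0] = ca * cb * cg - sa * sg
    r[:, 0, 1] = -ca * cb * sg - sa * cg
    r[:, 0, 2] = ca * sb
    r[:, 1, 0] = sa * cb * cg + ca * sg
    r[:, 1, 1] = -sa * cb * sg + ca * cg
    r[:, 1, 2] = sa * sb
    r[:, 2, 0] = -sb * cg
    r[:, 2, 1] = sb * sg
    r[:, 2, 2] = cb
    return r


def _best_on_grid(
    m: np.ndarray,
    centers: tuple[float, float, float],
    half_width: float,
    step: float,
) -> tuple[float, tuple[float, float, float]]:
    """Maximise tr(R M) over a local Euler grid; return (score, best angles)."""
    axes = [
        np.arange(c - half_width, c + half_width + 0.5 * step, step)
        for c in centers
    ]
    aa, bb, gg = np.meshgrid(*axes, indexing="ij")
    rots = _euler_zyz(aa.ravel(), bb.ravel(), gg.ravel())
    scores = np.einsum("kij,ji->k", rots, m)
    k = int(np.argmax(scores))
    return float(scores[k]), (aa.ravel()[k], bb.ravel()[k], gg.ravel()[k])


def grid_search_rmsd(
    mobile: np.ndarray,
    target: np.ndarray,
    coarse_deg: float = 6.0,
    final_deg: float = 1.0,
) -> float:
    """Minimum RMSD by exhaustive rotation-grid search.

    A global z-y-z Euler scan at ``coarse_deg`` resolution is refined around
    the best cell, halving the step until it reaches ``final_deg`` (or
    finer).  Translation is handled exactly by centering both point sets.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    n = a.shape[0]
    c0 = float(np.sum(a**2) + np.sum(b**2))
    m = sum(np.outer(a[i], b[i]) for i in range(n))

    step = np.deg2rad(coarse_deg)
    # global scan: alpha, gamma in [0, 2pi), beta in [0, pi]
    alphas = np.arange(0.0, 2 * np.pi, step)
    betas = np.arange(0.0, np.pi + 0.5 * step, step)
    gammas = np.arange(0.0, 2 * np.pi, step)
    aa, bb, gg = np.meshgrid(alphas, betas, gammas, indexing="ij")
    rots = _euler_zyz(aa.ravel(), bb.ravel(), gg.ravel())
    scores = np.einsum("kij,ji->k", rots, m)
    k = int(np.argmax(scores))
    best_score = float(scores[k])
    best = (aa.ravel()[k], bb.ravel()[k], gg.ravel()[k])

    final = np.deg2rad(final_deg)
    half = step
    while step > final:
        step = max(step / 2.0, final)
        score, best = _best_on_grid(m, best, half, step)
        best_score = max(best_score, score)
        half = 2 * step
    cost = max(c0 - 2.0 * best_score, 0.0)
    return float(np.sqrt(cost / n))


def quaternion_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Minimum RMSD via Horn's closed-form quaternion method.

    The optimal rotation corresponds to the eigenvector with the largest
    eigenvalue ``lam`` of the symmetric 4x4 key matrix built from the
    cross-covariance; the minimum cost is ``|A|^2 + |B|^2 - 2 lam``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    n = a.shape[0]
    sxx, sxy, sxz = (a[:, 0] * b[:, 0]).sum(), (a[:, 0] * b[:, 1]).sum(), (a[:, 0] * b[:, 2]).sum()
    syx, syy, syz = (a[:, 1] * b[:, 0]).sum(), (a[:, 1] * b[:, 1]).sum(), (a[:, 1] * b[:, 2]).sum()
    szx, szy, szz = (a[:, 2] * b[:, 0]).sum(), (a[:, 2] * b[:, 1]).sum(), (a[:, 2] * b[:, 2]).sum()
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = float(np.linalg.eigvalsh(key)[-1])
    cost = max(float(np.sum(a**2) + np.sum(b**2)) - 2.0 * lam, 0.0)
    return float(np.sqrt(cost / n))
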