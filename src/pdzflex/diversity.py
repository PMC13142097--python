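"""Ensemble conformational-diversity analysis.

The core multi-structure comparison: the all-pairs C-alpha RMSD matrix over
an aligned ensemble, agglomerative clustering of that matrix with flat cuts
and inter-cluster distances, the per-residue average pairwise RMSD profile,
and threshold-based flexible-region calling (default threshold 1.0 Angstrom
for crystal-ensemble profiles).

Clustering is implemented directly on the precomputed distance matrix so
tie-breaking is fully deterministic: among equally close cluster pairs the
pair whose (lexicographically smallest member, second smallest) label pair
sorts first is merged.  Average linkage (UPGMA) is the default and is
monotone, so merge heights never decrease.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidDistanceMatrixError, PdzflexError
from .profiles import FlexibleRegion, ResidueProfile, call_regions
from .structure import AlignedEnsemble
from .superpose import kabsch_superpose

__all__ = [
    "PairwiseMatrix",
    "ClusterTree",
    "pairwise_rmsd_matrix",
    "hierarchical_cluster",
    "flat_clusters",
    "inter_cluster_distance",
    "per_residue_avg_rmsd",
    "call_regions",
    "matrix_to_tsv",
    "tree_to_newick",
]

_SYMMETRY_TOL = 1e-8


@dataclass
class PairwiseMatrix:
    """Symmetric zero-diagonal RMSD matrix over labelled ensemble members."""

    labels: list[str]
    values: np.ndarray  # (n, n) Angstrom

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidDistanceMatrixError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if n < 2:
            raise InvalidDistanceMatrixError("need at least 2 members")
        if np.any(self.values < 0):
            raise InvalidDistanceMatrixError("negative distances")
        if np.max(np.abs(self.values - self.values.T)) > _SYMMETRY_TOL:
            raise InvalidDistanceMatrixError("matrix is not symmetric")
        if np.max(np.abs(np.diag(self.values))) > _SYMMETRY_TOL:
            raise InvalidDistanceMatrixError("diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, label_a: str, label_b: str) -> float:
        i, j = self.labels.index(label_a), self.labels.index(label_b)
        return float(self.values[i, j])


@dataclass
class ClusterTree:
    """Agglomerative merge history.

    ``merges`` holds one step per row: the two clusters merged (as sorted
    label tuples) and the merge height in Angstrom.  For n members there are
    exactly n - 1 merges.
    """

    labels: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    linkage: str = "average"

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


_LINKAGES = ("average", "single", "complete")


def pairwise_rmsd_matrix(ensemble: AlignedEnsemble) -> PairwiseMatrix:
    """All-pairs C-alpha RMSD on the ensemble's common residues."""
    n = ensemble.n_members
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            r = kabsch_superpose(ensemble.coords[i], ensemble.coords[j]).rmsd
        except PdzflexError as exc:
            raise type(exc)(
                f"superposition failed for pair "
                f"({ensemble.labels[i]}, {ensemble.labels[j]}): {exc}"
            ) from exc
        values[i, j] = values[j, i] = r
    return PairwiseMatrix(labels=list(ensemble.labels), values=values)


def hierarchical_cluster(matrix: PairwiseMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of a precomputed distance matrix.

    Ties in the minimum inter-cluster distance are broken by the smallest
    lexicographic (representative label) pair, where a cluster's
    representative is its lexicographically smallest member.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    # clusters as sorted label tuples
    clusters: list[tuple[str, ...]] = [(lab,) for lab in matrix.labels]
    idx = {lab: i for i, lab in enumerate(matrix.labels)}

    def cross_pairs(a: tuple[str, ...], b: tuple[str, ...]) -> np.ndarray:
        rows = [idx[x] for x in a]
        cols = [idx[x] for x in b]
        return matrix.values[np.ix_(rows, cols)]

    def linkage_distance(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        block = cross_pairs(a, b)
        if linkage == "average":
            return float(block.mean())
        if linkage == "single":
            return float(block.min())
        return float(block.max())

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        best: tuple[float, str, str] | None = None
        best_pair: tuple[int, int] | None = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            a, b = clusters[i], clusters[j]
            d = linkage_distance(a, b)
            ra, rb = sorted((a[0], b[0]))
            key = (d, ra, rb)
            if best is None or key < best:
                best = key
                best_pair = (i, j)
        assert best is not None and best_pair is not None
        i, j = best_pair
        a, b = sorted((clusters[i], clusters[j]), key=lambda c: c[0])
        merges.append((a, b, best[0]))
        merged = tuple(sorted(a + b))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return ClusterTree(labels=list(matrix.labels), merges=merges, linkage=linkage)


def flat_clusters(tree: ClusterTree, k: int) -> dict[str, int]:
    """Cut the tree into exactly ``k`` clusters.

    Replays the first n - k merges.  Cluster ids are assigned 0..k-1 in
    order of each cluster's lexicographically smallest member, so the map is
    stable under input permutation up to that canonical relabelling.
    """
    n = len(tree.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent: dict[str, str] = {lab: lab for lab in tree.labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _h in tree.merges[: n - k]:
        ra, rb = find(a[0]), find(b[0])
        if ra != rb:
            lo, hi = sorted((ra, rb))
            parent[hi] = lo
    groups: dict[str, list[str]] = {}
    for lab in tree.labels:
        groups.setdefault(find(lab), []).append(lab)
    assignment: dict[str, int] = {}
    for cid, root in enumerate(sorted(groups, key=lambda r: min(groups[r]))):
        for lab in groups[root]:
            assignment[lab] = cid
    return assignment


def inter_cluster_distance(
    matrix: PairwiseMatrix,
    clusters: dict[str, int],
    aggregate: str = "mean",
) -> dict[tuple[int, int], float]:
    """Distance between every pair of clusters.

    Default aggregate is the mean over all cross-pair RMSDs (consistent with
    average linkage); ``"single"`` and ``"complete"`` give min and max.
    """
    ids = sorted(set(clusters.values()))
    if len(ids) < 2:
        raise PdzflexError("inter-cluster distances need at least two clusters")
    if aggregate not in ("mean", "single", "complete"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    idx = {lab: i for i, lab in enumerate(matrix.labels)}
    members = {cid: [idx[lab] for lab, c in clusters.items() if c == cid] for cid in ids}
    out: dict[tuple[int, int], float] = {}
    for a, b in itertools.combinations(ids, 2):
        block = matrix.values[np.ix_(members[a], members[b])]
        if aggregate == "mean":
            out[(a, b)] = float(block.mean())
        elif aggregate == "single":
            out[(a, b)] = float(block.min())
        else:
            out[(a, b)] = float(block.max())
    return out


def per_residue_avg_rmsd(
    ensemble: AlignedEnsemble,
    groups: dict[str, object] | None = None,
    fit_selection: np.ndarray | list[int] | None = None,
) -> ResidueProfile:
    """Average per-residue deviation over ensemble pairs.

    For every unordered member pair the two coordinate sets are superposed
    (on ``fit_selection``, default all common residues) and the per-site
    deviation recorded; the profile value at a residue is the mean deviation
    there over all pairs considered.

    Parameters
    ----------
    groups : mapping label -> group key, optional
        When given, only pairs whose members share a group are averaged
        (e.g. chain-A-only pairs); default averages all pairs.
    """
    pairs = [
        (i, j)
        for i, j in itertools.combinations(range(ensemble.n_members), 2)
        if groups is None
        or groups[ensemble.labels[i]] == groups[ensemble.labels[j]]
    ]
    if not pairs:
        raise PdzflexError("no member pairs selected for per-residue averaging")
    total = np.zeros(ensemble.n_residues)
    for i, j in pairs:
        result = kabsch_superpose(
            ensemble.coords[i], ensemble.coords[j], fit_selection=fit_selection
        )
        total += result.per_site_deviation
    return ResidueProfile(
        residues=ensemble.residue_numbers,
        values=total / len(pairs),
        kind="avg_pairwise_rmsd",
        units="A",
    )


# ---------------------------------------------------------------------------
# writers


def matrix_to_tsv(matrix: PairwiseMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(matrix.labels) + "\n")
        for lab, row in zip(matrix.labels, matrix.values):
            fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def tree_to_newick(tree: ClusterTree) -> str:
    """Newick with ultrametric branch lengths (leaf depth = height / 2)."""
    node: dict[tuple[str, ...], tuple[str, float]] = {
        (lab,): (_quote(lab), 0.0) for lab in tree.labels
    }
    text = ""
    for a, b, h in tree.merges:
        (ta, ha), (tb, hb) = node[a], node[b]
        half = h / 2.0
        text = f"({ta}:{half - ha:.6f},{tb}:{half - hb:.6f})"
        node[tuple(sorted(a + b))] = (text, half)
    return text + ";"


def _quote(label: str) -> str:
    return label.replace(" ", "_").replace(",", "_").replace(":", "_").replace(
        "(", "_"
    ).replace(")", "_").replace(";", "_")
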