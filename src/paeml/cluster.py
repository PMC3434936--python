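"""Pairwise area distances from presence/absence data and UPGMA
clustering (overall floristic similarity, independent of common ancestry).

The UPGMA agglomeration is implemented directly (rather than through a
generic linkage routine) so that ties in the minimum distance are broken
by a documented, stable rule: the lexicographically smallest pair of
sorted cluster name sets wins. Output is an ultrametric dendrogram whose
branch lengths are in the same units as the distances (merge height / 2
to each tip).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import TaxonAreaMatrix
from .trees import AreaTree

METRICS = ("hamming", "jaccard")


@dataclass
class DistanceMatrix:
    area_names: list[str]
    values: np.ndarray        # symmetric, zero diagonal, entries in [0, 1]
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.area_names),) * 2:
            raise ValueError("distance matrix shape does not match names")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.area_names.index(a), self.area_names.index(b)
        return float(self.values[i, j])


def distance_matrix(
    matrix: TaxonAreaMatrix, metric: str = "hamming"
) -> DistanceMatrix:
    """Pairwise distances between area rows.

    ``hamming``: proportion of species whose state differs.
    ``jaccard``: 1 - |shared presences| / |united presences| (0 when both
    areas hold no species at all).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if matrix.n_areas < 2:
        raise ValueError("need at least 2 areas")
    X = matrix.cells.astype(float)
    n = matrix.n_areas
    if metric == "hamming":
        if matrix.n_species == 0:
            d = np.zeros((n, n))
        else:
            diff = (X[:, None, :] != X[None, :, :]).sum(axis=2)
            d = diff / matrix.n_species
    else:
        inter = X @ X.T
        sums = X.sum(axis=1)
        union = sums[:, None] + sums[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
        d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(matrix.area_names), d, metric)


def upgma(d: DistanceMatrix) -> AreaTree:
    """Average-linkage agglomeration into an ultrametric dendrogram."""
    names = list(d.area_names)
    # cluster state: id -> (sorted member names, size, height, newick core)
    clusters: dict[int, tuple[tuple[str, ...], int, float, str]] = {
        i: ((nm,), 1, 0.0, nm) for i, nm in enumerate(names)
    }
    dist: dict[tuple[int, int], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            dist[(i, j)] = float(d.values[i, j])
    next_id = len(names)
    while len(clusters) > 1:
        best_key, best_val, best_names = None, np.inf, None
        for (i, j), v in dist.items():
            pair_names = tuple(sorted((clusters[i][0], clusters[j][0])))
            if v < best_val - 1e-15 or (
                abs(v - best_val) <= 1e-15
                and (best_names is None or pair_names < best_names)
            ):
                best_key, best_val, best_names = (i, j), v, pair_names
        i, j = best_key
        ni, nj = clusters[i][1], clusters[j][1]
        h = best_val / 2.0
        left = f"{clusters[i][3]}:{h - clusters[i][2]:.10g}"
        right = f"{clusters[j][3]}:{h - clusters[j][2]:.10g}"
        merged = (
            tuple(sorted(clusters[i][0] + clusters[j][0])),
            ni + nj,
            h,
            f"({left},{right})",
        )
        new_dist: dict[tuple[int, int], float] = {}
        for (a, b), v in dist.items():
            if i in (a, b) or j in (a, b):
                continue
            new_dist[(a, b)] = v
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            new_dist[tuple(sorted((next_id, k)))] = (ni * dik + nj * djk) / (ni + nj)
        del clusters[i], clusters[j]
        clusters[next_id] = merged
        dist = new_dist
        next_id += 1
    (_, _, _, core) = next(iter(clusters.values()))
    tree = AreaTree.from_newick(core + ";")
    tree.dendropy_tree.is_rooted = True
    return tree


def cophenetic_distance(tree: AreaTree, a: str, b: str) -> float:
    """Path length between two tips on the dendrogram."""
    d = tree.dendropy_tree
    pdm = d.phylogenetic_distance_matrix()
    ta = tb = None
    for t in d.taxon_namespace:
        if t.label == a:
            ta = t
        if t.label == b:
            tb = t
    if ta is None or tb is None:
        raise ValueError("tip not found")
    return float(pdm.distance(ta, tb))
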