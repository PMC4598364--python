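"""Discrete colour categories by average-linkage hierarchical clustering.

Spectra (as integral-normalised 401-point curves) or colour loci ((x, y) in
the bee hexagon, (x, y, z) in the hummingbird space) are grouped by
agglomerative clustering on Euclidean distances using unweighted average
linkage (UPGMA): at each step the two groups with the smallest mean
point-to-point distance are merged. The number of colour categories is chosen
at an "elbow" — a step where the merge height jumps steeply — with ranked
candidates exposed rather than a single hard choice, since the cutoff is
ultimately a judgement call; a fixed k can always be imposed instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "CategoryAssignment",
    "euclidean_distances",
    "upgma_cluster",
    "elbow_candidates",
    "cut_categories",
    "categorize",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if np.any(np.isnan(v)):
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class Dendrogram:
    """Full merge trace of an agglomerative clustering.

    ``linkage`` is a scipy-format (n−1)×4 matrix; ``merge_heights`` are the
    average between-group distances at each merge, non-decreasing for
    average linkage.
    """

    labels: tuple[str, ...]
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.linkage) + 1),
                "group_a": self.linkage[:, 0].astype(int),
                "group_b": self.linkage[:, 1].astype(int),
                "height": self.merge_heights,
                "size": self.linkage[:, 3].astype(int),
            }
        )

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as node depths (viewing only)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id].replace(" ", "_")
            left, right = node.get_left(), node.get_right()
            parts = ",".join(
                f"{walk(ch)}:{max(node.dist - ch.dist, 0.0):g}" for ch in (left, right)
            )
            return f"({parts})"

        return walk(tree) + ";"


@dataclass(frozen=True)
class CategoryAssignment:
    """Discrete colour-category labels for a set of accessions."""

    labels: dict[str, int]
    k: int
    cut_height: float
    elbow_candidates: tuple[tuple[int, float], ...] = ()

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="category")


def euclidean_distances(rows: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise Euclidean distances between equal-length numeric row vectors."""
    if isinstance(rows, pd.DataFrame):
        labels = tuple(str(i) for i in rows.index) if labels is None else tuple(labels)
        values = rows.to_numpy(dtype=float)
    else:
        values = np.asarray(rows, dtype=float)
        labels = tuple(f"row{i}" for i in range(values.shape[0])) if labels is None else tuple(labels)
    if values.ndim != 2:
        raise ValueError("expected a 2-D array of row vectors")
    if np.any(np.isnan(values)):
        raise ValueError("missing values in input vectors")
    return DistanceMatrix(labels, squareform(pdist(values, metric="euclidean")))


def upgma_cluster(d: DistanceMatrix) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) agglomerative clustering.

    The height of each merge is the mean distance from all points of one
    group to all points of the other; the two groups with the smallest mean
    distance merge first.
    """
    if len(d.labels) < 2:
        raise ValueError("need at least two observations to cluster")
    Z = hierarchy.linkage(d.condensed, method="average")
    return Dendrogram(d.labels, Z)


def elbow_candidates(dg: Dendrogram) -> tuple[tuple[int, float], ...]:
    """Merge steps ranked by the increase in merge height over the previous step.

    Returns ((step, height_increase), ...) with 1-based steps, best first.
    A cut just below the top candidate's merge defines the default number of
    categories. Ties break towards the latest step (fewest clusters).
    """
    h = dg.merge_heights
    if h.size < 3:
        raise ValueError("need at least three merges for elbow detection")
    increases = np.diff(h)  # increase of step i+2 over step i+1 (1-based)
    order = sorted(range(increases.size), key=lambda i: (-increases[i], -i))
    return tuple((i + 2, float(increases[i])) for i in order)


def cut_categories(
    dg: Dendrogram,
    height: float | None = None,
    k: int | None = None,
) -> CategoryAssignment:
    """Cut the dendrogram into discrete categories.

    Exactly one of ``height`` or ``k`` may be given; with neither, the cut is
    placed just below the top elbow candidate. ``k`` reproduces a fixed
    published category count (visual-inspection override).
    """
    n = dg.n_leaves
    heights = dg.merge_heights
    candidates = elbow_candidates(dg) if n >= 4 else ()
    if height is not None and k is not None:
        raise ValueError("give height or k, not both")
    if k is not None:
        if not (1 <= k <= n):
            raise ValueError(f"k={k} outside 1..{n}")
        flat = hierarchy.fcluster(dg.linkage, t=k, criterion="maxclust")
        cut = float(heights[n - k - 1]) if k < n else 0.0
    else:
        if height is None:
            if not candidates:
                raise ValueError("too few merges for an elbow; give height or k")
            step = candidates[0][0]
            height = 0.5 * (heights[step - 2] + heights[step - 1])
        flat = hierarchy.fcluster(dg.linkage, t=height, criterion="distance")
        cut = float(height)
    labels = {lab: int(c) for lab, c in zip(dg.labels, flat)}
    return CategoryAssignment(labels, k=len(set(flat)), cut_height=cut, elbow_candidates=candidates)


def categorize(
    rows: pd.DataFrame,
    k: int | None = None,
    height: float | None = None,
) -> tuple[CategoryAssignment, Dendrogram]:
    """Distance matrix -> UPGMA -> elbow (or fixed k) cut, in one call."""
    d = euclidean_distances(rows)
    dg = upgma_cluster(d)
    return cut_categories(dg, height=height, k=k), dg
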