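"""Ordination and composition-overlap analysis.

Covariance PCA of slide x taxon relative abundances, convex hulls of
treatment point clouds in the leading ordination plane, hull overlap and
point-containment fractions, pairwise dissimilarity matrices (Sorensen,
Euclidean, Bray-Curtis) and Mantel tests between the two assemblages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateHullError, ValidationError

METRICS = ("sorensen", "euclidean", "bray_curtis")


@dataclass
class OrdinationResult:
    """PCA scores/loadings with percent variance explained per component."""

    scores: pd.DataFrame  # slides x components
    loadings: pd.DataFrame  # taxa x components
    var_explained: np.ndarray  # percentages, non-increasing
    mean_: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Scores @ loadings' + column means; identity when all components kept."""
        return self.scores.to_numpy() @ self.loadings.to_numpy().T + self.mean_


def pca(matrix) -> OrdinationResult:
    """Covariance PCA (column-centered, unscaled) of slides x taxa proportions.

    Components are ordered by eigenvalue; the sign of each component is fixed
    so its largest-magnitude loading is positive.  ``var_explained`` is
    100 * eigenvalue / total variance.
    """
    if isinstance(matrix, pd.DataFrame):
        M = matrix.to_numpy(dtype=float)
        slide_ids, taxa = list(matrix.index), list(matrix.columns)
    else:
        M = np.asarray(matrix, dtype=float)
        slide_ids = list(range(M.shape[0]))
        taxa = list(range(M.shape[1]))
    n, t = M.shape
    if n < 2 or t < 2:
        raise ValidationError(f"PCA needs >= 2 slides and >= 2 taxa, got {M.shape}")
    mean = M.mean(axis=0)
    C = M - mean
    total_var = float(np.sum(C**2) / (n - 1))
    if total_var == 0:
        raise ValidationError("constant matrix: no variance to ordinate")
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    eig = s**2 / (n - 1)
    load = Vt.T
    scores = U * s
    for j in range(load.shape[1]):  # sign convention
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
            scores[:, j] = -scores[:, j]
    k = load.shape[1]
    comp = [f"PC{j + 1}" for j in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=slide_ids, columns=comp),
        loadings=pd.DataFrame(load, index=taxa, columns=comp),
        var_explained=100.0 * eig / total_var,
        mean_=mean,
    )


@dataclass
class Hull:
    """Counter-clockwise convex hull of a 2-D point set, with the originals."""

    vertices: np.ndarray  # (m, 2), counter-clockwise, no collinear triples
    points: np.ndarray  # the full input set


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> Hull:
    """Monotone-chain convex hull; strictly convex vertices only.

    Raises :class:`DegenerateHullError` for fewer than 3 distinct points or
    an all-collinear set (the error carries the degenerate segment).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"expected (n, 2) points, got {pts.shape}")
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] < 3:
        raise DegenerateHullError(f"need >= 3 distinct points, got {uniq.shape[0]}", uniq)
    order = np.lexsort((uniq[:, 1], uniq[:, 0]))
    P = uniq[order]

    def half(points_iter):
        chain: list[np.ndarray] = []
        for p in points_iter:
            while len(chain) >= 2 and _cross(chain[-2], chain[-1], p) <= 0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(P)
    upper = half(P[::-1])
    verts = np.array(lower[:-1] + upper[:-1])
    if verts.shape[0] < 3:
        raise DegenerateHullError("all points are collinear", np.array([P[0], P[-1]]))
    return Hull(vertices=verts, points=pts)


def point_in_hull(point, hull: Hull, atol: float = 1e-12) -> bool:
    """True if the point is inside or on the boundary of the hull (CCW test)."""
    p = np.asarray(point, dtype=float)
    V = hull.vertices
    for i in range(len(V)):
        a, b = V[i], V[(i + 1) % len(V)]
        if _cross(a, b, p) < -atol * max(1.0, np.abs(V).max()):
            return False
    return True


def _segments_intersect(p1, p2, q1, q2) -> bool:
    def orient(a, b, c):
        v = _cross(a, b, c)
        return 0 if v == 0 else (1 if v > 0 else -1)

    def on_seg(a, b, c):
        return (
            min(a[0], b[0]) <= c[0] <= max(a[0], b[0])
            and min(a[1], b[1]) <= c[1] <= max(a[1], b[1])
        )

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    if o1 != o2 and o3 != o4:
        return True
    if o1 == 0 and on_seg(p1, p2, q1):
        return True
    if o2 == 0 and on_seg(p1, p2, q2):
        return True
    if o3 == 0 and on_seg(q1, q2, p1):
        return True
    if o4 == 0 and on_seg(q1, q2, p2):
        return True
    return False


def hull_overlap(a: Hull, b: Hull) -> dict:
    """Overlap record between two hulls.

    ``overlaps`` is true iff a vertex of either hull lies inside the other
    or any pair of edges intersects (covers the cross-shaped case where
    neither polygon contains a vertex of the other).
    ``fraction_of_b_points_inside_a`` uses b's original points, matching the
    "how much of treatment b falls inside the reference polygon" reading.
    """
    overlaps = any(point_in_hull(v, a) for v in b.vertices) or any(
        point_in_hull(v, b) for v in a.vertices
    )
    if not overlaps:
        Va, Vb = a.vertices, b.vertices
        for i in range(len(Va)):
            for j in range(len(Vb)):
                if _segments_intersect(
                    Va[i], Va[(i + 1) % len(Va)], Vb[j], Vb[(j + 1) % len(Vb)]
                ):
                    overlaps = True
                    break
            if overlaps:
                break
    frac = float(np.mean([point_in_hull(p, a) for p in b.points]))
    return {"overlaps": bool(overlaps), "fraction_of_b_points_inside_a": frac}


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with slide labels."""

    values: pd.DataFrame
    metric: str

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(), checks=False)


def distance_matrix(table: pd.DataFrame, metric: str) -> DistanceMatrix:
    """Pairwise slide dissimilarities on a long community table.

    Abundances are closed to per-slide proportions first (Euclidean and
    Bray-Curtis operate on relative abundances); Sorensen uses
    presence/absence (presence = abundance strictly > 0), equivalent to the
    Dice dissimilarity 1 - 2a/(2a + b + c).
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    wide = table.pivot_table(
        index="slide_id", columns="taxon_id", values="abundance", fill_value=0.0
    ).sort_index()
    M = wide.to_numpy(dtype=float)
    totals = M.sum(axis=1)
    empty = wide.index[totals <= 0].tolist()
    if empty and metric in ("sorensen", "bray_curtis"):
        raise ValidationError(f"{metric} undefined for all-zero slides: {empty}")
    if metric == "sorensen":
        d = pdist(M > 0, metric="dice")
    else:
        P = M / np.where(totals > 0, totals, 1.0)[:, None]
        d = pdist(P, metric="euclidean" if metric == "euclidean" else "braycurtis")
    frame = pd.DataFrame(squareform(d), index=wide.index, columns=wide.index)
    return DistanceMatrix(values=frame, metric=metric)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "two_sided",
) -> dict:
    """Mantel test: Pearson r of the upper triangles, label-permutation null.

    The null permutes rows and columns of ``d2`` jointly; the p-value uses
    the add-one correction (count as-or-more extreme + 1)/(n_perm + 1).
    """
    A = d1.values
    B = d2.values
    if A.shape != B.shape or list(A.index) != list(B.index):
        raise ValidationError("distance matrices must share shape and slide ordering")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a = A.to_numpy()[iu]
    Bm = B.to_numpy()
    if a.std() == 0 or Bm[iu].std() == 0:
        raise ValidationError(
            f"constant {d1.metric if a.std() == 0 else d2.metric} distances; "
            "Mantel correlation undefined"
        )
    r_obs = float(np.corrcoef(a, Bm[iu])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = float(np.corrcoef(a, Bm[np.ix_(perm, perm)][iu])[0, 1])
        if alternative == "two_sided":
            count += abs(r) >= abs(r_obs) - 1e-15
        elif alternative == "greater":
            count += r >= r_obs - 1e-15
        elif alternative == "less":
            count += r <= r_obs + 1e-15
        else:
            raise ValidationError(f"unknown alternative {alternative!r}")
    return {"r": r_obs, "p": (count + 1) / (n_perm + 1), "n_perm": n_perm}
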