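"""Automated pseudolandmark 3D geometric morphometrics.

The pipeline mirrors automated correspondence-based shape analysis of
tooth crowns: evenly spread pseudolandmarks over each surface (greedy
farthest-point sampling), align every pair of specimens with iterative
closest points (rotations, optionally reflections, on unit-centroid-size
point sets), propagate point correspondences along the minimum spanning
tree of pairwise alignment distances, then run generalized Procrustes
superimposition and principal component analysis in the tangent space at
the mean shape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


class MorphometricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pseudolandmark spreading


def surface_sample(mesh, n: int, rng) -> np.ndarray:
    """Uniform-by-area random points on a triangle mesh."""
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    tri = verts[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    if areas.sum() == 0:
        raise MorphometricsError("degenerate mesh: zero surface area")
    idx = rng.choice(len(faces), size=n, p=areas / areas.sum())
    r1, r2 = rng.random(n), rng.random(n)
    sq = np.sqrt(r1)
    bary = np.column_stack([1 - sq, sq * (1 - r2), sq * r2])
    return np.einsum("nij,ni->nj", tri[idx], bary)


def farthest_point_sample(points: np.ndarray, n: int,
                          start: int = 0) -> np.ndarray:
    """Greedy farthest-point subset: each added point maximizes its
    distance to the points already chosen."""
    pts = np.asarray(points, dtype=float)
    if n > len(pts):
        raise MorphometricsError(f"asked for {n} points from {len(pts)}")
    chosen = [start]
    dist = np.linalg.norm(pts - pts[start], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(pts - pts[nxt], axis=1))
    return pts[chosen]


def spread_pseudolandmarks(mesh, n: int, oversample: int = 8,
                           seed: int = 0) -> np.ndarray:
    """Evenly spread ``n`` pseudolandmarks over a mesh surface.

    Candidate points are an area-uniform surface sample (augmented with
    the mesh vertices); the greedy farthest-point rule then picks an
    even subset.  Returns an (n, 3) array on the surface.
    """
    verts = np.asarray(mesh.vertices, dtype=float)
    if len(verts) < 4 or np.linalg.matrix_rank(verts - verts.mean(0)) < 2:
        raise MorphometricsError("degenerate mesh")
    if n < 1:
        raise MorphometricsError("need at least one pseudolandmark")
    rng = np.random.default_rng(seed)
    cand = np.vstack([verts,
                      surface_sample(mesh, max(oversample * n, 64), rng)])
    if n == 1:
        return cand[:1]
    return farthest_point_sample(cand, n)


# ---------------------------------------------------------------------------
# Pairwise ICP alignment


def _unit_size(points: np.ndarray):
    c = points.mean(axis=0)
    x = points - c
    size = math.sqrt((x ** 2).sum())
    return x / size, c, size


def _orthogonal_fit(A, B, allow_reflections):
    """Least-squares orthogonal map R with B ~ A @ R.T."""
    H = A.T @ B
    U, s, Vt = np.linalg.svd(H)
    R = Vt.T @ U.T
    if not allow_reflections and np.linalg.det(R) < 0:
        Vt2 = Vt.copy()
        Vt2[-1] *= -1
        R = Vt2.T @ U.T
    return R


@dataclass
class PairwiseAlignment:
    rotation: np.ndarray           # maps unit-size A onto B
    correspondence: np.ndarray     # permutation: B index for each A point
    distance: float                # Procrustes-style residual distance
    converged: bool


def pairwise_align(A: np.ndarray, B: np.ndarray,
                   allow_reflections: bool = True,
                   max_iters: int = 3000, tol: float = 1e-10
                   ) -> PairwiseAlignment:
    """Iterative-closest-point alignment of two pseudolandmark sets.

    Both sets are pre-normalized to unit centroid size.  ICP alternates
    nearest-neighbor correspondence and orthogonal Procrustes fits from
    several principal-axis initializations (including reflections when
    allowed); the final correspondence is the optimal one-to-one
    assignment.  The residual distance is symmetric in A and B.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise MorphometricsError("point sets must have equal counts")
    a, _, _ = _unit_size(A)
    b, _, _ = _unit_size(B)
    tree_b = cKDTree(b)

    # principal-axis initializations with sign flips
    _, _, Vta = np.linalg.svd(a, full_matrices=False)
    _, _, Vtb = np.linalg.svd(b, full_matrices=False)
    inits = []
    for sx in (1, -1):
        for sy in (1, -1):
            S = np.diag([sx, sy, sx * sy])
            inits.append(Vtb.T @ S @ Vta)
            if allow_reflections:
                S = np.diag([sx, sy, -sx * sy])
                inits.append(Vtb.T @ S @ Vta)
    inits.append(np.eye(3))

    best = (np.inf, None, False)
    iters_per_init = max(max_iters // len(inits), 10)
    for R in inits:
        prev = np.inf
        converged = False
        for _ in range(iters_per_init):
            mapped = a @ R.T
            d, idx = tree_b.query(mapped)
            rss = float((d ** 2).sum())
            if abs(prev - rss) < tol:
                converged = True
                break
            prev = rss
            R = _orthogonal_fit(a, b[idx], allow_reflections)
        if prev < best[0]:
            best = (prev, R, converged)
    rss, R, converged = best
    if not converged:
        logger.warning("ICP did not converge; returning best-so-far")

    # refine under the bijective objective: alternate optimal assignment
    # and orthogonal fits (this objective is symmetric in A and B)
    prev_perm = None
    for _ in range(50):
        mapped = a @ R.T
        cost = ((mapped[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(len(a), dtype=int)
        perm[rows] = cols
        if prev_perm is not None and np.array_equal(perm, prev_perm):
            break
        prev_perm = perm
        R = _orthogonal_fit(a, b[perm], allow_reflections)
    mapped = a @ R.T
    dist = math.sqrt(float(((mapped - b[perm]) ** 2).sum()))
    return PairwiseAlignment(rotation=R, correspondence=perm,
                             distance=dist, converged=converged)


# ---------------------------------------------------------------------------
# Globally consistent correspondence


def global_align(entries: list, allow_reflections: bool = True,
                 max_iters: int = 3000):
    """Propagate correspondences along the minimum spanning tree.

    Pairwise alignments are computed for all specimen pairs; the MST of
    the alignment-distance graph then defines the paths along which
    point relabelings are composed, yielding one consistent labeling
    (specimen 0's ordering).  Returns (aligned_arrays, distance_matrix).
    """
    n = len(entries)
    if n < 2:
        raise MorphometricsError("need at least two specimens")
    dist = np.zeros((n, n))
    aligns: dict = {}
    for i in range(n):
        for j in range(i + 1, n):
            al = pairwise_align(entries[i], entries[j],
                                allow_reflections, max_iters)
            aligns[(i, j)] = al
            dist[i, j] = dist[j, i] = al.distance

    # Prim's MST on the dense symmetric distance matrix (ties and
    # exact-zero distances between congruent specimens are fine)
    adj = [[] for _ in range(n)]
    in_tree = {0}
    while len(in_tree) < n:
        best = None
        for i in in_tree:
            for j in range(n):
                if j not in in_tree and (best is None
                                         or dist[i, j] < best[0]):
                    best = (dist[i, j], i, j)
        _, i, j = best
        adj[i].append(j)
        adj[j].append(i)
        in_tree.add(j)

    # perm[i][p] = index in specimen i corresponding to reference point p
    perms = {0: np.arange(len(entries[0]))}
    stack = [0]
    seen = {0}
    while stack:
        i = stack.pop()
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if (min(i, j), max(i, j)) in aligns:
                al = aligns[(min(i, j), max(i, j))]
                step = al.correspondence if i < j else \
                    np.argsort(al.correspondence)
            perms[j] = step[perms[i]]
            stack.append(j)
    if len(seen) < n:
        raise MorphometricsError("alignment graph is disconnected")

    aligned = [np.asarray(entries[i], dtype=float)[perms[i]]
               for i in range(n)]
    return aligned, dist


# ---------------------------------------------------------------------------
# Generalized Procrustes + tangent PCA


@dataclass
class ShapeSpace:
    """Procrustes shape space: superimposed coordinates, tangent-space
    PC scores and per-component variance fractions."""

    aligned: np.ndarray            # (n_specimens, n_points, 3)
    mean_shape: np.ndarray
    scores: np.ndarray             # (n_specimens, n_components)
    variance_fractions: np.ndarray

    def scree_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(1, len(self.variance_fractions) + 1),
            "variance_fraction": self.variance_fractions,
            "cumulative": np.cumsum(self.variance_fractions)})


def procrustes_tangent_pca(point_sets, allow_reflections: bool = False,
                           max_iter: int = 100, tol: float = 1e-12
                           ) -> ShapeSpace:
    """Generalized Procrustes superimposition and tangent-space PCA.

    Specimens (already in point correspondence) are centered, scaled to
    unit centroid size and iteratively rotated onto the evolving mean
    shape; tangent coordinates are deviations from the mean, and PCA is
    an SVD of their covariance without further weighting.
    """
    X = np.asarray(point_sets, dtype=float)
    if X.ndim != 3 or X.shape[0] < 3:
        raise MorphometricsError("need >= 3 specimens of equal point count")
    n = X.shape[0]
    Y = np.empty_like(X)
    for i in range(n):
        Y[i], _, _ = _unit_size(X[i])
    mean = Y[0].copy()
    prev = np.inf
    for _ in range(max_iter):
        for i in range(n):
            R = _orthogonal_fit(Y[i], mean, allow_reflections)
            Y[i] = Y[i] @ R.T
        new_mean = Y.mean(axis=0)
        new_mean, _, _ = _unit_size(new_mean)
        change = float(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if abs(prev - change) < tol or change < tol:
            break
        prev = change

    flat = Y.reshape(n, -1)
    mean_flat = mean.reshape(-1)
    tangent = flat - mean_flat
    tangent -= tangent.mean(axis=0)
    U, s, Vt = np.linalg.svd(tangent, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        fracs = np.zeros_like(var)
        scores = np.zeros_like(U)
    else:
        fracs = var / total
        scores = U * s
    return ShapeSpace(aligned=Y, mean_shape=mean, scores=scores,
                      variance_fractions=fracs)


def flag_outliers(scores: np.ndarray, labels, factor: float = 3.0
                  ) -> np.ndarray:
    """Flag specimens whose distance to their class centroid exceeds
    ``factor`` x the class median distance (an explicit, logged
    stand-in for ad hoc outlier removal)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    flagged = np.zeros(len(scores), dtype=bool)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        centroid = scores[idx].mean(axis=0)
        d = np.linalg.norm(scores[idx] - centroid, axis=1)
        med = np.median(d)
        if med > 0:
            flagged[idx] = d > factor * med
    if flagged.any():
        logger.info("flagged %d outlier specimens", int(flagged.sum()))
    return flagged


def morphometrics_pipeline(meshes, n_initial: int = 300,
                           n_final: int = 1100,
                           allow_reflections: bool = True,
                           max_iters: int = 3000, seed: int = 0):
    """Full two-resolution pipeline over a list of meshes.

    A coarse pseudolandmark set establishes the pairwise alignment
    distances (and hence the MST); the refined set is then corresponded
    in a second pass and fed to Procrustes tangent PCA.  Returns
    (ShapeSpace, coarse distance_matrix).
    """
    coarse = [spread_pseudolandmarks(m, n_initial, seed=seed + i)
              for i, m in enumerate(meshes)]
    aligned_coarse, dist = global_align(coarse, allow_reflections,
                                        max_iters)
    fine = [spread_pseudolandmarks(m, n_final, seed=seed + 1000 + i)
            for i, m in enumerate(meshes)]
    aligned_fine, _ = global_align(fine, allow_reflections, max_iters)
    space = procrustes_tangent_pca(aligned_fine,
                                   allow_reflections=allow_reflections)
    return space, dist
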