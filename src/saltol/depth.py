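"""Directional quantiles, quantile envelopes and Tukey halfspace depth.

The p-th directional quantile of planar data in unit direction s is the
inf-based empirical quantile of the projections s'y.  The directional
quantile envelope is the intersection of the supporting halfspaces
H(s, q) = {y : s'y >= q} over a finite set of directions,

    D(p) = intersection_s H(s, Q(p, s)),

which (with all directions) is exactly the Tukey depth level set
{y : depth(y) >= p}.  The centerpoint theorem guarantees a non-empty
envelope for p <= 1/3; the largest non-empty level p* in (1/3, 1/2]
defines the median envelope, whose vertex average is the bivariate median.

``tukey_depth`` is an exact O(n log n) angular-sweep computation used both
as the test oracle and to report depths of selected points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import HalfspaceIntersection

__all__ = [
    "DirectionSet",
    "QuantileEnvelope",
    "EnvelopeFamily",
    "PStarResult",
    "directional_quantile",
    "directional_quantiles",
    "build_envelope",
    "envelope_from_offsets",
    "find_p_star",
    "bivariate_median",
    "tukey_depth",
]

FEAS_TOL = 1e-9
P_STAR_STEP = 0.005


@dataclass(frozen=True)
class DirectionSet:
    """M equally spaced unit directions s_k = (cos th_k, sin th_k)."""

    angles: np.ndarray
    vectors: np.ndarray

    @classmethod
    def uniform(cls, M: int = 360) -> "DirectionSet":
        if M < 3:
            raise ValueError("need at least 3 directions")
        th = 2.0 * np.pi * np.arange(M) / M
        return cls(angles=th, vectors=np.column_stack([np.cos(th), np.sin(th)]))

    @property
    def M(self) -> int:
        return len(self.angles)


@dataclass
class QuantileEnvelope:
    """A (possibly empty or degenerate) convex polygon at level p.

    ``vertices`` are ordered counter-clockwise; a degenerate envelope
    (feasible set of measure ~0) is represented by a single vertex.
    """

    p: float
    vertices: np.ndarray
    is_empty: bool
    direction_count: int
    offsets: np.ndarray | None = None
    directions: DirectionSet | None = None

    @property
    def centroid(self) -> np.ndarray:
        if self.is_empty:
            raise ValueError("empty envelope has no centroid")
        return self.vertices.mean(axis=0)

    def contains(self, points: np.ndarray, tol: float = 1e-8) -> np.ndarray:
        """Membership via the defining halfspace constraints."""
        if self.offsets is None or self.directions is None:
            raise ValueError("envelope carries no halfspace description")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ok = (pts @ self.directions.vectors.T) >= (self.offsets - tol)
        return ok.all(axis=1)


@dataclass
class EnvelopeFamily:
    outer: QuantileEnvelope
    inner: QuantileEnvelope
    median: QuantileEnvelope
    p_star: float
    p_star_at_bound: bool = False


@dataclass
class PStarResult:
    p_star: float
    envelope: QuantileEnvelope
    at_centerpoint_bound: bool = False


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty data")
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 2:
        raise ValueError(f"expected n x 2 data, got shape {pts.shape}")
    return pts


def directional_quantile(points, s, p: float) -> float:
    """Inf-based empirical quantile of the projections s'y_i.

    Q(p, s) = inf{t : F_s(t) >= p}: the smallest projection value whose
    empirical CDF reaches p.  p = 1 returns the maximum projection.
    """
    pts = _as_points(points)
    s = np.asarray(s, dtype=float)
    if not np.isclose(np.linalg.norm(s), 1.0):
        raise ValueError("direction must be a unit vector")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"quantile level must be in (0, 1], got {p}")
    proj = np.sort(pts @ s)
    n = len(proj)
    idx = int(np.ceil(n * p)) - 1
    return float(proj[max(idx, 0)])


def directional_quantiles(points, directions: DirectionSet, p: float) -> np.ndarray:
    """Vectorised Q(p, s_k) over all directions of a DirectionSet."""
    pts = _as_points(points)
    if not 0.0 < p <= 1.0:
        raise ValueError(f"quantile level must be in (0, 1], got {p}")
    proj = np.sort(pts @ directions.vectors.T, axis=0)
    idx = max(int(np.ceil(pts.shape[0] * p)) - 1, 0)
    return proj[idx, :]


def envelope_from_offsets(
    offsets: np.ndarray, directions: DirectionSet, p: float
) -> QuantileEnvelope:
    """Intersect the halfspaces {y : s_k'y >= q_k} into a convex polygon.

    Emptiness is decided by the Chebyshev-center feasibility LP (maximum
    inscribed-circle radius r):  infeasible or r < -FEAS_TOL means empty;
    |r| within tolerance of zero yields a degenerate single-vertex
    envelope; otherwise the polygon vertices are enumerated by halfspace
    intersection about the strictly interior Chebyshev center.
    """
    S = directions.vectors
    q = np.asarray(offsets, dtype=float)
    M = directions.M
    if M < 3:
        raise ValueError("need at least 3 directions")
    # max r  s.t.  s_k'y - r >= q_k   (unit normals, so r is a true radius)
    A_ub = np.column_stack([-S, np.ones(M)])
    res = linprog(
        c=[0.0, 0.0, -1.0],
        A_ub=A_ub,
        b_ub=-q,
        bounds=[(None, None), (None, None), (None, None)],
        method="highs",
    )
    if res.status != 0:
        return QuantileEnvelope(p, np.empty((0, 2)), True, M, q, directions)
    r = -res.fun
    center = res.x[:2]
    if r < -FEAS_TOL:
        return QuantileEnvelope(p, np.empty((0, 2)), True, M, q, directions)
    if r <= FEAS_TOL:
        # feasible set has (numerically) no interior: a point or segment
        return QuantileEnvelope(p, center[None, :], False, M, q, directions)
    halfspaces = np.column_stack([-S, q])  # -s'y + q <= 0
    hs = HalfspaceIntersection(halfspaces, center)
    verts = hs.intersections
    verts = _dedupe_ccw(verts)
    return QuantileEnvelope(p, verts, False, M, q, directions)


def _dedupe_ccw(verts: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    # halfspace-intersection output is a vertex set of a convex polygon
    # (possibly with numerical duplicates): angular ordering suffices
    if len(verts) <= 1:
        return verts
    c = verts.mean(axis=0)
    order = np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))
    verts = verts[order]
    keep = [0]
    for i in range(1, len(verts)):
        if np.linalg.norm(verts[i] - verts[keep[-1]]) > tol:
            keep.append(i)
    if len(keep) > 1 and np.linalg.norm(verts[keep[0]] - verts[keep[-1]]) <= tol:
        keep.pop()
    return verts[keep]


def build_envelope(points, p: float, directions: DirectionSet | None = None) -> QuantileEnvelope:
    """Directional quantile envelope D(p) of a planar point cloud."""
    pts = _as_points(points)
    if directions is None:
        directions = DirectionSet.uniform()
    q = directional_quantiles(pts, directions, p)
    return envelope_from_offsets(q, directions, p)


def find_p_star(
    points,
    directions: DirectionSet | None = None,
    step: float = P_STAR_STEP,
) -> PStarResult:
    """Largest level in (1/3, 1/2] with a non-empty envelope (grid search).

    Searches the grid 1/2, 1/2 - step, ... descending; if every level above
    1/3 is empty, returns 1/3 (the centerpoint bound) with a flag.  An
    empty envelope at 1/3 violates the centerpoint theorem and raises.
    """
    pts = _as_points(points)
    if directions is None:
        directions = DirectionSet.uniform()
    base = build_envelope(pts, 1.0 / 3.0, directions)
    if base.is_empty:
        raise RuntimeError(
            "envelope empty at p = 1/3; the centerpoint theorem forbids this "
            "— degenerate data or a numerical failure"
        )
    grid = np.arange(0.5, 1.0 / 3.0, -step)
    for p in grid:
        env = build_envelope(pts, float(p), directions)
        if not env.is_empty:
            return PStarResult(float(p), env, at_centerpoint_bound=False)
    return PStarResult(1.0 / 3.0, base, at_centerpoint_bound=True)


def bivariate_median(envelope: QuantileEnvelope) -> np.ndarray:
    """Vertex average of the median envelope (depth-based location)."""
    if envelope.is_empty:
        raise ValueError("cannot take the bivariate median of an empty envelope")
    return envelope.vertices.mean(axis=0)


def tukey_depth(point, points) -> float:
    """Exact halfspace depth of ``point`` relative to ``points``.

    depth = min over closed halfplanes through the point of the fraction
    of data they contain; computed by an angular sweep: with data angles
    theta_i about the query, the minimum closed-halfplane count equals
    n' - max_i #{theta_j in (theta_i - pi, theta_i]} plus any data
    coincident with the query.
    """
    pts = _as_points(points)
    q = np.asarray(point, dtype=float).ravel()
    d = pts - q
    r = np.hypot(d[:, 0], d[:, 1])
    coincident = r < 1e-12
    m = int(coincident.sum())
    d = d[~coincident]
    n = pts.shape[0]
    if len(d) == 0:
        return 1.0
    th = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2.0 * np.pi)
    th.sort()
    ext = np.concatenate([th, th + 2.0 * np.pi])
    hi = np.searchsorted(ext, th + 2.0 * np.pi, side="right")
    lo = np.searchsorted(ext, th + np.pi, side="right")
    max_open = int((hi - lo).max())
    return (m + len(d) - max_open) / n
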