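"""Vascular-canal orientation analysis.

The canal network mask is thinned to a one-voxel-wide skeleton, the skeleton
is decomposed into branches between branch points and endpoints, and each
branch is reduced to the straight chord between its terminal voxels.  Two
angles describe each chord:

* the **longitudinal angle** θL — the angle relative to the bone's long axis
  (the stack axis z), with 90° meaning parallel to the axis;
* the **radial angle** θR — the angle by which the chord deviates from the
  tangent plane of the (circular-cylinder) bone surface at the chord
  midpoint, with 90° meaning purely radial.

Each chord is classified as longitudinal, radial, laminar or oblique from
the (θL, θR) pair, and length-weighted category proportions form the
orientation indices (laminarity etc.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import DegenerateInputError, FitFailureError, UndefinedGeometryError
from .volumes import BinaryVolume

# Angle-box boundaries (degrees) for the orientation categories.
LONGITUDINAL_MIN_DEG = 67.5   # θL at/above this → longitudinal, any θR
RADIAL_MIN_DEG = 67.5         # else θR at/above this → radial
LAMINAR_MAX_DEG = 22.5        # else θR at/below this → laminar
CATEGORIES = ("laminar", "longitudinal", "radial", "oblique")


@dataclass
class BoneFrame:
    """Reference frame for angle measurement: the bone long axis is the
    volume z axis; ``center`` is the (x, y) position of that axis in μm,
    which may lie outside a quadrant crop."""

    center: tuple[float, float]

    def __post_init__(self) -> None:
        cx, cy = self.center
        if not (np.isfinite(cx) and np.isfinite(cy)):
            raise ValueError("bone centre must be finite")


@dataclass
class CanalSegment:
    """A straight canal abstraction between two skeleton terminal voxels."""

    endpoints: np.ndarray          # (2, 3) world (x, y, z) μm
    midpoint: np.ndarray           # (3,) μm
    direction: np.ndarray          # unit vector, sign-free canonical form
    chord_length: float            # μm, endpoint-to-endpoint
    path_length: float             # μm, along the skeleton branch
    theta_long: float              # degrees [0, 90]
    theta_rad: float               # degrees [0, 90]
    category: str


@dataclass
class OrientationIndices:
    """Length-weighted proportions of the four canal orientation classes."""

    laminar_index: float
    longitudinal_index: float
    radial_index: float
    oblique_index: float
    total_weighted_length: float   # μm (sum of chord lengths)
    n_segments: int

    def as_dict(self) -> dict[str, float]:
        return {
            "laminar_index": self.laminar_index,
            "longitudinal_index": self.longitudinal_index,
            "radial_index": self.radial_index,
            "oblique_index": self.oblique_index,
            "total_weighted_length_um": self.total_weighted_length,
            "n_segments": self.n_segments,
        }


def longitudinal_angle(direction) -> float:
    """Angle (degrees) of a direction relative to the bone long axis z;
    90° iff parallel to the axis.  Sign-free: v and −v are equivalent."""
    v = np.asarray(direction, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return float(np.degrees(np.arcsin(min(1.0, abs(v[2]) / n))))


def radial_angle(midpoint, direction, frame: BoneFrame) -> float:
    """Angle (degrees) by which a canal deviates from the tangent plane of
    the bone surface at its midpoint: 0° in-plane (e.g. circumferential or
    axial), 90° purely radial (a spoke toward the surface)."""
    v = np.asarray(direction, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    m = np.asarray(midpoint, dtype=float)
    dx, dy = m[0] - frame.center[0], m[1] - frame.center[1]
    rho = np.hypot(dx, dy)
    if rho == 0:
        raise UndefinedGeometryError("midpoint lies on the bone axis")
    r_hat = np.array([dx / rho, dy / rho, 0.0])
    return float(np.degrees(np.arcsin(min(1.0, abs(v @ r_hat) / n))))


def classify_segment(theta_long: float, theta_rad: float) -> str:
    """Classify one (θL, θR) pair.  Longitudinal is tested first (its box
    spans any radial angle), then radial, then laminar; everything else is
    oblique.  Interval bounds are inclusive."""
    if not (0.0 <= theta_long <= 90.0 and 0.0 <= theta_rad <= 90.0):
        raise ValueError(f"angles must be in [0, 90], got ({theta_long}, {theta_rad})")
    if theta_long >= LONGITUDINAL_MIN_DEG:
        return "longitudinal"
    if theta_rad >= RADIAL_MIN_DEG:
        return "radial"
    if theta_rad <= LAMINAR_MAX_DEG:
        return "laminar"
    return "oblique"


def classify_many(theta_long, theta_rad) -> np.ndarray:
    """Vectorised :func:`classify_segment` over arrays of angles."""
    tl = np.asarray(theta_long, dtype=float)
    tr = np.asarray(theta_rad, dtype=float)
    if np.any((tl < 0) | (tl > 90) | (tr < 0) | (tr > 90)):
        raise ValueError("angles must be in [0, 90]")
    out = np.full(tl.shape, "oblique", dtype=object)
    out[tr <= LAMINAR_MAX_DEG] = "laminar"
    out[tr >= RADIAL_MIN_DEG] = "radial"
    out[tl >= LONGITUDINAL_MIN_DEG] = "longitudinal"
    return out


def skeletonize(canals: BinaryVolume) -> BinaryVolume:
    """Topology-preserving 3D thinning of the canal mask to single-voxel
    lines (medial-axis skeleton)."""
    if canals.count() == 0:
        raise DegenerateInputError("cannot skeletonise an empty mask")
    skel = _sk_skeletonize(canals.voxels)
    return BinaryVolume(skel, canals.voxel_size, label="skeleton")


_OFFSETS = np.array(
    [(dz, dy, dx)
     for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)],
    dtype=np.int64,
)


def _skeleton_graph(skel: np.ndarray):
    """26-connected adjacency over skeleton voxels.

    Returns (coords (N,3) int array in (z,y,x), adjacency list of lists)."""
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    adj: list[list[int]] = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in _OFFSETS:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None and j > i:
                adj[i].append(j)
                adj[j].append(i)
    return coords, adj


def _branch_paths(coords: np.ndarray, adj: list[list[int]]) -> list[list[int]]:
    """Decompose the skeleton graph into branches: voxel paths whose interior
    nodes all have degree 2 and whose ends are endpoints (degree ≤ 1) or
    branch points (degree ≥ 3).  Pure cycles are split into two chords at
    their two most distant nodes."""
    deg = np.array([len(a) for a in adj])
    terminals = set(np.nonzero(deg != 2)[0].tolist())
    visited_edges: set[tuple[int, int]] = set()

    def _edge(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    paths: list[list[int]] = []
    for t in terminals:
        for n in adj[t]:
            if _edge(t, n) in visited_edges:
                continue
            path = [t, n]
            visited_edges.add(_edge(t, n))
            prev, cur = t, n
            while cur not in terminals:
                nxts = [q for q in adj[cur] if q != prev]
                if not nxts:
                    break
                nxt = nxts[0]
                if _edge(cur, nxt) in visited_edges:
                    break
                visited_edges.add(_edge(cur, nxt))
                path.append(nxt)
                prev, cur = cur, nxt
            paths.append(path)

    # Remaining components are pure cycles (every node degree 2).
    in_cycle = (deg == 2)
    for i in np.nonzero(in_cycle)[0]:
        if any(_edge(i, j) in visited_edges for j in adj[i]):
            continue
        cyc = [i]
        prev, cur = i, adj[i][0]
        visited_edges.add(_edge(i, cur))
        while cur != i:
            cyc.append(cur)
            nxts = [q for q in adj[cur] if q != prev]
            if not nxts:
                break
            prev, cur = cur, nxts[0]
            visited_edges.add(_edge(prev, cur))
        # split the cycle at its two most (Euclidean) distant nodes
        pts = coords[cyc].astype(float)
        m = len(cyc)
        if m < 4:
            continue
        if m <= 2000:
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            a, b = np.unravel_index(np.argmax(d2), d2.shape)
        else:
            a, b = 0, m // 2
        a, b = sorted((int(a), int(b)))
        paths.append(cyc[a:b + 1])
        paths.append(cyc[b:] + cyc[:a + 1])
    return paths


def _canonical_direction(v: np.ndarray) -> np.ndarray:
    """Sign-free canonical unit vector: first nonzero component positive."""
    u = v / np.linalg.norm(v)
    for c in u:
        if c != 0:
            return u if c > 0 else -u
    raise ValueError("zero direction vector")


def extract_segments(
    skeleton: BinaryVolume,
    frame: BoneFrame,
    min_length: float | None = None,
) -> list[CanalSegment]:
    """Decompose a skeleton into straight chords between branch points and
    endpoints, with per-chord angles and orientation category.

    ``min_length`` (μm) discards spur chords shorter than the threshold;
    default 3 voxels.  An empty skeleton yields an empty list.
    """
    h = skeleton.voxel_size
    if min_length is None:
        min_length = 3.0 * h
    if skeleton.count() == 0:
        return []
    coords, adj = _skeleton_graph(skeleton.voxels)
    paths = _branch_paths(coords, adj)

    segments: list[CanalSegment] = []
    for path in paths:
        pts_zyx = coords[path].astype(float)
        # world coordinates (x, y, z) of voxel centres
        pts = (pts_zyx[:, ::-1] + 0.5) * h
        p0, p1 = pts[0], pts[-1]
        chord = float(np.linalg.norm(p1 - p0))
        if chord <= 0 or chord < min_length:
            continue
        path_len = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        v = _canonical_direction(p1 - p0)
        mid = 0.5 * (p0 + p1)
        tl = longitudinal_angle(v)
        try:
            tr = radial_angle(mid, v, frame)
        except UndefinedGeometryError:
            continue
        segments.append(
            CanalSegment(
                endpoints=np.stack([p0, p1]),
                midpoint=mid,
                direction=v,
                chord_length=chord,
                path_length=path_len,
                theta_long=tl,
                theta_rad=tr,
                category=classify_segment(tl, tr),
            )
        )
    return segments


def orientation_indices(segments: list[CanalSegment]) -> OrientationIndices:
    """Chord-length-weighted proportions of the four orientation classes."""
    if not segments:
        raise DegenerateInputError("orientation indices undefined for an empty segment list")
    total = sum(s.chord_length for s in segments)
    by_cat = {c: 0.0 for c in CATEGORIES}
    for s in segments:
        by_cat[s.category] += s.chord_length
    return OrientationIndices(
        laminar_index=by_cat["laminar"] / total,
        longitudinal_index=by_cat["longitudinal"] / total,
        radial_index=by_cat["radial"] / total,
        oblique_index=by_cat["oblique"] / total,
        total_weighted_length=total,
        n_segments=len(segments),
    )


def _fit_circle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kåsa) least-squares circle fit; returns (cx, cy, R)."""
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    if np.linalg.matrix_rank(A) < 3:
        raise FitFailureError("degenerate boundary: collinear points")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if not np.isfinite(r2) or r2 <= 0:
        raise FitFailureError("circle fit produced a non-positive radius")
    return float(cx), float(cy), float(np.sqrt(r2))


def estimate_center(
    solid_cortex: BinaryVolume,
    n_trials: int = 400,
    inlier_tol_voxels: float = 1.5,
    min_arc_deg: float = 30.0,
    seed: int = 0,
) -> BoneFrame:
    """Estimate the bone's central axis position by a robust circle fit to
    the cortex boundary of the mid-slice.

    A seeded RANSAC over 3-point circle fits finds the dominant circular
    arc (the periosteal boundary; the concentric endosteal arc yields the
    same centre), ignoring the straight cut edges of a quadrant crop; the
    winning consensus set is then refined by algebraic least squares.  The
    centre may lie outside the imaged volume.  Boundaries without measurable
    curvature raise a fit failure: a straight edge can sit within tolerance
    of a large circle, so the consensus set must also subtend at least
    ``min_arc_deg`` (default 30°) around the fitted centre.
    """
    if solid_cortex.count() == 0:
        raise DegenerateInputError("empty cortex mask")
    h = solid_cortex.voxel_size
    mid = solid_cortex.voxels[solid_cortex.shape[0] // 2]
    if not mid.any():
        # fall back to the densest slice
        counts = solid_cortex.voxels.sum(axis=(1, 2))
        mid = solid_cortex.voxels[int(np.argmax(counts))]
    boundary = mid & ~ndi.binary_erosion(mid)
    iy, ix = np.nonzero(boundary)
    x = (ix + 0.5) * h
    y = (iy + 0.5) * h
    if len(x) < 3:
        raise FitFailureError("too few boundary voxels for a circle fit")
    extent = max(x.max() - x.min(), y.max() - y.min(), h)
    tol = inlier_tol_voxels * h
    rng = np.random.default_rng(seed)
    best: tuple[int, float, float, float] | None = None
    for _ in range(n_trials):
        i, j, k = rng.choice(len(x), size=3, replace=False)
        try:
            cx, cy, R = _fit_circle(x[[i, j, k]], y[[i, j, k]])
        except FitFailureError:
            continue
        if R > 5.0 * extent:  # near-collinear sample: a line, not an arc
            continue
        n_in = int(np.sum(np.abs(np.hypot(x - cx, y - cy) - R) <= tol))
        if best is None or n_in > best[0]:
            best = (n_in, cx, cy, R)
    if best is None or best[0] < max(10, 0.15 * len(x)):
        raise FitFailureError("boundary has no dominant circular arc")
    _, cx, cy, R = best
    inliers = None
    for _ in range(3):  # refine on the consensus set
        inliers = np.abs(np.hypot(x - cx, y - cy) - R) <= tol
        if inliers.sum() < 3:
            break
        cx, cy, R = _fit_circle(x[inliers], y[inliers])
    if R > 5.0 * extent:
        raise FitFailureError("boundary has no measurable curvature")
    if not (np.isfinite(cx) and np.isfinite(cy)):
        raise FitFailureError("circle fit diverged")
    if inliers is not None and inliers.sum() >= 3:
        ang = np.sort(np.degrees(np.arctan2(y[inliers] - cy, x[inliers] - cx)))
        gaps = np.diff(np.append(ang, ang[0] + 360.0))
        span = 360.0 - gaps.max()
        if span < min_arc_deg:
            raise FitFailureError(
                f"consensus boundary subtends only {span:.1f} degrees: not a circular arc")
        # a straight edge can masquerade as a large arc: reject if a line
        # fits the consensus set almost as well as the circle does
        pts = np.column_stack([x[inliers], y[inliers]])
        centred = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        perp = np.abs(centred @ vt[1])
        if perp.max() <= 3.0 * tol:
            raise FitFailureError("boundary indistinguishable from a straight edge")
    return BoneFrame(center=(cx, cy))


def estimate_outer_radius(solid_cortex: BinaryVolume, frame: BoneFrame) -> float:
    """Mean periosteal radius (μm) of the mid-slice about ``frame.center``."""
    if solid_cortex.count() == 0:
        raise DegenerateInputError("empty cortex mask")
    h = solid_cortex.voxel_size
    mid = solid_cortex.voxels[solid_cortex.shape[0] // 2]
    boundary = mid & ~ndi.binary_erosion(mid)
    iy, ix = np.nonzero(boundary)
    x = (ix + 0.5) * h - frame.center[0]
    y = (iy + 0.5) * h - frame.center[1]
    ang = np.degrees(np.arctan2(y, x))
    rad = np.hypot(x, y)
    radii = []
    for b in np.unique(np.floor(ang / 2.0)):
        sel = np.floor(ang / 2.0) == b
        radii.append(rad[sel].max())
    return float(np.mean(radii))
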