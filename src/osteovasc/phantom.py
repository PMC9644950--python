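"""Ground-truthed phantom volumes of a mid-diaphyseal bone cortex.

The phantom is a hollow cylinder (optionally a quadrant/sector crop) of
mineralised "bone" containing two pore populations:

* **vascular canals** — tubes of known centreline, radius and orientation
  class (laminar canals run as circumferential/helical arcs; longitudinal,
  radial and oblique canals are straight tubes whose direction is drawn
  uniformly from the feasible part of the corresponding angle box);
* **osteocyte lacunae** — small ellipsoids below the 1000 μm³ canal/lacuna
  volume boundary, which the size filter must remove.

Every canal record carries its analytically computed chord, longitudinal
angle and radial angle, so the downstream segmentation, morphometry and
orientation stages can be validated against exact ground truth without any
external scan data.

Note the two angles of a direction are not independent:
``sin²θL + sin²θR ≤ 1`` always holds, so "uniform in the angle box" means
uniform over the feasible part of the box (for the radial box this forces
θL ≤ 22.5°).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import orientation as ori
from .errors import VoxelBudgetError
from .volumes import BinaryVolume, GrayscaleVolume, write_tiff

#: boundary (μm³) between osteocyte lacunae and vascular canals
LACUNA_VOLUME_UM3 = 1000.0


@dataclass
class CanalGroundTruth:
    """One vascular canal: centreline polyline plus analytic truth."""

    category: str
    centerline: np.ndarray            # (N, 3) world (x, y, z) μm
    radius: float                     # μm
    true_longitudinal_angle: float    # degrees, chord-based
    true_radial_angle: float          # degrees, chord-based, at chord midpoint
    chord_length: float               # μm, endpoint to endpoint
    path_length: float                # μm along the centreline

    @property
    def length(self) -> float:
        """Chord length (μm) — the straight-segment abstraction's length."""
        return self.chord_length

    @property
    def volume_um3(self) -> float:
        """Analytic tube volume π r² L (path length)."""
        return float(np.pi * self.radius**2 * self.path_length)


@dataclass
class LacunaGroundTruth:
    center: np.ndarray     # (3,) world μm
    semi_axes: np.ndarray  # (3,) μm

    @property
    def volume_um3(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))


@dataclass
class PhantomSpec:
    """Geometry, contrast and content of one phantom volume.

    Defaults give a full-ring cortex small enough for seconds-scale tests:
    outer radius 600 μm, cortical thickness 300 μm, height 400 μm at 2 μm
    voxels.  ``sector`` restricts the shell to a polar-angle range (degrees),
    emulating the quadrant sections cut from larger bones.
    """

    outer_radius: float = 600.0
    cortical_thickness: float = 300.0
    height: float = 400.0
    sector: tuple[float, float] = (0.0, 360.0)
    voxel_size: float = 2.0
    canal_specs: list[CanalGroundTruth] = field(default_factory=list)
    lacuna_specs: list[LacunaGroundTruth] = field(default_factory=list)
    foreground_intensity: float = 200.0
    background_intensity: float = 50.0
    noise_sd: float = 10.0
    seed: int = 0
    max_voxels: int = 400_000_000

    def __post_init__(self) -> None:
        if not (self.outer_radius > self.cortical_thickness > 0):
            raise ValueError("need outer_radius > cortical_thickness > 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.foreground_intensity <= self.background_intensity:
            raise ValueError("foreground intensity must exceed background")
        a0, a1 = self.sector
        if not (0.0 <= a0 < a1 <= 360.0):
            raise ValueError("sector must satisfy 0 <= start < stop <= 360")
        if self.height <= 0:
            raise ValueError("height must be positive")

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.cortical_thickness

    # ---- bounding box / frame ------------------------------------------
    def _bbox_um(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the shell sector, centre at (0, 0)."""
        a0, a1 = np.radians(self.sector)
        ang = np.linspace(a0, a1, 721)
        pts_x = np.concatenate([self.outer_radius * np.cos(ang), self.inner_radius * np.cos(ang)])
        pts_y = np.concatenate([self.outer_radius * np.sin(ang), self.inner_radius * np.sin(ang)])
        return float(pts_x.min()), float(pts_x.max()), float(pts_y.min()), float(pts_y.max())

    def grid_shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx) voxel grid covering the shell plus a 2-voxel margin."""
        h = self.voxel_size
        xmin, xmax, ymin, ymax = self._bbox_um()
        nx = int(np.ceil((xmax - xmin) / h)) + 4
        ny = int(np.ceil((ymax - ymin) / h)) + 4
        nz = int(np.round(self.height / h))
        return nz, ny, nx

    def center_um(self) -> tuple[float, float]:
        """World (x, y) μm of the bone axis in the cropped volume."""
        h = self.voxel_size
        xmin, _, ymin, _ = self._bbox_um()
        return (-xmin + 2 * h, -ymin + 2 * h)

    def frame(self) -> ori.BoneFrame:
        return ori.BoneFrame(center=self.center_um())


# --------------------------------------------------------------------------
# canal population
# --------------------------------------------------------------------------

# feasible angle boxes per category (θL range, θR range), degrees
_BOXES = {
    "longitudinal": ((ori.LONGITUDINAL_MIN_DEG, 90.0), (0.0, 90.0)),
    "radial": ((0.0, ori.LONGITUDINAL_MIN_DEG), (ori.RADIAL_MIN_DEG, 90.0)),
    "laminar": ((0.0, ori.LONGITUDINAL_MIN_DEG), (0.0, ori.LAMINAR_MAX_DEG)),
}


def _sample_box_angles(rng: np.random.Generator, category: str) -> tuple[float, float]:
    """Uniform (θL, θR) over the feasible part of the category's box
    (feasibility: sin²θL + sin²θR ≤ 1; oblique = complement of the boxes)."""
    for _ in range(10_000):
        if category == "oblique":
            tl = rng.uniform(0.0, 90.0)
            tr = rng.uniform(0.0, 90.0)
            if ori.classify_segment(tl, tr) != "oblique":
                continue
        else:
            (l0, l1), (r0, r1) = _BOXES[category]
            tl = rng.uniform(l0, l1)
            tr = rng.uniform(r0, r1)
        if np.sin(np.radians(tl)) ** 2 + np.sin(np.radians(tr)) ** 2 <= 1.0:
            return tl, tr
    raise RuntimeError("angle sampling failed")  # pragma: no cover


def _inside_shell_mask(spec: PhantomSpec, pts: np.ndarray, margin: float) -> np.ndarray:
    """Per-point test: inside the shell with a radial/axial and angular
    safety margin (so a tube of that radius stays inside)."""
    cx, cy = spec.center_um()
    x, y, z = pts[:, 0] - cx, pts[:, 1] - cy, pts[:, 2]
    rho = np.hypot(x, y)
    ok = (rho >= spec.inner_radius + margin) & (rho <= spec.outer_radius - margin)
    ok &= (z >= margin) & (z <= spec.height - margin)
    a0, a1 = spec.sector
    if (a0, a1) != (0.0, 360.0):
        ang = np.degrees(np.arctan2(y, x)) % 360.0
        pad = np.degrees(margin / np.maximum(rho, 1e-9))
        ok &= (ang >= a0 + pad) & (ang <= a1 - pad)
    return ok


def _inside_shell(spec: PhantomSpec, pts: np.ndarray, margin: float) -> bool:
    return bool(_inside_shell_mask(spec, pts, margin).all())


def _chord_truth(spec: PhantomSpec, centerline: np.ndarray) -> tuple[float, float, float, float]:
    """Chord-based (θL, θR, chord_length, path_length) for a centreline."""
    p0, p1 = centerline[0], centerline[-1]
    chord = float(np.linalg.norm(p1 - p0))
    path = float(np.linalg.norm(np.diff(centerline, axis=0), axis=1).sum())
    v = (p1 - p0) / chord
    mid = 0.5 * (p0 + p1)
    tl = ori.longitudinal_angle(v)
    tr = ori.radial_angle(mid, v, spec.frame())
    return tl, tr, chord, path


def _make_straight_canal(
    rng: np.random.Generator,
    spec: PhantomSpec,
    category: str,
    radius: float,
    target_length: float,
    min_length: float,
) -> CanalGroundTruth | None:
    """One straight canal of the given category, confined to the shell, or
    None if no placement was found."""
    cx, cy = spec.center_um()
    h = spec.voxel_size
    margin = radius + h
    for _ in range(60):
        tl, tr = _sample_box_angles(rng, category)
        rho = rng.uniform(spec.inner_radius + margin, spec.outer_radius - margin)
        a0, a1 = spec.sector
        phi = np.radians(rng.uniform(a0, a1))
        z0 = rng.uniform(margin, spec.height - margin)
        m = np.array([cx + rho * np.cos(phi), cy + rho * np.sin(phi), z0])
        r_hat = np.array([np.cos(phi), np.sin(phi), 0.0])
        c_hat = np.array([-np.sin(phi), np.cos(phi), 0.0])
        sl, sr = np.sin(np.radians(tl)), np.sin(np.radians(tr))
        b = np.sqrt(max(0.0, 1.0 - sl**2 - sr**2))
        sgn = rng.choice([-1.0, 1.0], size=3)
        v = sgn[0] * sr * r_hat + sgn[1] * b * c_hat + sgn[2] * sl * np.array([0.0, 0.0, 1.0])
        v /= np.linalg.norm(v)
        # march outwards to find the in-shell extent
        step = h / 2.0
        ts = np.arange(step, target_length / 2.0 + step, step)

        def _extent(sign: float) -> float:
            ok = _inside_shell_mask(spec, m[None, :] + sign * ts[:, None] * v, margin)
            if ok.all():
                return float(ts[-1])
            first_bad = int(np.argmin(ok))
            return float(ts[first_bad - 1]) if first_bad > 0 else 0.0

        t_plus, t_minus = _extent(+1.0), _extent(-1.0)
        length = t_plus + t_minus
        if length < min_length:
            continue
        p0, p1 = m - t_minus * v, m + t_plus * v
        centerline = np.stack([p0, p1])
        tl2, tr2, chord, path = _chord_truth(spec, centerline)
        if ori.classify_segment(tl2, tr2) != category:
            continue  # frame shift moved the true angles out of the box
        if np.pi * radius**2 * path <= LACUNA_VOLUME_UM3 * 1.2:
            continue  # must comfortably survive the lacuna filter
        return CanalGroundTruth(category, centerline, radius, tl2, tr2, chord, path)
    return None


def _make_laminar_canal(
    rng: np.random.Generator,
    spec: PhantomSpec,
    radius: float,
    target_length: float,
    min_length: float,
) -> CanalGroundTruth | None:
    """One laminar canal: a circumferential (optionally helical) arc at fixed
    radius.  The chord of such an arc is perpendicular to the radial
    direction at the chord midpoint, so the chord-based true radial angle is
    exactly 0; the pitch sets the longitudinal angle."""
    cx, cy = spec.center_um()
    h = spec.voxel_size
    margin = radius + h
    a0, a1 = spec.sector
    for _ in range(60):
        pitch = rng.uniform(0.0, ori.LONGITUDINAL_MIN_DEG)
        rho = rng.uniform(spec.inner_radius + margin, spec.outer_radius - margin)
        z0 = rng.uniform(margin, spec.height - margin)
        sp, cp = np.sin(np.radians(pitch)), np.cos(np.radians(pitch))
        # caps: z extent, sector extent, and <= 90 degrees of arc
        L = target_length
        if sp > 0:
            L = min(L, (spec.height - margin - z0) / sp)
        L = min(L, np.radians(90.0) * rho / max(cp, 1e-9))
        phi0 = rng.uniform(a0, a1)
        pad = np.degrees(margin / rho)
        avail = np.radians(max(0.0, a1 - pad - phi0)) * rho / max(cp, 1e-9) if (a0, a1) != (0.0, 360.0) else np.inf
        L = min(L, avail)
        if L < min_length:
            continue
        s = np.arange(0.0, L + h / 2.0, h)
        phi = np.radians(phi0) + s * cp / rho
        centerline = np.column_stack([
            cx + rho * np.cos(phi),
            cy + rho * np.sin(phi),
            z0 + s * sp,
        ])
        if not _inside_shell(spec, centerline, margin):
            continue
        tl2, tr2, chord, path = _chord_truth(spec, centerline)
        if ori.classify_segment(tl2, tr2) != "laminar":
            continue
        if np.pi * radius**2 * path <= LACUNA_VOLUME_UM3 * 1.2:
            continue
        return CanalGroundTruth("laminar", centerline, radius, tl2, tr2, chord, path)
    return None


def generate_canal_population(
    n: int,
    mixture: tuple[float, float, float, float],
    geometry: PhantomSpec,
    seed: int,
    radius_range: tuple[float, float] = (4.0, 8.0),
    length_range: tuple[float, float] = (100.0, 200.0),
    min_length: float = 60.0,
) -> list[CanalGroundTruth]:
    """Draw ``n`` canals with category proportions ``mixture`` (laminar,
    longitudinal, radial, oblique).  Canal radii and target lengths are drawn
    uniformly from the given ranges (μm); canals that cannot be placed inside
    the shell are skipped with a warning."""
    if n < 0:
        raise ValueError("n must be non-negative")
    mixture = np.asarray(mixture, dtype=float)
    if mixture.shape != (4,) or np.any(mixture < 0):
        raise ValueError("mixture must be 4 non-negative proportions")
    if abs(mixture.sum() - 1.0) > 1e-9:
        raise ValueError("mixture must sum to 1 (within 1e-9)")
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    counts = rng.multinomial(n, mixture)
    cats = np.repeat(np.array(ori.CATEGORIES), counts)
    rng.shuffle(cats)

    canals: list[CanalGroundTruth] = []
    n_skipped = 0
    for cat in cats:
        radius = rng.uniform(*radius_range)
        target = rng.uniform(*length_range)
        if cat == "laminar":
            c = _make_laminar_canal(rng, geometry, radius, target, min_length)
        else:
            c = _make_straight_canal(rng, geometry, cat, radius, target, min_length)
        if c is None:
            n_skipped += 1
        else:
            canals.append(c)
    if n_skipped:
        warnings.warn(f"{n_skipped} of {n} canals could not be placed in the shell and were skipped")
    return canals


def generate_lacuna_population(
    n: int,
    geometry: PhantomSpec,
    seed: int,
    semi_axis_range: tuple[float, float] = (2.5, 7.0),
) -> list[LacunaGroundTruth]:
    """Draw ``n`` ellipsoidal lacunae inside the shell, each below the
    1000 μm³ canal/lacuna volume boundary."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    cx, cy = geometry.center_um()
    out: list[LacunaGroundTruth] = []
    for _ in range(n):
        for _ in range(200):
            axes = np.sort(rng.uniform(*semi_axis_range, size=3))[::-1]
            vol = 4.0 / 3.0 * np.pi * np.prod(axes)
            if vol > LACUNA_VOLUME_UM3:
                continue
            margin = axes.max() + geometry.voxel_size
            rho = rng.uniform(geometry.inner_radius + margin, geometry.outer_radius - margin)
            a0, a1 = geometry.sector
            phi = np.radians(rng.uniform(a0, a1))
            z0 = rng.uniform(margin, geometry.height - margin)
            c = np.array([cx + rho * np.cos(phi), cy + rho * np.sin(phi), z0])
            if _inside_shell(geometry, c[None, :], margin):
                out.append(LacunaGroundTruth(center=c, semi_axes=axes))
                break
    return out


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _shell_mask(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.grid_shape()
    h = spec.voxel_size
    cx, cy = spec.center_um()
    x = (np.arange(nx) + 0.5) * h - cx
    y = (np.arange(ny) + 0.5) * h - cy
    X, Y = np.meshgrid(x, y)  # (ny, nx)
    rho = np.hypot(X, Y)
    m2d = (rho >= spec.inner_radius) & (rho <= spec.outer_radius)
    a0, a1 = spec.sector
    if (a0, a1) != (0.0, 360.0):
        ang = np.degrees(np.arctan2(Y, X)) % 360.0
        m2d &= (ang >= a0) & (ang <= a1)
    return np.broadcast_to(m2d, (nz, ny, nx)).copy()


def _paint_tube(mask: np.ndarray, spec: PhantomSpec, canal: CanalGroundTruth) -> None:
    """OR the canal tube (distance to centreline ≤ radius) into ``mask``,
    working segment by segment on local bounding boxes."""
    h = spec.voxel_size
    nz, ny, nx = mask.shape
    pts = canal.centerline
    r = canal.radius
    for p0, p1 in zip(pts[:-1], pts[1:]):
        lo = np.minimum(p0, p1) - (r + h)
        hi = np.maximum(p0, p1) + (r + h)
        # world (x,y,z) -> index ranges (z,y,x)
        ix0, ix1 = max(0, int(lo[0] / h)), min(nx, int(np.ceil(hi[0] / h)) + 1)
        iy0, iy1 = max(0, int(lo[1] / h)), min(ny, int(np.ceil(hi[1] / h)) + 1)
        iz0, iz1 = max(0, int(lo[2] / h)), min(nz, int(np.ceil(hi[2] / h)) + 1)
        if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
            continue
        xs = (np.arange(ix0, ix1) + 0.5) * h
        ys = (np.arange(iy0, iy1) + 0.5) * h
        zs = (np.arange(iz0, iz1) + 0.5) * h
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        d = p1 - p0
        dd = float(d @ d)
        if dd == 0:
            dist2 = (X - p0[0]) ** 2 + (Y - p0[1]) ** 2 + (Z - p0[2]) ** 2
        else:
            t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / dd
            t = np.clip(t, 0.0, 1.0)
            dist2 = ((X - (p0[0] + t * d[0])) ** 2
                     + (Y - (p0[1] + t * d[1])) ** 2
                     + (Z - (p0[2] + t * d[2])) ** 2)
        mask[iz0:iz1, iy0:iy1, ix0:ix1] |= dist2 <= r * r


def _paint_ellipsoid(mask: np.ndarray, spec: PhantomSpec, lac: LacunaGroundTruth) -> np.ndarray | None:
    """Voxel set of one (axis-aligned) ellipsoid; returns the painted slice
    coordinates for overlap checks, or paints directly into ``mask``."""
    h = spec.voxel_size
    nz, ny, nx = mask.shape
    c, ax = lac.center, lac.semi_axes
    lo, hi = c - ax.max() - h, c + ax.max() + h
    ix0, ix1 = max(0, int(lo[0] / h)), min(nx, int(np.ceil(hi[0] / h)) + 1)
    iy0, iy1 = max(0, int(lo[1] / h)), min(ny, int(np.ceil(hi[1] / h)) + 1)
    iz0, iz1 = max(0, int(lo[2] / h)), min(nz, int(np.ceil(hi[2] / h)) + 1)
    xs = (np.arange(ix0, ix1) + 0.5) * h
    ys = (np.arange(iy0, iy1) + 0.5) * h
    zs = (np.arange(iz0, iz1) + 0.5) * h
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    inside = (((X - c[0]) / ax[0]) ** 2 + ((Y - c[1]) / ax[1]) ** 2 + ((Z - c[2]) / ax[2]) ** 2) <= 1.0
    mask[iz0:iz1, iy0:iy1, ix0:ix1] |= inside
    return None


@dataclass
class PhantomVolumes:
    """Rendered phantom: noisy grayscale plus noise-free ground-truth masks."""

    grayscale: GrayscaleVolume
    canal_truth: BinaryVolume
    bone_truth: BinaryVolume
    lacuna_truth: BinaryVolume
    spec: PhantomSpec
    dropped_lacunae: int = 0


def render_phantom(spec: PhantomSpec) -> PhantomVolumes:
    """Voxelise the phantom by centre-of-voxel inclusion.

    Grayscale = foreground intensity on mineralised voxels (shell minus
    pores), background elsewhere, plus additive Gaussian noise (seeded from
    ``spec.seed``); ground-truth masks are noise-free and pairwise disjoint.
    Lacunae that would touch a canal are dropped so the two pore populations
    stay disconnected.
    """
    nz, ny, nx = spec.grid_shape()
    if nz * ny * nx > spec.max_voxels:
        raise VoxelBudgetError(
            f"render of {nz}x{ny}x{nx} voxels exceeds the budget of {spec.max_voxels}")
    shell = _shell_mask(spec)
    canal = np.zeros_like(shell)
    for c in spec.canal_specs:
        _paint_tube(canal, spec, c)
    canal &= shell

    lacuna = np.zeros_like(shell)
    dropped = 0
    from scipy import ndimage as ndi
    canal_dil = ndi.binary_dilation(canal) if spec.lacuna_specs else canal
    for lac in spec.lacuna_specs:
        tmp = np.zeros_like(shell)
        _paint_ellipsoid(tmp, spec, lac)
        if (tmp & canal_dil).any():
            dropped += 1
            continue
        lacuna |= tmp
    lacuna &= shell & ~canal

    bone = shell & ~canal & ~lacuna
    rng = np.random.default_rng(spec.seed)
    gray = np.where(bone, spec.foreground_intensity, spec.background_intensity).astype(np.float64)
    if spec.noise_sd > 0:
        gray += rng.normal(0.0, spec.noise_sd, size=gray.shape)
    gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)

    h = spec.voxel_size
    return PhantomVolumes(
        grayscale=GrayscaleVolume(gray, h),
        canal_truth=BinaryVolume(canal, h, label="canals"),
        bone_truth=BinaryVolume(bone, h, label="mineralised"),
        lacuna_truth=BinaryVolume(lacuna, h, label="lacunae"),
        spec=spec,
        dropped_lacunae=dropped,
    )


def build_phantom(
    n_canals: int,
    mixture: tuple[float, float, float, float],
    n_lacunae: int = 0,
    seed: int = 0,
    **spec_kwargs,
) -> PhantomVolumes:
    """Convenience: generate a canal + lacuna population and render it."""
    base = PhantomSpec(seed=seed, **spec_kwargs)
    canals = generate_canal_population(n_canals, mixture, base, seed=seed + 1)
    lacunae = generate_lacuna_population(n_lacunae, base, seed=seed + 2)
    spec = dataclasses.replace(base, canal_specs=canals, lacuna_specs=lacunae)
    return render_phantom(spec)


def ground_truth_indices(canals: list[CanalGroundTruth]) -> ori.OrientationIndices:
    """Length-weighted orientation indices computed directly from the canal
    ground-truth records (chord-length weighting, as in the recovery path)."""
    from .errors import DegenerateInputError
    if not canals:
        raise DegenerateInputError("no canals")
    total = sum(c.chord_length for c in canals)
    by_cat = {c: 0.0 for c in ori.CATEGORIES}
    for c in canals:
        by_cat[c.category] += c.chord_length
    return ori.OrientationIndices(
        laminar_index=by_cat["laminar"] / total,
        longitudinal_index=by_cat["longitudinal"] / total,
        radial_index=by_cat["radial"] / total,
        oblique_index=by_cat["oblique"] / total,
        total_weighted_length=total,
        n_segments=len(canals),
    )


def canal_table(canals: list[CanalGroundTruth]) -> pd.DataFrame:
    """Tidy per-canal ground-truth table (one row per canal)."""
    return pd.DataFrame(
        {
            "category": [c.category for c in canals],
            "true_longitudinal_angle_deg": [c.true_longitudinal_angle for c in canals],
            "true_radial_angle_deg": [c.true_radial_angle for c in canals],
            "chord_length_um": [c.chord_length for c in canals],
            "path_length_um": [c.path_length for c in canals],
            "radius_um": [c.radius for c in canals],
        }
    )


def write_phantom(outdir, vols: PhantomVolumes) -> None:
    """Write grayscale + ground-truth TIFFs, the canal table CSV, and a JSON
    manifest carrying the generating spec and seed."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tiff(outdir / "grayscale.tif", vols.grayscale)
    write_tiff(outdir / "canals_truth.tif", vols.canal_truth)
    write_tiff(outdir / "bone_truth.tif", vols.bone_truth)
    write_tiff(outdir / "lacunae_truth.tif", vols.lacuna_truth)
    canal_table(vols.spec.canal_specs).to_csv(outdir / "canals_truth.csv", index=False)
    spec = vols.spec
    manifest = {
        "outer_radius_um": spec.outer_radius,
        "cortical_thickness_um": spec.cortical_thickness,
        "height_um": spec.height,
        "sector_deg": list(spec.sector),
        "voxel_size_um": spec.voxel_size,
        "foreground_intensity": spec.foreground_intensity,
        "background_intensity": spec.background_intensity,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "n_canals": len(spec.canal_specs),
        "n_lacunae": len(spec.lacuna_specs),
        "dropped_lacunae": vols.dropped_lacunae,
        "center_um": list(spec.center_um()),
        "grid_shape_zyx": list(spec.grid_shape()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
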