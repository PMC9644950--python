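"""Shared fixtures: geometric masks and a session-scoped phantom pipeline run."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from osteovasc import morphometry as mm
from osteovasc import orientation as ori
from osteovasc import phantom as ph
from osteovasc import segmentation as seg
from osteovasc.volumes import BinaryVolume


def make_ball(diameter_vox: float, voxel_size: float = 2.0) -> BinaryVolume:
    n = int(np.ceil(diameter_vox)) + 7
    c = n // 2  # integer centre: the canonical digitisation of a sphere
    z, y, x = np.ogrid[:n, :n, :n]
    m = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= (diameter_vox / 2.0) ** 2
    return BinaryVolume(m, voxel_size)


def make_cylinder(diameter_vox: float, length_vox: int, voxel_size: float = 2.0,
                  pad_z: int = 5) -> BinaryVolume:
    n = int(np.ceil(diameter_vox)) + 7
    c = n // 2
    nz = length_vox + 2 * pad_z
    z, y, x = np.ogrid[:1, :n, :n]
    disk = (x - c) ** 2 + (y - c) ** 2 <= (diameter_vox / 2.0) ** 2
    m = np.zeros((nz, n, n), dtype=bool)
    m[pad_z:pad_z + length_vox] = disk
    return BinaryVolume(m, voxel_size)


def make_hollow_cylinder(outer_vox: float, wall_vox: float, nz: int = 40,
                         voxel_size: float = 2.0) -> BinaryVolume:
    n = int(np.ceil(2 * outer_vox)) + 8
    c = (n - 1) / 2.0
    z, y, x = np.ogrid[:1, :n, :n]
    rho = np.hypot(x - c, y - c)
    ring = (rho <= outer_vox) & (rho >= outer_vox - wall_vox)
    return BinaryVolume(np.broadcast_to(ring, (nz, n, n)).copy(), voxel_size)


def brute_force_local_thickness(mask: BinaryVolume) -> np.ndarray:
    """Independent inscribed-sphere oracle: for every foreground voxel, the
    largest sphere (centre c, coverage radius EDT(c), reported radius
    EDT(c) − 0.5) that contains it.  Values in voxels, in argwhere order."""
    m = mask.voxels
    edt = ndi.distance_transform_edt(m)
    pts = np.argwhere(m).astype(float)
    cover = edt[m]
    rho = cover - 0.5
    lt = np.zeros(len(pts))
    for i, p in enumerate(pts):
        d = np.linalg.norm(pts - p, axis=1)
        lt[i] = 2 * rho[d <= cover].max()
    return lt


SMALL_PHANTOM_KW = dict(outer_radius=300, cortical_thickness=150, height=240,
                        sector=(0.0, 90.0))


@pytest.fixture(scope="session")
def small_phantom() -> ph.PhantomVolumes:
    """~150³-voxel quadrant phantom with 40 canals and 30 lacunae."""
    return ph.build_phantom(40, (0.25, 0.25, 0.25, 0.25), n_lacunae=30, seed=3,
                            **SMALL_PHANTOM_KW)


@pytest.fixture(scope="session")
def phantom200() -> dict:
    """The 200-canal quadrant phantom (default shell geometry, mixture
    0.4/0.3/0.2/0.1) run through the full segmentation → morphometry →
    orientation pipeline once, with ground truth attached."""
    vols = ph.build_phantom(200, (0.4, 0.3, 0.2, 0.1), n_lacunae=150, seed=11,
                            sector=(0.0, 90.0))
    mineral = seg.threshold_min_cross_entropy(vols.grayscale)
    cortex = seg.close_cortex(mineral, 8)
    pores = seg.extract_pores(cortex, mineral)
    canals, lacunae, table = seg.partition_pores(pores)
    frame = ori.estimate_center(cortex)
    skel = ori.skeletonize(canals)
    segments = ori.extract_segments(skel, frame)
    indices = ori.orientation_indices(segments)
    return {
        "vols": vols,
        "mineral": mineral,
        "cortex": cortex,
        "canals": canals,
        "lacunae": lacunae,
        "pore_table": table,
        "frame": frame,
        "segments": segments,
        "indices": indices,
        "gt_indices": ph.ground_truth_indices(vols.spec.canal_specs),
        "porosity": mm.porosity(canals, cortex),
        "gt_porosity": vols.canal_truth.count()
        / (vols.canal_truth.count() + vols.bone_truth.count() + vols.lacuna_truth.count()),
    }
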