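"""Segmentation of the cortex and its intracortical pore network.

Workflow: (1) binarise the grey-value volume with the minimum cross-entropy
(Li) threshold to get the mineralised mask; (2) close the canals with a
ball-structuring-element closing plus hole filling to get the solid cortex
mask; (3) pores = solid cortex minus mineralised tissue (minus an optional
manual exclusion mask, e.g. medullary bone); (4) partition the pore
components by volume into vascular canals (> 1000 μm³) and osteocyte
lacunae (≤ 1000 μm³).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import DegenerateInputError
from .volumes import BinaryVolume, GrayscaleVolume

log = logging.getLogger(__name__)

#: default canal/lacuna volume boundary, μm³
DEFAULT_LACUNA_THRESHOLD = 1000.0

#: 26-neighbourhood structuring element used for pore connectivity
_PORE_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


def minimum_cross_entropy_threshold(values: np.ndarray) -> float:
    """Threshold minimising the cross-entropy objective (Li's criterion) by
    exhaustive search over the grey-level histogram.

    Minimises ``-(A0(t)·log μ0(t) + A1(t)·log μ1(t))`` over all candidate
    thresholds ``t`` taken at observed grey levels, where ``A`` and ``μ`` are
    the grey-value sum and mean of the background (≤ t) and foreground (> t)
    classes.  Foreground is strictly above the returned threshold.  Ties are
    broken toward the lowest threshold.
    """
    vals = np.asarray(values).ravel()
    levels, counts = np.unique(vals, return_counts=True)
    if levels.size < 2:
        raise DegenerateInputError("constant image: thresholding undefined")
    if levels.size > 65536:  # continuous data: bin before searching
        hist, edges = np.histogram(vals, bins=1024)
        levels = 0.5 * (edges[:-1] + edges[1:])
        counts = hist
        keep = counts > 0
        levels, counts = levels[keep], counts[keep]
    levels = levels.astype(np.float64)
    # grey values may be <= 0 on arbitrary data; shift so all levels > 0
    # (the argmin is invariant only up to this monotone relabelling, so the
    # shift is recorded in the objective consistently for all candidates)
    shift = 1.0 - levels.min() if levels.min() <= 0 else 0.0
    g = levels + shift
    w = counts.astype(np.float64)
    cum_n = np.cumsum(w)
    cum_a = np.cumsum(w * g)
    n_tot, a_tot = cum_n[-1], cum_a[-1]
    # candidate thresholds: all levels except the last (both classes nonempty)
    n0, a0 = cum_n[:-1], cum_a[:-1]
    n1, a1 = n_tot - n0, a_tot - a0
    mu0, mu1 = a0 / n0, a1 / n1
    obj = -(a0 * np.log(mu0) + a1 * np.log(mu1))
    i = int(np.argmin(obj))
    return float(levels[i])


def threshold_min_cross_entropy(volume: GrayscaleVolume) -> BinaryVolume:
    """Binarise a grayscale volume at the minimum cross-entropy threshold;
    foreground = grey value strictly above the threshold.  The chosen
    threshold is logged and attached as ``.threshold`` on the result."""
    t = minimum_cross_entropy_threshold(volume.voxels)
    log.info("minimum cross-entropy threshold: %g (foreground > threshold)", t)
    mask = BinaryVolume(volume.voxels > t, volume.voxel_size, label="mineralised")
    mask.threshold = t
    return mask


def _edt_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean dilation by a ball: voxels within ``radius`` of the mask."""
    if mask.all() or not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= radius


def _edt_erode_border_padded(mask: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean erosion by a ball, treating outside-the-volume as foreground
    (so structures that extend to the volume border are not eaten back)."""
    if mask.all():
        return mask.copy()
    if not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(mask) > radius


def close_cortex(mineralised: BinaryVolume, closing_radius: float) -> BinaryVolume:
    """Fill the canals: morphological closing (ball of ``closing_radius``
    voxels — dilation then erosion) followed by hole filling of any interior
    cavities fully enclosed after closing.

    ``closing_radius`` should be at least the largest expected canal radius
    in voxels.  The outer boundary is preserved up to closing-radius
    smoothing; the medullary lumen, being open at the stack ends, is not
    filled.
    """
    if closing_radius <= 0:
        raise ValueError("closing_radius must be positive")
    m = mineralised.voxels
    # Edge-replicate padding so structures cut off by the volume border
    # (quadrant crops) are closed consistently instead of growing a rind
    # where the dilation is truncated.
    pad = int(np.ceil(closing_radius)) + 1
    mp = np.pad(m, pad, mode="edge")
    closed = _edt_erode_border_padded(_edt_dilate(mp, closing_radius), closing_radius)
    closed = closed[pad:-pad, pad:-pad, pad:-pad]
    # closing is extensive; numerical/discrete edge cases must not lose input
    closed |= m
    closed = ndi.binary_fill_holes(closed)
    return BinaryVolume(closed, mineralised.voxel_size, label="solid_cortex")


@dataclass
class LabelledPores:
    """Connected pore components (26-connectivity) of the cortex."""

    labels: np.ndarray       # int array, 0 = background
    voxel_size: float
    voxel_counts: np.ndarray  # (n_components,), counts for labels 1..n

    @property
    def n_components(self) -> int:
        return len(self.voxel_counts)

    @property
    def volumes_um3(self) -> np.ndarray:
        return self.voxel_counts * self.voxel_size**3

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(1, self.n_components + 1),
                "voxel_count": self.voxel_counts,
                "volume_um3": self.volumes_um3,
            }
        )


def extract_pores(
    solid_cortex: BinaryVolume,
    mineralised: BinaryVolume,
    exclusion: BinaryVolume | None = None,
) -> LabelledPores:
    """Pores = solid cortex AND NOT mineralised (AND NOT exclusion), labelled
    with 26-connectivity."""
    if solid_cortex.shape != mineralised.shape:
        raise ValueError("solid_cortex and mineralised masks differ in shape")
    pores = solid_cortex.voxels & ~mineralised.voxels
    if exclusion is not None:
        if exclusion.shape != pores.shape:
            raise ValueError("exclusion mask differs in shape")
        pores &= ~exclusion.voxels
    labels, n = ndi.label(pores, structure=_PORE_STRUCTURE)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    log.debug("extracted %d pore components", n)
    return LabelledPores(labels=labels, voxel_size=solid_cortex.voxel_size, voxel_counts=counts)


def partition_pores(
    components: LabelledPores,
    lacuna_threshold: float = DEFAULT_LACUNA_THRESHOLD,
) -> tuple[BinaryVolume, BinaryVolume, pd.DataFrame]:
    """Split pore components into canals (volume strictly greater than
    ``lacuna_threshold`` μm³) and lacunae (everything else).

    Returns (canal mask, lacuna mask, per-component table with class)."""
    if lacuna_threshold < 0:
        raise ValueError("lacuna_threshold must be non-negative")
    vols = components.volumes_um3
    is_canal = vols > lacuna_threshold
    canal_ids = np.nonzero(is_canal)[0] + 1
    canal_mask = np.isin(components.labels, canal_ids) & (components.labels > 0)
    lacuna_mask = (components.labels > 0) & ~canal_mask
    table = components.table()
    table["class"] = np.where(is_canal, "canal", "lacuna")
    return (
        BinaryVolume(canal_mask, components.voxel_size, label="canals"),
        BinaryVolume(lacuna_mask, components.voxel_size, label="lacunae"),
        table,
    )
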