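"""AFM surface metrology: RMS/mean roughness and particle volume.

Height maps carry heights in nanometers on an isotropic lateral grid whose
pixel size is given in micrometers.  Roughness is computed after removing the
best-fit plane (standard sample-tilt correction); particles are 8-connected
regions above a height threshold (Otsu's level by default) and their volume
integrates the above-threshold height over the particle footprint, reported
in cubic micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu


@dataclass
class HeightMap:
    """A 2-D AFM height raster (nm) with lateral pixel size (um/pixel)."""

    heights: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2:
            raise ValueError("height map must be 2-D")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("non-finite heights")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class ParticleStats:
    """Segmentation result of :func:`particle_volume`."""

    total_volume_um3: float
    count: int
    volumes_um3: np.ndarray
    threshold_nm: float


def detrend_plane(heights: np.ndarray) -> np.ndarray:
    """Subtract the least-squares best-fit plane from a height raster."""
    h = np.asarray(heights, dtype=np.float64)
    ny, nx = h.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([xx.ravel(), yy.ravel(), np.ones(h.size)])
    coef, *_ = np.linalg.lstsq(A, h.ravel(), rcond=None)
    return h - (A @ coef).reshape(h.shape)


def surface_roughness(hmap: HeightMap, kind: str = "Rq") -> float:
    """Surface roughness in nm after plane detrending.

    ``Rq`` (default) is the root-mean-square deviation, ``Ra`` the mean
    absolute deviation.  A perfectly flat or purely tilted surface gives 0.
    """
    if hmap.heights.size < 2:
        raise ValueError("roughness needs at least 2 pixels")
    d = detrend_plane(hmap.heights)
    if kind == "Rq":
        return float(np.sqrt(np.mean(d ** 2)))
    if kind == "Ra":
        return float(np.mean(np.abs(d)))
    raise ValueError(f"unknown roughness kind {kind!r} (use 'Rq' or 'Ra')")


_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def particle_volume(hmap: HeightMap,
                    threshold: float | None = None) -> ParticleStats:
    """Segment particles above a height threshold and integrate their volume.

    ``threshold`` is in nm; None selects Otsu's level on the height
    histogram.  Particles are 8-connected components of the above-threshold
    mask; each pixel contributes (height - threshold) * pixel_size^2 with
    heights converted nm -> um, so volumes are in um^3.
    """
    h = hmap.heights
    if threshold is None:
        if h.max() == h.min():
            return ParticleStats(0.0, 0, np.array([]), float(h.max()))
        threshold = float(threshold_otsu(h))
    mask = h > threshold
    if not mask.any():
        return ParticleStats(0.0, 0, np.array([]), float(threshold))
    labels, count = ndimage.label(mask, structure=_EIGHT_CONN)
    excess_um = (h - threshold) * 1e-3 * mask
    per_particle = ndimage.sum_labels(excess_um, labels,
                                      index=np.arange(1, count + 1))
    per_particle = np.asarray(per_particle) * hmap.pixel_size ** 2
    return ParticleStats(float(per_particle.sum()), int(count),
                         per_particle, float(threshold))


def load_height_map(path: str | Path, pixel_size: float) -> HeightMap:
    """Read a float TIFF or whitespace-delimited ASCII matrix of heights (nm)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        heights = tifffile.imread(path)
    else:
        heights = np.loadtxt(path)
    return HeightMap(heights=heights, pixel_size=pixel_size)


def save_height_map(hmap: HeightMap, path: str | Path) -> None:
    """Write a height map as 32-bit float TIFF or ASCII matrix by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, hmap.heights.astype(np.float32))
    else:
        np.savetxt(path, hmap.heights)
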