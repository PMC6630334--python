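"""Seed segmentation and per-seed mean-spectrum extraction.

Seeds sit on a dark plate, so a single NIR band image thresholded at a fixed
reflectance separates them from the background; 1301 nm (a band informative
for seed composition) at threshold 0.15 is the default.  Connected components
of the binary mask become seed regions; the pixels of each region are
averaged into one spectrum per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InternalInconsistencyError
from .hsi_io import CalibratedCube, nearest_band
from .spectra import SpectraTable

# 4-connectivity: diagonal neighbours do not bridge regions.
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class SeedMask:
    """Labelled seed regions: 0 = background, 1..K = seeds in raster order."""

    labels: np.ndarray
    band_used: float
    threshold: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or np.any(self.labels < 0):
            raise ValueError("labels must be a 2-D non-negative integer image")

    @property
    def n_seeds(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def seed_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def threshold_mask(cube: CalibratedCube, band_nm: float = 1301.0,
                   threshold: float = 0.15) -> np.ndarray:
    """Binary foreground mask: reflectance at the band nearest ``band_nm``
    strictly above ``threshold``."""
    wl = cube.wavelengths
    if not wl[0] <= band_nm <= wl[-1]:
        raise ValueError(
            f"band {band_nm} nm outside the cube range "
            f"[{wl[0]:.2f}, {wl[-1]:.2f}] nm"
        )
    band = nearest_band(wl, band_nm)
    return cube.reflectance[:, :, band] > threshold


def label_seeds(binary: np.ndarray, min_area: int = 10,
                band_used: float = 1301.0, threshold: float = 0.15) -> SeedMask:
    """Label 4-connected components, dropping specks below ``min_area`` pixels.

    Surviving components are renumbered 1..K in raster order of their first
    pixel.
    """
    binary = np.asarray(binary, dtype=bool)
    raw_labels, n_raw = ndimage.label(binary, structure=_STRUCTURE_4)
    if n_raw == 0:
        return SeedMask(labels=np.zeros_like(raw_labels), band_used=band_used,
                        threshold=threshold)
    areas = np.bincount(raw_labels.ravel(), minlength=n_raw + 1)
    keep = np.nonzero(areas[1:] >= min_area)[0] + 1
    # scipy labels components in raster order of first encounter, so a dense
    # renumbering of the kept ids preserves raster order.
    remap = np.zeros(n_raw + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return SeedMask(labels=remap[raw_labels], band_used=band_used,
                    threshold=threshold)


def extract_mean_spectra(cube: CalibratedCube, mask: SeedMask) -> SpectraTable:
    """One arithmetic-mean spectrum per labelled seed, rows in label order."""
    if mask.labels.shape != cube.reflectance.shape[:2]:
        raise ValueError("mask and cube spatial shapes differ")
    k = mask.n_seeds
    n_bands = cube.reflectance.shape[2]
    if k == 0:
        return SpectraTable(spectra=np.empty((0, n_bands)),
                            wavelengths=cube.wavelengths.copy(),
                            seed_ids=np.empty(0, dtype=int))
    flat_labels = mask.labels.ravel()
    counts = np.bincount(flat_labels, minlength=k + 1)[1:]
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        raise InternalInconsistencyError(
            f"seed label {empty[0] + 1} has no pixels"
        )
    pixels = cube.reflectance.reshape(-1, n_bands)
    sums = np.zeros((k + 1, n_bands))
    np.add.at(sums, flat_labels, pixels)
    means = sums[1:] / counts[:, np.newaxis]
    return SpectraTable(spectra=means, wavelengths=cube.wavelengths.copy(),
                        seed_ids=np.arange(1, k + 1))
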